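"""Drawing of lattice conformations in the Euclidean embedding."""

from __future__ import annotations

from typing import Optional

from .lattice import to_euclidean
from .model import FoldsLike, decode, energy


def plot_conformation(seq: str, folds: FoldsLike, ax=None, path: Optional[str] = None,
                      title: Optional[str] = None):
    """Draw a conformation: filled dots for H, open circles for P.

    Returns the matplotlib Axes; saves to ``path`` if given.
    """
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    walk = decode(folds)
    pts = [to_euclidean((int(x), int(y))) for x, y in walk]
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    ax.plot(xs, ys, "-", color="0.6", lw=1.5, zorder=1)
    for (x, y), res in zip(pts, seq):
        if res == "H":
            ax.plot(x, y, "o", color="black", ms=9, zorder=2)
        else:
            ax.plot(x, y, "o", mfc="white", mec="red", ms=9, zorder=2)
    ax.set_aspect("equal")
    ax.axis("off")
    if title is None:
        try:
            title = f"E = {energy(seq, folds)}"
        except ValueError:
            title = "infeasible"
    ax.set_title(title)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
    return ax
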