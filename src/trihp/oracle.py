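"""Exhaustive ground-truth enumeration for short HP sequences.

Depth-first enumeration of all self-avoiding fold strings with prefix
pruning, returning the exact minimum free energy and a witness. This is
deliberately an independent implementation — incremental contact
counting over a site dictionary, no shared scoring code with the search
path — so it can serve as a correctness oracle for the GA.

To keep the feasible length up around 12 residues, lattice symmetries
are quotiented out: the first step is fixed to R (rotations) and the
first step off the R/L axis is restricted to the upper half-plane
(reflections). Energies are unaffected; the count of optima is then per
symmetry class. The unpruned enumeration remains available via
``symmetry=False`` and the two are cross-checked in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import validate_hp

__all__ = ["OracleResult", "OracleSizeError", "enumerate_min_energy"]

# direction-code unit vectors, order R, RU, LU, L, LD, RD
_VECS = ((1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1))
_UP_OFF_AXIS = (1, 2)  # RU, LU
_DOWN_OFF_AXIS = (4, 5)  # LD, RD


class OracleSizeError(ValueError):
    """Enumeration refused: the sequence exceeds the size guard."""


@dataclass(frozen=True)
class OracleResult:
    min_energy: int
    optimal_count: int
    one_optimum: np.ndarray

    def __iter__(self):  # convenience unpacking
        return iter((self.min_energy, self.optimal_count, self.one_optimum))


def enumerate_min_energy(seq: str, max_n: int = 12, symmetry: bool = True) -> OracleResult:
    """Exact minimum energy over all self-avoiding conformations.

    Parameters
    ----------
    seq : HP string, length at most ``max_n``.
    max_n : refusal guard; the search space grows like 6**(n-1).
    symmetry : quotient out rotation/reflection symmetry (12x fewer
        walks; identical minimum energy).
    """
    validate_hp(seq)
    n = len(seq)
    if n > max_n:
        raise OracleSizeError(
            f"sequence length {n} exceeds the enumeration guard {max_n}; "
            "raise max_n explicitly if you really want this"
        )
    if n == 1:
        return OracleResult(0, 1, np.empty(0, dtype=np.int64))

    is_h = [c == "H" for c in seq]
    occupied = {(0, 0): 0}
    folds = [0] * (n - 1)

    best = {"energy": 1, "count": 0, "witness": None}

    def dfs(i: int, x: int, y: int, contacts: int, off_axis: bool) -> None:
        # i = index of the residue being placed next (1..n-1)
        if i == n:
            e = -contacts
            if e < best["energy"]:
                best["energy"] = e
                best["count"] = 1
                best["witness"] = list(folds)
            elif e == best["energy"]:
                best["count"] += 1
            return
        if symmetry and i == 1:
            choices = (0,)  # first step fixed to R
        elif symmetry and not off_axis:
            choices = (0, 1, 2, 3)  # first off-axis step must go up
        else:
            choices = (0, 1, 2, 3, 4, 5)
        for d in choices:
            dx, dy = _VECS[d]
            nx, ny = x + dx, y + dy
            if (nx, ny) in occupied:
                continue
            gained = 0
            if is_h[i]:
                for ex, ey in _VECS:
                    j = occupied.get((nx + ex, ny + ey))
                    if j is not None and j < i - 1 and is_h[j]:
                        gained += 1
            occupied[(nx, ny)] = i
            folds[i - 1] = d
            dfs(i + 1, nx, ny, contacts + gained, off_axis or d in (1, 2, 4, 5))
            del occupied[(nx, ny)]

    dfs(1, 0, 0, 0, off_axis=False)
    assert best["witness"] is not None  # a straight chain is always feasible
    return OracleResult(
        int(best["energy"]), int(best["count"]), np.array(best["witness"], dtype=np.int64)
    )
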