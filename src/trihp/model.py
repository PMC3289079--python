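"""HP sequences, power notation, conformation decoding and free energy.

An HP sequence is a plain string over ``{H, P}``; H residues are
hydrophobic, P residues polar. A conformation of an n-residue chain is
a fold string of length n-1 over the six triangular-lattice directions,
giving the absolute step from each residue to the next. Decoding places
residue 0 at the origin and follows the steps.

The free energy of a self-avoiding conformation is -1 per topological
H-H contact: a pair of H residues non-adjacent in the sequence whose
sites are lattice neighbors. Lower energy is better; the native
structure is modeled as the global minimum over all self-avoiding walks.

For search, infeasible (self-colliding) conformations are scored by a
penalized fitness: the raw contact score plus a dominating penalty per
colliding residue pair, so every infeasible chromosome ranks strictly
below every feasible one while still feeling a gradient toward
feasibility.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Iterator, List, Sequence, Tuple, Union

import numpy as np

from .lattice import DIRECTION_VECTORS, Direction
from ._kernels import Evaluator

__all__ = [
    "ParseError",
    "InfeasibleConformationError",
    "validate_hp",
    "parse_hp_notation",
    "hp_mask",
    "fold_array",
    "folds_to_symbols",
    "decode",
    "is_self_avoiding",
    "count_hh_contacts",
    "energy",
    "fitness",
    "default_penalty",
    "read_hp_fasta",
    "write_hp_fasta",
    "read_conformations",
    "write_conformations",
]

FoldsLike = Union[str, Sequence[Union[int, str, Direction]], np.ndarray]


class ParseError(ValueError):
    """Raised for malformed HP strings or power notation."""


class InfeasibleConformationError(ValueError):
    """Raised when an energy is requested for a self-colliding walk."""


def validate_hp(seq: str) -> str:
    """Check that ``seq`` is a nonempty string over {H, P} and return it."""
    if not seq:
        raise ParseError("empty HP sequence")
    bad = re.search(r"[^HP]", seq)
    if bad:
        raise ParseError(f"invalid residue {seq[bad.start()]!r} at position {bad.start()}")
    return seq


def parse_hp_notation(text: str) -> str:
    """Expand power notation like ``(HP)^2PH^3`` into a plain HP string.

    The grammar is a sequence of terms, each an ``H``, a ``P`` or a
    parenthesized group, optionally followed by ``^k`` with k >= 1.
    Expansion is purely syntactic repetition, applied recursively.
    """
    text = text.strip()
    pos = 0

    def parse_seq(depth: int) -> str:
        nonlocal pos
        out: List[str] = []
        while pos < len(text):
            ch = text[pos]
            if ch in "HP":
                unit = ch
                pos += 1
            elif ch == "(":
                pos += 1
                unit = parse_seq(depth + 1)
                if pos >= len(text) or text[pos] != ")":
                    raise ParseError(f"unbalanced '(' opened before position {pos}")
                pos += 1
            elif ch == ")":
                if depth == 0:
                    raise ParseError(f"unbalanced ')' at position {pos}")
                break
            else:
                raise ParseError(f"unexpected character {ch!r} at position {pos}")
            if pos < len(text) and text[pos] == "^":
                pos += 1
                m = re.match(r"\d+", text[pos:])
                if not m:
                    raise ParseError(f"missing exponent after '^' at position {pos}")
                k = int(m.group())
                if k <= 0:
                    raise ParseError(f"exponent must be >= 1 at position {pos}")
                pos += len(m.group())
                unit = unit * k
            out.append(unit)
        return "".join(out)

    result = parse_seq(0)
    if pos != len(text):
        raise ParseError(f"unexpected character {text[pos]!r} at position {pos}")
    return validate_hp(result)


def hp_mask(seq: str) -> np.ndarray:
    """Return a uint8 mask, 1 where the residue is H."""
    validate_hp(seq)
    return np.frombuffer(seq.encode(), dtype=np.uint8) == ord("H")


_SYMBOL_TO_CODE = {d.name: int(d) for d in Direction}


def fold_array(folds: FoldsLike) -> np.ndarray:
    """Coerce a fold description to an int64 array of direction codes.

    Accepts a dash-separated symbol string (``"R-RU-LU"``), an iterable
    of :class:`Direction`/symbol names/integer codes, or an ndarray.
    """
    if isinstance(folds, np.ndarray):
        arr = folds.astype(np.int64, copy=True)
    elif isinstance(folds, str):
        if not folds:
            return np.empty(0, dtype=np.int64)
        try:
            arr = np.array([_SYMBOL_TO_CODE[s] for s in folds.split("-")], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"unknown direction symbol {exc.args[0]!r}") from None
    else:
        codes = []
        for f in folds:
            if isinstance(f, str):
                if f not in _SYMBOL_TO_CODE:
                    raise ValueError(f"unknown direction symbol {f!r}")
                codes.append(_SYMBOL_TO_CODE[f])
            else:
                codes.append(int(Direction(f)))
        arr = np.array(codes, dtype=np.int64)
    if arr.size and (arr.min() < 0 or arr.max() > 5):
        raise ValueError("direction codes must be in 0..5")
    return arr


def folds_to_symbols(folds: FoldsLike) -> str:
    """Render a fold array as a dash-separated symbol string."""
    arr = fold_array(folds)
    return "-".join(Direction(int(c)).name for c in arr)


def decode(folds: FoldsLike) -> np.ndarray:
    """Decode a fold string into an (n, 2) array of axial coordinates.

    The first residue sits at the origin; decoding never fails (self
    collisions are detected separately by :func:`is_self_avoiding`).
    """
    arr = fold_array(folds)
    n = arr.shape[0] + 1
    coords = np.zeros((n, 2), dtype=np.int64)
    vecs = np.array(DIRECTION_VECTORS, dtype=np.int64)
    if arr.size:
        np.cumsum(vecs[arr], axis=0, out=coords[1:])
    return coords


def is_self_avoiding(walk: np.ndarray) -> bool:
    """True iff all coordinates of the decoded walk are distinct."""
    return len({(int(x), int(y)) for x, y in walk}) == len(walk)


def count_hh_contacts(seq: str, walk: np.ndarray) -> int:
    """Count H-H pairs non-adjacent in sequence sitting at unit distance.

    Counted on the coordinates as given, whether or not the walk is
    self-avoiding. Implemented as a vectorized all-pairs scan (the
    search path uses a faster occupancy-grid kernel; the two are checked
    against each other in the test suite).
    """
    mask = hp_mask(seq)
    if walk.shape[0] != mask.shape[0]:
        raise ValueError(f"walk length {walk.shape[0]} != sequence length {mask.shape[0]}")
    idx = np.flatnonzero(mask)
    if idx.size < 2:
        return 0
    pts = walk[idx]
    dx = pts[:, 0][:, None] - pts[:, 0][None, :]
    dy = pts[:, 1][:, None] - pts[:, 1][None, :]
    unit = (np.abs(dx) <= 1) & (np.abs(dy) <= 1) & (np.abs(dx + dy) <= 1) & ~((dx == 0) & (dy == 0))
    sep = np.abs(idx[:, None] - idx[None, :]) > 1
    return int(np.count_nonzero(np.triu(unit & sep)))


def default_penalty(seq: str) -> int:
    """Dominating per-collision penalty: 4n (no walk has more contacts)."""
    return 4 * len(seq)


def energy(seq: str, folds: FoldsLike) -> int:
    """Free energy of a self-avoiding conformation: -1 per H-H contact.

    Raises :class:`InfeasibleConformationError` if the decoded walk
    revisits a site; use :func:`fitness` for penalized scoring.
    """
    arr = fold_array(folds)
    _check_lengths(seq, arr)
    ev = Evaluator(hp_mask(seq))
    fit, contacts, collisions = ev.evaluate(arr)
    if collisions:
        raise InfeasibleConformationError(
            f"conformation revisits a site ({collisions} colliding pair(s))"
        )
    return -contacts


def fitness(seq: str, folds: FoldsLike, penalty_per_collision: int | None = None) -> int:
    """Penalized score: equals :func:`energy` when self-avoiding, else
    ``-contacts + penalty * (number of colliding residue pairs)``.
    """
    arr = fold_array(folds)
    _check_lengths(seq, arr)
    ev = Evaluator(hp_mask(seq), penalty=penalty_per_collision)
    fit, _, _ = ev.evaluate(arr)
    return int(fit)


def _check_lengths(seq: str, arr: np.ndarray) -> None:
    if arr.shape[0] != len(seq) - 1:
        raise ValueError(
            f"fold string length {arr.shape[0]} != n-1 = {len(seq) - 1}"
        )


# ---------------------------------------------------------------------------
# Text formats
# ---------------------------------------------------------------------------

_NOTATION_HINT = re.compile(r"[\d()^]")


def read_hp_fasta(path: Union[str, Path]) -> List[Tuple[str, str]]:
    """Read a FASTA-like file of HP sequences.

    Records start with ``>name``; sequence lines may be plain HP strings
    or power notation (auto-detected by the presence of digits,
    parentheses or '^'). Returns a list of (name, expanded sequence).
    """
    records: List[Tuple[str, str]] = []
    name = None
    chunks: List[str] = []

    def flush():
        if name is not None:
            body = "".join(chunks)
            seq = parse_hp_notation(body) if _NOTATION_HINT.search(body) else validate_hp(body)
            records.append((name, seq))

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].strip()
            chunks = []
        else:
            if name is None:
                raise ParseError("sequence data before any '>' header")
            chunks.append(line)
    flush()
    return records


def write_hp_fasta(path: Union[str, Path], records: Iterable[Tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def write_conformations(
    path: Union[str, Path],
    records: Iterable[Tuple[str, FoldsLike, int]],
) -> None:
    """Write conformation records: ``name <TAB> R-RU-... <TAB> energy``."""
    with open(path, "w") as fh:
        for name, folds, e in records:
            fh.write(f"{name}\t{folds_to_symbols(folds)}\t{int(e)}\n")


def read_conformations(path: Union[str, Path]) -> Iterator[Tuple[str, np.ndarray, int]]:
    """Yield (name, fold array, energy) from the conformation text format."""
    for i, raw in enumerate(Path(path).read_text().splitlines()):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) != 3:
            raise ParseError(f"line {i + 1}: expected 3 tab-separated fields")
        name, sym, e = parts
        yield name, fold_array(sym), int(e)
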