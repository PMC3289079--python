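"""2D triangular-lattice geometry: fold directions, neighbor tests, rotations.

The lattice is represented in integer axial coordinates so that
self-avoidance and contact tests are exact. Each site has six neighbors,
reached by the six unit fold directions R, RU, LU, L, LD, RD. The
directions are numbered 0..5 counter-clockwise, so a rotation by
``k * 60`` degrees is addition of ``k`` modulo 6.

Axial convention (normative for this package)::

    R  = ( 1,  0)    L  = (-1,  0)
    RU = ( 0,  1)    LD = ( 0, -1)
    LU = (-1,  1)    RD = ( 1, -1)

The Euclidean embedding ``(x + y/2, y * sqrt(3)/2)`` maps lattice
neighbors to points at unit distance.
"""

from __future__ import annotations

import math
from enum import IntEnum
from typing import Tuple

__all__ = [
    "Direction",
    "DIRECTION_VECTORS",
    "direction_vector",
    "opposite",
    "are_neighbors",
    "rotate_direction",
    "to_euclidean",
]

LatticeCoord = Tuple[int, int]


class Direction(IntEnum):
    """One of the six fold directions, ordered counter-clockwise from R."""

    R = 0
    RU = 1
    LU = 2
    L = 3
    LD = 4
    RD = 5

    @property
    def vector(self) -> LatticeCoord:
        return DIRECTION_VECTORS[self]

    @property
    def opposite(self) -> "Direction":
        return Direction((self + 3) % 6)


#: Unit step of each direction, indexed by Direction value.
DIRECTION_VECTORS: Tuple[LatticeCoord, ...] = (
    (1, 0),  # R
    (0, 1),  # RU
    (-1, 1),  # LU
    (-1, 0),  # L
    (0, -1),  # LD
    (1, -1),  # RD
)

_UNIT_SET = frozenset(DIRECTION_VECTORS)

_SQRT3_2 = math.sqrt(3.0) / 2.0


def direction_vector(d: Direction) -> LatticeCoord:
    """Return the axial unit step for direction ``d``."""
    try:
        return DIRECTION_VECTORS[Direction(d)]
    except ValueError as exc:
        raise ValueError(f"invalid direction: {d!r}") from exc


def opposite(d: Direction) -> Direction:
    """Return the direction pointing the opposite way (180 degrees)."""
    return Direction(d).opposite


def are_neighbors(a: LatticeCoord, b: LatticeCoord) -> bool:
    """True iff ``a`` and ``b`` are distinct sites at unit lattice distance."""
    return (b[0] - a[0], b[1] - a[1]) in _UNIT_SET


def rotate_direction(d: Direction, angle_steps: int) -> Direction:
    """Rotate ``d`` counter-clockwise by ``angle_steps`` * 60 degrees.

    ``angle_steps`` must lie in 1..5; three steps give the opposite
    direction and six steps would be the identity.
    """
    if not 1 <= angle_steps <= 5:
        raise ValueError(f"rotation must be 1..5 steps of 60 degrees, got {angle_steps}")
    return Direction((Direction(d) + angle_steps) % 6)


def to_euclidean(c: LatticeCoord) -> Tuple[float, float]:
    """Map an axial coordinate to the Euclidean plane (unit edge length)."""
    x, y = c
    return (x + y / 2.0, y * _SQRT3_2)
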