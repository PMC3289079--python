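"""Numba-compiled inner loops for conformation evaluation and local search.

Conformations are held as int64 arrays of direction codes 0..5 (see
:mod:`trihp.lattice` for the code/vector convention). The evaluation
kernel decodes the walk, counts colliding residue pairs with an
occupancy grid (chained by residue index so multiply-occupied sites are
handled exactly), and counts H-H topological contacts on the
coordinates as given. Fitness is ``-contacts + penalty * collisions``.

All randomness is drawn outside the kernels and passed in as arrays, so
runs are reproducible from a single seeded NumPy generator.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Unit vectors in direction-code order R, RU, LU, L, LD, RD.
_VECX = np.array([1, 0, -1, -1, 0, 1], dtype=np.int64)
_VECY = np.array([0, 1, 1, 0, -1, -1], dtype=np.int64)


@njit(cache=True)
def _evaluate(hmask, folds, penalty, xs, ys, head, nxt, grid_n):
    """Decode and score one conformation.

    Returns (fitness, contacts, collisions). ``head``/``nxt`` implement
    per-site chains of residue indices; touched cells are reset before
    returning so the workspace can be reused.
    """
    n = hmask.shape[0]
    x = np.int64(0)
    y = np.int64(0)
    xs[0] = 0
    ys[0] = 0
    for i in range(n - 1):
        d = folds[i]
        x += _VECX[d]
        y += _VECY[d]
        xs[i + 1] = x
        ys[i + 1] = y

    collisions = 0
    for i in range(n):
        c = (xs[i] + n) * grid_n + (ys[i] + n)
        j = head[c]
        while j != -1:
            collisions += 1
            j = nxt[j]
        nxt[i] = head[c]
        head[c] = i

    contacts = 0
    for i in range(n):
        if hmask[i]:
            for d in range(6):
                c = (xs[i] + _VECX[d] + n) * grid_n + (ys[i] + _VECY[d] + n)
                j = head[c]
                while j != -1:
                    # count each pair once, from its lower index
                    if j > i + 1 and hmask[j]:
                        contacts += 1
                    j = nxt[j]

    for i in range(n):
        head[(xs[i] + n) * grid_n + (ys[i] + n)] = -1

    fitness = -contacts + penalty * collisions
    return fitness, contacts, collisions


@njit(cache=True)
def _ls1_pass(hmask, folds, order, offsets, penalty, cur_fit, xs, ys, head, nxt, grid_n):
    """One first-improvement pass of single-direction hill climbing.

    Visits positions in the given order; at position ``order[t]``
    proposes replacing the direction by ``(old + offsets[t]) % 6``
    (offsets in 1..5, i.e. a uniformly random different symbol) and
    accepts iff the fitness strictly improves. Mutates ``folds`` in
    place and returns the resulting fitness.
    """
    fit = cur_fit
    for t in range(order.shape[0]):
        pos = order[t]
        old = folds[pos]
        folds[pos] = (old + offsets[t]) % 6
        f2, _, _ = _evaluate(hmask, folds, penalty, xs, ys, head, nxt, grid_n)
        if f2 < fit:
            fit = f2
        else:
            folds[pos] = old
    return fit


@njit(cache=True)
def _ls2_rotate_tail(hmask, folds, pivot, penalty, cur_fit, xs, ys, head, nxt, grid_n):
    """Try the five tail rotations about ``pivot``; keep the best if it
    strictly improves on ``cur_fit``. Mutates ``folds`` in place and
    returns the resulting fitness. Ties favor the smallest rotation.
    """
    m = folds.shape[0]
    best_k = 0
    best_fit = cur_fit
    for k in range(1, 6):
        for i in range(pivot, m):
            folds[i] = (folds[i] + 1) % 6
        f2, _, _ = _evaluate(hmask, folds, penalty, xs, ys, head, nxt, grid_n)
        if f2 < best_fit:
            best_fit = f2
            best_k = k
    # folds is now rotated by 5 steps; bring it to best_k (0 = original)
    back = (best_k - 5) % 6
    if back != 0:
        for i in range(pivot, m):
            folds[i] = (folds[i] + back) % 6
    return best_fit


class Evaluator:
    """Reusable scoring workspace for one HP sequence.

    Parameters
    ----------
    hmask : array of bool/uint8, length n
        True where the residue is hydrophobic.
    penalty : int
        Fitness penalty added per colliding residue pair. The default
        4n dominates any attainable contact count, so every infeasible
        conformation scores strictly worse than every self-avoiding one.
    """

    def __init__(self, hmask: np.ndarray, penalty: int | None = None):
        self.hmask = np.ascontiguousarray(hmask, dtype=np.uint8)
        n = int(self.hmask.shape[0])
        self.n = n
        self.penalty = np.int64(4 * n if penalty is None else penalty)
        self._xs = np.empty(n, dtype=np.int64)
        self._ys = np.empty(n, dtype=np.int64)
        self._grid_n = np.int64(2 * n + 1)
        self._head = np.full(self._grid_n * self._grid_n, -1, dtype=np.int64)
        self._nxt = np.empty(n, dtype=np.int64)

    def evaluate(self, folds: np.ndarray):
        """Return (fitness, contacts, collisions) for a fold array."""
        if folds.shape[0] != self.n - 1:
            raise ValueError(
                f"fold string length {folds.shape[0]} != n-1 = {self.n - 1}"
            )
        return _evaluate(
            self.hmask, folds, self.penalty,
            self._xs, self._ys, self._head, self._nxt, self._grid_n,
        )

    def ls1_pass(self, folds, order, offsets, cur_fit):
        return _ls1_pass(
            self.hmask, folds, order, offsets, self.penalty, cur_fit,
            self._xs, self._ys, self._head, self._nxt, self._grid_n,
        )

    def ls2_rotate_tail(self, folds, pivot, cur_fit):
        return _ls2_rotate_tail(
            self.hmask, folds, np.int64(pivot), self.penalty, cur_fit,
            self._xs, self._ys, self._head, self._nxt, self._grid_n,
        )
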