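"""Hill-climbing local search operators and the HHGA hybrid.

Two operators refine a chromosome between reproduction and insertion:

* **Local search I** — single-direction moves. One pass visits every
  gene in a random order, proposes a uniformly random different
  direction, and accepts the move iff the fitness strictly improves
  (first-improvement hill climbing).

* **Local search II** — tail rotations. A pivot is picked among the
  interior gene positions; rotating every gene from the pivot onward by
  k*60 degrees (k = 1..5) rigidly rotates the decoded tail sub-walk
  about the pivot residue. The best of the five rotations replaces the
  input iff it strictly improves.

Neither operator ever returns a worse fitness than its input. The HHGA
is the ERS-GA with both operators applied to every newly bred offspring
(elite members are left alone), trading roughly a (n+5)-fold increase
in fitness evaluations for much stronger exploitation.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from ._kernels import Evaluator
from .ga import GAConfig, Individual, Refiner, RunResult, run_ga
from .model import FoldsLike, fold_array, hp_mask

__all__ = ["local_search_1", "local_search_2", "run_hhga"]


def _ls1_inplace(ev: Evaluator, ind: Individual, passes: int, rng: np.random.Generator) -> Individual:
    m = ind.folds.shape[0]
    fit = ind.fitness
    for _ in range(passes):
        order = rng.permutation(m)
        offsets = rng.integers(1, 6, size=m)
        fit = int(ev.ls1_pass(ind.folds, order, offsets, fit))
    if fit != ind.fitness:
        f2, contacts, collisions = ev.evaluate(ind.folds)
        return Individual(ind.folds, int(f2), int(contacts), int(collisions))
    return ind


def _ls2_inplace(ev: Evaluator, ind: Individual, trials: int, scan_all: bool,
                 rng: np.random.Generator) -> Individual:
    m = ind.folds.shape[0]
    if m < 2:
        return ind
    fit = ind.fitness
    if scan_all:
        for pivot in range(1, m):
            fit = int(ev.ls2_rotate_tail(ind.folds, pivot, fit))
    else:
        for _ in range(trials):
            pivot = int(rng.integers(1, m))
            fit = int(ev.ls2_rotate_tail(ind.folds, pivot, fit))
    if fit != ind.fitness:
        f2, contacts, collisions = ev.evaluate(ind.folds)
        return Individual(ind.folds, int(f2), int(contacts), int(collisions))
    return ind


def local_search_1(
    seq: str,
    folds: FoldsLike,
    passes: int = 1,
    rng: Optional[np.random.Generator] = None,
    penalty: Optional[int] = None,
) -> np.ndarray:
    """First-improvement hill climbing over single-direction moves.

    Returns a (possibly improved) copy of the fold array; the returned
    fitness is never worse than the input's.
    """
    if passes < 0:
        raise ValueError("passes must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    arr = fold_array(folds)
    ev = Evaluator(hp_mask(seq), penalty=penalty)
    fit, contacts, collisions = ev.evaluate(arr)
    _ls1_inplace(ev, Individual(arr, int(fit), int(contacts), int(collisions)), passes, rng)
    return arr


def local_search_2(
    seq: str,
    folds: FoldsLike,
    rng: Optional[np.random.Generator] = None,
    penalty: Optional[int] = None,
    pivot: Optional[int] = None,
) -> np.ndarray:
    """Best-of-five tail rotation about one pivot (random unless given).

    Too-short chromosomes (fewer than two genes) are returned unchanged.
    """
    rng = np.random.default_rng() if rng is None else rng
    arr = fold_array(folds)
    m = arr.shape[0]
    if m < 2:
        return arr
    ev = Evaluator(hp_mask(seq), penalty=penalty)
    fit, _, _ = ev.evaluate(arr)
    if pivot is None:
        pivot = int(rng.integers(1, m))
    elif not 1 <= pivot < m:
        raise ValueError(f"pivot must be in 1..{m - 1}")
    ev.ls2_rotate_tail(arr, pivot, int(fit))
    return arr


def _make_refiner(cfg: GAConfig):
    def factory(ev: Evaluator, rng: np.random.Generator) -> Refiner:
        def refine(ind: Individual) -> Individual:
            ind = _ls1_inplace(ev, ind, cfg.ls1_passes, rng)
            ind = _ls2_inplace(ev, ind, cfg.ls2_trials_per_offspring, cfg.ls2_scan_all, rng)
            return ind
        return refine
    return factory


def run_hhga(seq: str, cfg: GAConfig) -> RunResult:
    """Run the hybrid: ERS-GA with both local searches on each offspring.

    With zero local-search budget this reduces exactly to
    :func:`trihp.ga.run_ersga` under the same seed.
    """
    cfg = cfg.with_(local_search=True)
    if cfg.ls1_passes == 0 and cfg.ls2_trials_per_offspring == 0 and not cfg.ls2_scan_all:
        return run_ga(seq, cfg, refine_factory=None)
    return run_ga(seq, cfg, refine_factory=_make_refiner(cfg))
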