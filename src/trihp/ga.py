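"""Elite-based-reproduction genetic algorithm (ERS-GA) for lattice folding.

Each chromosome is a fold string of length n-1 over the six triangular
directions; the fitness is the penalized free energy from
:mod:`trihp.model` (lower is better). Every generation, the fitter half
of the sorted population survives unchanged and the other half is
replaced by offspring bred via two-point crossover and uniform
mutation (by default: random pairing over the whole population, and a
0.4 chance per offspring of re-drawing one gene; both choices are
configurable, see :class:`GAConfig`). Elitism makes the best fitness non-increasing over
generations.

All stochastic draws consume one seeded NumPy generator in a fixed
order (initialization, then per generation: pairing, per pair crossover
decision and cut points, per offspring mutation and local search), so a
run is bit-reproducible from (sequence, config, seed).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Tuple

import numpy as np

from ._kernels import Evaluator
from .model import hp_mask, validate_hp

__all__ = ["GAConfig", "Individual", "Population", "RunResult",
           "initialize_population", "two_point_crossover", "uniform_mutation",
           "elite_reproduction", "run_ersga"]


@dataclass(frozen=True)
class GAConfig:
    """Tunables of the ERS-GA and its hill-climbing hybrid.

    Defaults are the settings used throughout the benchmark study:
    population 200, two-point crossover at rate 0.8, uniform per-gene
    mutation at rate 0.4, 200 generations, 30 repeated runs.
    """

    population_size: int = 200
    crossover_rate: float = 0.8
    mutation_rate: float = 0.4
    max_generations: int = 200
    seed: int = 0
    penalty_per_collision: Optional[int] = None  # None -> 4n
    runs: int = 30
    local_search: bool = False
    ls1_passes: int = 1
    ls2_trials_per_offspring: int = 1
    ls2_scan_all: bool = False
    parent_pool: str = "whole"  # or "bottom_half"
    mutation_scope: str = "chromosome"  # or "gene"

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError("population_size must be a positive even integer")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if self.parent_pool not in ("bottom_half", "whole"):
            raise ValueError(f"unknown parent_pool {self.parent_pool!r}")
        if self.mutation_scope not in ("gene", "chromosome"):
            raise ValueError(f"unknown mutation_scope {self.mutation_scope!r}")

    def with_(self, **kw) -> "GAConfig":
        return replace(self, **kw)


@dataclass
class Individual:
    """A chromosome with its cached evaluation."""

    folds: np.ndarray
    fitness: int
    contacts: int
    collisions: int

    @property
    def feasible(self) -> bool:
        return self.collisions == 0


Population = List[Individual]  # kept sorted ascending by fitness


@dataclass
class RunResult:
    """Outcome of one seeded run.

    ``best_conf``/``best_energy`` are the best *feasible* conformation
    ever seen; ``feasible`` is False in the pathological case that no
    self-avoiding chromosome ever appeared.
    """

    best_conf: Optional[np.ndarray]
    best_energy: Optional[int]
    feasible: bool
    generation_log: List[Tuple[int, float]] = field(repr=False, default_factory=list)
    seed: int = 0
    generations_run: int = 0
    wall_time: float = 0.0


def _evaluate_new(ev: Evaluator, folds: np.ndarray) -> Individual:
    fit, contacts, collisions = ev.evaluate(folds)
    return Individual(folds, int(fit), int(contacts), int(collisions))


def _sorted(pop: Population) -> Population:
    return sorted(pop, key=lambda ind: ind.fitness)  # stable: ties keep order


def initialize_population(
    seq: str, cfg: GAConfig, rng: np.random.Generator, ev: Optional[Evaluator] = None
) -> Population:
    """Uniform random chromosomes, evaluated and sorted best-first."""
    validate_hp(seq)
    n = len(seq)
    if n < 2:
        raise ValueError("sequence must have at least 2 residues")
    if ev is None:
        ev = Evaluator(hp_mask(seq), penalty=cfg.penalty_per_collision)
    genes = rng.integers(0, 6, size=(cfg.population_size, n - 1), dtype=np.int64)
    return _sorted([_evaluate_new(ev, genes[i].copy()) for i in range(cfg.population_size)])


def two_point_crossover(
    a: np.ndarray,
    b: np.ndarray,
    rng: np.random.Generator,
    cuts: Optional[Tuple[int, int]] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Exchange the segment between two uniform cut points.

    Cut points p <= q are drawn uniformly on 0..len (or taken from
    ``cuts``); p == q degenerates to cloning, which is permitted.
    """
    if a.shape[0] != b.shape[0]:
        raise ValueError("parents must have equal length")
    m = a.shape[0]
    if cuts is None:
        p, q = np.sort(rng.integers(0, m + 1, size=2))
    else:
        p, q = cuts
        if not 0 <= p <= q <= m:
            raise ValueError(f"cut points must satisfy 0 <= p <= q <= {m}")
    c1 = a.copy()
    c2 = b.copy()
    c1[p:q] = b[p:q]
    c2[p:q] = a[p:q]
    return c1, c2


def uniform_mutation(
    folds: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    scope: str = "gene",
) -> np.ndarray:
    """Replace genes by a uniformly random *different* direction.

    With ``scope='gene'`` every gene mutates independently with
    probability ``rate``; with ``scope='chromosome'`` the whole
    chromosome mutates one random gene with probability ``rate``.
    """
    m = folds.shape[0]
    out = folds.copy()
    if scope == "gene":
        mask = rng.random(m) < rate
        offsets = rng.integers(1, 6, size=m)
        out[mask] = (out[mask] + offsets[mask]) % 6
    elif scope == "chromosome":
        if rng.random() < rate:
            pos = rng.integers(0, m)
            out[pos] = (out[pos] + rng.integers(1, 6)) % 6
    else:
        raise ValueError(f"unknown mutation scope {scope!r}")
    return out


Refiner = Callable[[Individual], Individual]


def elite_reproduction(
    pop: Population,
    cfg: GAConfig,
    rng: np.random.Generator,
    ev: Evaluator,
    refine: Optional[Refiner] = None,
) -> Population:
    """One generation: keep the top half, breed the bottom half.

    Parents are paired by a random shuffle without replacement (from the
    bottom half by default, or from the whole population with
    ``parent_pool='whole'``); each pair crosses over with probability
    ``crossover_rate`` (otherwise clones), every offspring is mutated,
    optionally refined by local search, and evaluated. The union of the
    elite and the offspring is re-sorted.
    """
    size = cfg.population_size
    if len(pop) != size:
        raise ValueError(f"population has {len(pop)} members, expected {size}")
    half = size // 2
    elite = pop[:half]

    pool = pop if cfg.parent_pool == "whole" else pop[half:]
    order = rng.permutation(len(pool))

    offspring: Population = []
    i = 0
    while len(offspring) < half:
        if i + 1 < len(order):
            pa = pool[order[i]].folds
            pb = pool[order[i + 1]].folds
            i += 2
            if rng.random() < cfg.crossover_rate:
                c1, c2 = two_point_crossover(pa, pb, rng)
            else:
                c1, c2 = pa.copy(), pb.copy()
            children = [c1, c2]
        else:  # odd pool tail: clone the leftover parent
            children = [pool[order[i]].folds.copy()]
            i = 0
            order = rng.permutation(len(pool))
        for child in children:
            if len(offspring) >= half:
                break
            child = uniform_mutation(child, cfg.mutation_rate, rng, cfg.mutation_scope)
            ind = _evaluate_new(ev, child)
            if refine is not None:
                ind = refine(ind)
            offspring.append(ind)

    return _sorted(elite + offspring)


def run_ga(
    seq: str,
    cfg: GAConfig,
    refine_factory: Optional[Callable[[Evaluator, np.random.Generator], Refiner]] = None,
) -> RunResult:
    """Shared generation loop for ERS-GA and its local-search hybrid."""
    validate_hp(seq)
    t0 = time.perf_counter()
    rng = np.random.default_rng(cfg.seed)
    ev = Evaluator(hp_mask(seq), penalty=cfg.penalty_per_collision)
    refine = refine_factory(ev, rng) if refine_factory is not None else None

    pop = initialize_population(seq, cfg, rng, ev)
    best: Optional[Individual] = None

    def track(p: Population) -> None:
        nonlocal best
        for ind in p:
            if ind.feasible and (best is None or ind.fitness < best.fitness):
                best = ind

    track(pop)
    log: List[Tuple[int, float]] = [
        (pop[0].fitness, float(np.mean([m.fitness for m in pop])))
    ]
    gens = 0
    for _ in range(cfg.max_generations):
        pop = elite_reproduction(pop, cfg, rng, ev, refine)
        track(pop)
        log.append((pop[0].fitness, float(np.mean([m.fitness for m in pop]))))
        gens += 1

    wall = time.perf_counter() - t0
    if best is None:
        return RunResult(None, None, False, log, cfg.seed, gens, wall)
    return RunResult(best.folds.copy(), -best.contacts, True, log, cfg.seed, gens, wall)


def run_ersga(seq: str, cfg: GAConfig) -> RunResult:
    """Run the plain ERS-GA (no local search) once."""
    return run_ga(seq, cfg, refine_factory=None)
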