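"""ERS-GA operators: initialization, crossover, mutation, elitism, runs."""

import numpy as np
import pytest
from scipy import stats

from trihp._kernels import Evaluator
from trihp.ga import (
    GAConfig,
    elite_reproduction,
    initialize_population,
    run_ersga,
    two_point_crossover,
    uniform_mutation,
)
from trihp.model import decode, hp_mask, is_self_avoiding


class TestGAConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"population_size": 7},
            {"population_size": 0},
            {"crossover_rate": 1.5},
            {"mutation_rate": -0.1},
            {"max_generations": 0},
            {"parent_pool": "elite"},
            {"mutation_scope": "locus"},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            GAConfig(**kw)

    def test_with_returns_modified_copy(self):
        cfg = GAConfig()
        assert cfg.with_(seed=7).seed == 7
        assert cfg.seed == 0  # frozen original


class TestInitialization:
    def test_two_residue_chains_all_score_zero(self, rng):
        pop = initialize_population("HP", GAConfig(population_size=4, seed=0), rng)
        assert len(pop) == 4
        assert all(ind.fitness == 0 for ind in pop)
        assert all(ind.folds.shape == (1,) for ind in pop)

    def test_seed_determinism(self):
        cfg = GAConfig(population_size=10)
        a = initialize_population("HPHPH", cfg, np.random.default_rng(3))
        b = initialize_population("HPHPH", cfg, np.random.default_rng(3))
        assert all((x.folds == y.folds).all() for x, y in zip(a, b))

    def test_population_sorted_best_first(self, rng):
        pop = initialize_population("HPHHPHHP", GAConfig(population_size=50), rng)
        fits = [ind.fitness for ind in pop]
        assert fits == sorted(fits)

    def test_single_residue_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            initialize_population("H", GAConfig(), rng)

    def test_gene_marginals_uniform(self, rng):
        genes = np.concatenate(
            [ind.folds for ind in
             initialize_population("H" * 10, GAConfig(population_size=10000), rng)]
        )
        counts = np.bincount(genes, minlength=6)
        assert stats.chisquare(counts).pvalue > 0.01


class TestCrossover:
    def test_identical_parents_clone(self, rng):
        a = np.array([0, 1, 2, 3], dtype=np.int64)
        c1, c2 = two_point_crossover(a, a.copy(), rng)
        assert (c1 == a).all() and (c2 == a).all()

    def test_splice_with_fixed_cuts(self, rng):
        a = np.zeros(4, dtype=np.int64)  # RRRR
        b = np.full(4, 3, dtype=np.int64)  # LLLL
        c1, c2 = two_point_crossover(a, b, rng, cuts=(1, 3))
        assert c1.tolist() == [0, 3, 3, 0]
        assert c2.tolist() == [3, 0, 0, 3]

    def test_locus_multisets_conserved(self, rng):
        for _ in range(20):
            a = rng.integers(0, 6, 9, dtype=np.int64)
            b = rng.integers(0, 6, 9, dtype=np.int64)
            c1, c2 = two_point_crossover(a, b, rng)
            for locus in range(9):
                assert sorted([c1[locus], c2[locus]]) == sorted([a[locus], b[locus]])

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="equal length"):
            two_point_crossover(np.zeros(3, np.int64), np.zeros(4, np.int64), rng)


class TestMutation:
    def test_rate_zero_is_identity(self, rng):
        arr = rng.integers(0, 6, 12, dtype=np.int64)
        assert (uniform_mutation(arr, 0.0, rng) == arr).all()

    def test_rate_one_single_gene_always_changes(self, rng):
        arr = np.array([2], dtype=np.int64)
        for _ in range(50):
            assert uniform_mutation(arr, 1.0, rng)[0] != 2

    def test_per_gene_flip_frequency(self, rng):
        arr = np.zeros(20, dtype=np.int64)
        flips = sum(
            int((uniform_mutation(arr, 0.4, rng) != arr).sum()) for _ in range(10000)
        )
        assert flips / 200000 == pytest.approx(0.4, abs=0.02)

    def test_chromosome_scope_changes_at_most_one_gene(self, rng):
        arr = np.zeros(15, dtype=np.int64)
        changed = [
            int((uniform_mutation(arr, 0.4, rng, scope="chromosome") != arr).sum())
            for _ in range(2000)
        ]
        assert set(changed) <= {0, 1}
        assert sum(changed) / 2000 == pytest.approx(0.4, abs=0.05)


class TestEliteReproduction:
    def _pop(self, seq, cfg, seed):
        ev = Evaluator(hp_mask(seq))
        return initialize_population(seq, cfg, np.random.default_rng(seed), ev), ev

    def test_zero_rates_copy_population(self, rng):
        cfg = GAConfig(population_size=8, crossover_rate=0.0, mutation_rate=0.0,
                       parent_pool="bottom_half")
        pop, ev = self._pop("HPHHPH", cfg, 5)
        nxt = elite_reproduction(pop, cfg, rng, ev)
        assert sorted(tuple(i.folds) for i in nxt) == sorted(tuple(i.folds) for i in pop)

    def test_top_half_survives_verbatim(self, rng):
        cfg = GAConfig(population_size=4)
        pop, ev = self._pop("HPHHPHPH", cfg, 5)
        nxt = elite_reproduction(pop, cfg, rng, ev)
        surviving = {tuple(i.folds) for i in nxt}
        for elite in pop[:2]:
            assert tuple(elite.folds) in surviving

    def test_best_never_worsens(self, rng):
        cfg = GAConfig(population_size=20)
        pop, ev = self._pop("HHPHHPPHHP", cfg, 5)
        for _ in range(30):
            nxt = elite_reproduction(pop, cfg, rng, ev)
            assert nxt[0].fitness <= pop[0].fitness
            pop = nxt

    def test_wrong_size_rejected(self, rng):
        cfg = GAConfig(population_size=8)
        pop, ev = self._pop("HPHHPH", cfg, 5)
        with pytest.raises(ValueError, match="population"):
            elite_reproduction(pop[:6], cfg, rng, ev)


class TestRunErsga:
    def test_determinism_gene_for_gene(self):
        cfg = GAConfig(population_size=20, max_generations=30, seed=11)
        r1 = run_ersga("HPHHPHHPH", cfg)
        r2 = run_ersga("HPHHPHHPH", cfg)
        assert r1.best_energy == r2.best_energy
        assert (r1.best_conf == r2.best_conf).all()
        assert r1.generation_log == r2.generation_log

    def test_best_trace_monotone_and_result_feasible(self):
        cfg = GAConfig(population_size=30, max_generations=50, seed=2)
        res = run_ersga("HHPPHHPHPHHH", cfg)
        bests = [b for b, _ in res.generation_log]
        assert all(b2 <= b1 for b1, b2 in zip(bests, bests[1:]))  # non-increasing
        assert res.feasible
        assert is_self_avoiding(decode(res.best_conf))

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_hhhh_always_reaches_ground_state(self, seed):
        res = run_ersga("HHHH", GAConfig(seed=seed))
        assert res.best_energy == -2

    def test_all_p_best_zero(self):
        res = run_ersga("PPPPPP", GAConfig(population_size=20, max_generations=10, seed=0))
        assert res.best_energy == 0
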