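"""Binary ant lion optimizer: operators and the full loop."""

import numpy as np
import pytest
from scipy import stats

from kpdclear import ALOParams, build_compatibility_matrix, enumerate_exchanges, run_alo
from kpdclear.alo import (
    ant_update,
    catch_and_rebuild,
    flip_mutation,
    gvp_binarize,
    initialize_population,
    roulette_select,
)
from kpdclear.objective import ExchangeEvaluator

from conftest import oracle_optimum, random_pool


class TestGVP:
    def test_strictly_decreasing_maps_to_zeros(self):
        np.testing.assert_array_equal(gvp_binarize([3.0, 2.0, 1.0]), [0, 0, 0])

    def test_strictly_increasing(self):
        np.testing.assert_array_equal(gvp_binarize([1.0, 2.0, 3.0]), [1, 1, 0])

    def test_single_dimension_is_zero(self):
        np.testing.assert_array_equal(gvp_binarize([0.7]), [0])

    def test_ties_break_toward_lower_index(self):
        # equal values: permutation is [1, 2, 3] -> all zeros
        np.testing.assert_array_equal(gvp_binarize([0.5, 0.5, 0.5]), [0, 0, 0])

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            gvp_binarize([])

    def test_output_is_binary_for_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            y = gvp_binarize(rng.random(int(rng.integers(1, 30))))
            assert set(np.unique(y)) <= {0, 1}


class TestRoulette:
    def test_single_individual(self):
        rng = np.random.default_rng(0)
        assert roulette_select(np.array([-3.0]), rng) == 0

    def test_uniform_when_fitness_equal(self):
        rng = np.random.default_rng(1)
        draws = np.array([roulette_select(np.zeros(4), rng) for _ in range(10000)])
        counts = np.bincount(draws, minlength=4)
        assert stats.chisquare(counts).pvalue > 1e-4

    def test_negative_fitness_shift(self):
        """Frequencies follow the shifted weights s = f - min(f) + eps: for
        fitness [5, -45] that is essentially [50, 0] -> index 0 nearly
        always, index 1 with vanishing probability."""
        rng = np.random.default_rng(2)
        n = 10000
        draws = sum(roulette_select(np.array([5.0, -45.0]), rng) for _ in range(n))
        assert draws < 10  # expected ~ n * eps/50 ~ 0

    def test_proportional_frequencies(self):
        rng = np.random.default_rng(3)
        f = np.array([1.0, 3.0])       # shifted weights [eps, 2]
        n = 10000
        ones = sum(roulette_select(f, rng) for _ in range(n))
        assert ones > n - 3 * np.sqrt(n)


class TestBitOperators:
    def test_flip_changes_exactly_one_bit(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            x = (rng.random(12) < 0.5).astype(np.int8)
            y = flip_mutation(x, rng)
            assert int(np.sum(x != y)) == 1

    def test_flip_is_involution_at_same_index(self):
        x = np.array([0, 1, 0], dtype=np.int8)
        y = x.copy()
        y[1] ^= 1
        np.testing.assert_array_equal(y, [0, 0, 0])
        y[1] ^= 1
        np.testing.assert_array_equal(y, x)

    def test_crossover_identical_parents(self):
        rng = np.random.default_rng(5)
        x = np.array([1, 0, 1, 1], dtype=np.int8)
        np.testing.assert_array_equal(ant_update(x, x, rng), x)

    def test_crossover_boundaries(self):
        class AllLow:
            def random(self, n):
                return np.zeros(n)

        class AllHigh:
            def random(self, n):
                return np.ones(n)

        ra = np.array([1, 1, 0], dtype=np.int8)
        re = np.array([0, 0, 1], dtype=np.int8)
        np.testing.assert_array_equal(ant_update(ra, re, AllLow()), re)
        np.testing.assert_array_equal(ant_update(ra, re, AllHigh()), ra)

    def test_crossover_dimension_mismatch(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            ant_update(np.zeros(3), np.zeros(4), rng)


class TestCatchAndRebuild:
    def _state(self, ant_f, antlion_f, worked_example):
        ev = ExchangeEvaluator(worked_example)
        st_ = initialize_population(ev, ALOParams(n_ants=1, n_antlions=1), 50.0,
                                    np.random.default_rng(0))
        st_.ant_fitness[0] = ant_f
        st_.antlion_fitness[0] = antlion_f
        st_.ants[0] = [1, 1, 1, 1]
        st_.antlions[0] = [0, 0, 0, 0]
        return st_

    def test_fitter_ant_replaces_antlion(self, worked_example):
        st_ = self._state(5.0, 3.0, worked_example)
        catch_and_rebuild(st_, 0, 0)
        np.testing.assert_array_equal(st_.antlions[0], [1, 1, 1, 1])
        assert st_.antlion_fitness[0] == 5.0

    def test_equal_fitness_leaves_antlion(self, worked_example):
        st_ = self._state(3.0, 3.0, worked_example)
        catch_and_rebuild(st_, 0, 0)
        np.testing.assert_array_equal(st_.antlions[0], [0, 0, 0, 0])

    def test_weaker_ant_leaves_antlion(self, worked_example):
        st_ = self._state(-44.0, 0.0, worked_example)
        catch_and_rebuild(st_, 0, 0)
        assert st_.antlion_fitness[0] == 0.0


class TestInitialization:
    def test_deterministic_per_seed(self, worked_example):
        ev = ExchangeEvaluator(worked_example)
        params = ALOParams(n_ants=10, n_antlions=10)
        a = initialize_population(ev, params, 50.0, np.random.default_rng(3))
        b = initialize_population(ev, params, 50.0, np.random.default_rng(3))
        np.testing.assert_array_equal(a.ants, b.ants)
        np.testing.assert_array_equal(a.antlions, b.antlions)
        assert a.elite_fitness == b.elite_fitness

    def test_elite_is_best_antlion(self, worked_example):
        ev = ExchangeEvaluator(worked_example)
        st_ = initialize_population(ev, ALOParams(n_ants=8, n_antlions=8), 50.0,
                                    np.random.default_rng(4))
        assert st_.elite_fitness == st_.antlion_fitness.max()
        assert (st_.antlion_fitness <= st_.elite_fitness).all()


class TestRun:
    PARAMS = dict(n_ants=20, n_antlions=20, iterations=25, penalty_lambda=50.0)

    def test_finds_global_optimum_on_worked_example(self, worked_example):
        for seed in range(5):
            res = run_alo(worked_example, ALOParams(seed=seed, **self.PARAMS))
            assert res.breakdown.fitness == 5.0

    def test_trace_is_non_decreasing(self, worked_example):
        res = run_alo(worked_example, ALOParams(seed=0, **self.PARAMS))
        assert (np.diff(res.trace) >= 0).all()

    def test_seeded_determinism(self, worked_example):
        a = run_alo(worked_example, ALOParams(seed=11, **self.PARAMS))
        b = run_alo(worked_example, ALOParams(seed=11, **self.PARAMS))
        np.testing.assert_array_equal(a.selection, b.selection)
        np.testing.assert_array_equal(a.trace, b.trace)

    def test_positions_stay_binary(self, worked_example):
        res = run_alo(worked_example, ALOParams(seed=2, **self.PARAMS))
        assert set(np.unique(res.selection)) <= {0, 1}

    def test_more_generations_never_hurt(self):
        rng = np.random.default_rng(7)
        m = enumerate_exchanges(build_compatibility_matrix(random_pool(rng, 9, 2, 0.3)), 3)
        short = run_alo(m, ALOParams(n_ants=15, n_antlions=15, iterations=1, seed=3))
        long = run_alo(m, ALOParams(n_ants=15, n_antlions=15, iterations=30, seed=3))
        assert long.breakdown.fitness >= short.trace[0]

    def test_empty_exchange_set(self):
        from kpdclear.enumeration import ExchangeSet

        res = run_alo(ExchangeSet([], k=3), ALOParams(iterations=5))
        assert res.selection.size == 0 and res.breakdown.fitness == 0.0

    def test_reported_fitness_is_max_ever_trace_value(self, worked_example):
        res = run_alo(worked_example, ALOParams(seed=5, **self.PARAMS))
        assert res.breakdown.fitness == res.trace.max() == res.trace[-1]


def test_small_instances_reach_brute_force_optimum():
    """On small exchange sets the optimizer plus greedy post-processing
    recovers the exact optimum for nearly every seed."""
    from kpdclear.objective import ExchangeEvaluator, default_lambda
    from kpdclear.postprocess import postprocess

    rng = np.random.default_rng(12)
    hits = total = 0
    instances = 0
    while instances < 4:
        m = enumerate_exchanges(build_compatibility_matrix(random_pool(rng, 8, 2, 0.3)), 3)
        if not 1 <= len(m) <= 10:
            continue
        instances += 1
        target = oracle_optimum(m)
        ev = ExchangeEvaluator(m)
        for seed in range(5):
            res = run_alo(m, ALOParams(n_ants=30, n_antlions=30, iterations=40, seed=seed))
            sel = res.selection
            if not res.breakdown.feasible:
                sel = np.zeros(len(m), dtype=np.int8)
            sel = postprocess(sel, m)
            total += 1
            hits += ev.breakdown(sel, default_lambda(m)).utility == target
    assert hits / total >= 0.95
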