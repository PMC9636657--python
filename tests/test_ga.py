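import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import callusopt as co
from callusopt.ga import (
    GAConfig,
    GENE_RANGES,
    chromosome_of,
    crowding_distance,
    decode_chromosome,
    mutate,
    non_dominated_sort,
    single_point_crossover,
)

chromosomes = st.tuples(*(st.integers(1, r) for r in GENE_RANGES))


class _StubModel:
    """Deterministic pseudo-random surrogate used as GA fitness."""

    def __init__(self, seed, n_out=1):
        self.seed = seed

    def predict(self, X):
        X = np.atleast_2d(X)
        # hash-like but smooth-free deterministic values per condition
        rng_vals = np.sin(X @ np.arange(1, X.shape[1] + 1) * (self.seed + 1) * 0.7919)
        return 50.0 + 50.0 * rng_vals


class TestCrossover:
    def test_suffix_swap_at_cut_two(self):
        c1, c2 = single_point_crossover((6, 4, 1, 1), (1, 1, 3, 2), cut=2)
        assert (c1, c2) == ((6, 4, 3, 2), (1, 1, 1, 1))

    def test_identical_parents_give_identical_children(self):
        for cut in (1, 2, 3):
            assert single_point_crossover((2, 3, 1, 2), (2, 3, 1, 2), cut) == (
                (2, 3, 1, 2),
                (2, 3, 1, 2),
            )

    def test_not_applied_returns_parents(self):
        a, b = (6, 4, 1, 1), (1, 1, 3, 2)
        assert single_point_crossover(a, b, 2, apply=False) == (a, b)

    @pytest.mark.parametrize("cut", [0, 4, -1])
    def test_invalid_cut_rejected(self, cut):
        with pytest.raises(ValueError):
            single_point_crossover((1, 1, 1, 1), (2, 2, 2, 2), cut)

    @given(a=chromosomes, b=chromosomes, cut=st.integers(1, 3))
    @settings(max_examples=250, deadline=None)
    def test_allele_conservation_per_position(self, a, b, cut):
        c1, c2 = single_point_crossover(a, b, cut)
        for k in range(4):
            assert sorted((c1[k], c2[k])) == sorted((a[k], b[k]))


class TestMutation:
    def test_zero_rate_is_identity(self):
        rng = np.random.default_rng(0)
        assert mutate((3, 2, 1, 2), 0.0, rng) == (3, 2, 1, 2)

    def test_full_rate_stays_in_range(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            c = mutate((1, 1, 1, 1), 1.0, rng)
            assert all(1 <= g <= r for g, r in zip(c, GENE_RANGES))

    def test_empirical_change_rate_matches_binomial_expectation(self):
        rng = np.random.default_rng(123)
        p = 0.2
        n = 100_000
        base = (4, 2, 2, 1)
        changes = np.zeros(4)
        for _ in range(n):
            c = mutate(base, p, rng)
            changes += [c[k] != base[k] for k in range(4)]
        for k, r in enumerate(GENE_RANGES):
            expect = p * (1 - 1 / r)
            se = np.sqrt(expect * (1 - expect) / n)
            assert abs(changes[k] / n - expect) < 3 * se


class TestNonDominatedSort:
    def test_single_point_is_rank_zero(self):
        assert non_dominated_sort([[1.0, 1.0]]).tolist() == [0]

    def test_strict_domination(self):
        assert non_dominated_sort([[1, 1], [2, 2]]).tolist() == [1, 0]

    def test_equal_points_share_a_rank(self):
        assert non_dominated_sort([[1, 1], [1, 1], [0, 0]]).tolist() == [0, 0, 1]

    def test_matches_pairwise_oracle_on_random_point_sets(self):
        def oracle_ranks(pts):
            pts = np.asarray(pts, float)
            n = len(pts)
            ranks = np.full(n, -1)
            alive = list(range(n))
            r = 0
            while alive:
                front = []
                for i in alive:
                    dominated = any(
                        (pts[j] >= pts[i]).all() and (pts[j] > pts[i]).any()
                        for j in alive
                    )
                    if not dominated:
                        front.append(i)
                for i in front:
                    ranks[i] = r
                alive = [i for i in alive if i not in front]
                r += 1
            return ranks

        rng = np.random.default_rng(5)
        for _ in range(10):
            pts = rng.normal(size=(50, 2))
            np.testing.assert_array_equal(non_dominated_sort(pts), oracle_ranks(pts))

    def test_crowding_boundaries_are_infinite(self):
        pts = np.array([[0, 3.0], [1, 2.0], [2, 1.0], [3, 0.0]])
        d = crowding_distance(pts)
        assert np.isinf(d[0]) and np.isinf(d[3])
        assert np.isfinite(d[1:3]).all()


class TestOptimize:
    def test_chromosome_decode_round_trip(self):
        for t in range(1, 9):
            c = (t, 2, 3, 1)
            assert chromosome_of(decode_chromosome(c)) == c

    def test_ga_matches_exhaustive_enumeration_for_random_surrogates(self):
        for seed in range(20):
            model = _StubModel(seed)
            oracle = co.brute_force_optimum(model, None, "percentage")
            res = co.optimize(model, None, GAConfig(seed=seed, generations=300))
            assert res.best_chromosome == oracle.best_chromosome
            assert res.best_objectives == oracle.best_objectives

    def test_elitist_best_fitness_history_is_monotone(self):
        res = co.optimize(_StubModel(3), None, GAConfig(seed=9, generations=200))
        h = np.array(res.history)
        assert len(h) == 200
        assert np.all(np.diff(h) >= 0)

    def test_constant_fitness_ties_break_lexicographically(self):
        class Const:
            def predict(self, X):
                return np.full(len(np.atleast_2d(X)), 7.0)

        res = co.brute_force_optimum(Const(), None, "percentage")
        assert res.best_chromosome == (1, 1, 1, 1)

    def test_multi_objective_front_is_subset_of_exact_front(self):
        pct, speed = _StubModel(1), _StubModel(2)
        exact = co.brute_force_optimum(pct, speed, "both")
        res = co.optimize(pct, speed, GAConfig(seed=4, generations=300, objectives="both"))
        exact_set = {c for c, _, _ in exact.front}
        got = {c for c, _, _ in res.front}
        assert got <= exact_set
        # front members are mutually non-dominated
        pts = np.array([[p, s] for _, p, s in res.front])
        assert (non_dominated_sort(pts) == 0).all()
        assert res.selected_solution == exact.selected_solution

    def test_seeded_runs_are_reproducible(self):
        model = _StubModel(5)
        a = co.optimize(model, None, GAConfig(seed=11, generations=100))
        b = co.optimize(model, None, GAConfig(seed=11, generations=100))
        assert a.best_chromosome == b.best_chromosome
        assert a.history == b.history

    def test_missing_models_rejected(self):
        with pytest.raises(ValueError):
            co.optimize(None, None, GAConfig(objectives="percentage"))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GAConfig(population_size=1)
        with pytest.raises(ValueError):
            GAConfig(objectives="area")
        with pytest.raises(ValueError):
            GAConfig(mutation_prob=1.5)
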