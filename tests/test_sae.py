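"""Self-adaptive differential evolution: operators, memory, full runs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saegbls import (
    BLSArchitecture,
    NeighborGraphSpec,
    ParameterError,
    Population,
    SaEConfig,
    StrategyMemory,
    ValidationError,
    crossover,
    evaluate_individual,
    initialize_population,
    mutate,
    run_sae,
    select_strategy,
    select_survivor,
    update_probabilities,
)
from saegbls.graphs import build_graph_operators


def _pop(values, fitness=None):
    values = np.asarray(values, dtype=float)
    n = len(values)
    fit = np.arange(n, dtype=float) if fitness is None else np.asarray(fitness, float)
    return Population(values, fit, np.ones(n))


class TestInitialization:
    def test_population_inside_bounds(self):
        cfg = SaEConfig(population_size=10, bounds=(-1.0, 1.0), seed=0)
        pop = initialize_population(cfg, 20)
        assert pop.individuals.shape == (10, 20)
        assert np.all(pop.individuals >= -1.0) and np.all(pop.individuals <= 1.0)

    def test_degenerate_bounds_collapse_population(self):
        cfg = SaEConfig(population_size=6, bounds=(0.3, 0.3), seed=0)
        pop = initialize_population(cfg, 5)
        np.testing.assert_allclose(pop.individuals, 0.3)

    def test_sample_mean_near_interval_midpoint(self):
        cfg = SaEConfig(population_size=50, bounds=(-1.0, 1.0), seed=42)
        pop = initialize_population(cfg, 100)
        assert np.all(np.abs(pop.individuals.mean(axis=0)) < 0.35)
        assert abs(pop.individuals.mean()) < 0.1

    def test_too_small_population_rejected(self):
        with pytest.raises(ParameterError):
            initialize_population(SaEConfig(population_size=5), 10)


class TestStrategySelection:
    def test_degenerate_distribution_always_picks_strategy_one(self, rng):
        for _ in range(20):
            assert select_strategy([1.0, 0.0, 0.0, 0.0], rng) == 1

    def test_uniform_frequencies_during_learning_period(self):
        rng = np.random.default_rng(0)
        draws = np.array(
            [select_strategy([0.25] * 4, rng) for _ in range(10_000)]
        )
        freq = np.bincount(draws, minlength=5)[1:] / 10_000
        assert np.all(np.abs(freq - 0.25) < 0.02)

    def test_same_seed_same_draw_sequence(self):
        a = [select_strategy([0.25] * 4, np.random.default_rng(5)) for _ in range(1)]
        s1 = [select_strategy([0.1, 0.2, 0.3, 0.4], np.random.default_rng(7))]
        s2 = [select_strategy([0.1, 0.2, 0.3, 0.4], np.random.default_rng(7))]
        assert s1 == s2 and a[0] in (1, 2, 3, 4)


class TestProbabilityUpdate:
    def test_uniform_within_learning_period(self):
        mem = StrategyMemory(learning_period=3, epsilon=0.01)
        mem.record_generation(np.array([5, 0, 0, 0]), np.array([0, 5, 5, 5]))
        np.testing.assert_allclose(update_probabilities(mem, 2), 0.25)

    def test_equal_success_ratios_give_equal_probabilities(self):
        mem = StrategyMemory(learning_period=1, epsilon=0.01)
        mem.record_generation(np.array([2, 2, 2, 2]), np.array([3, 3, 3, 3]))
        np.testing.assert_allclose(update_probabilities(mem, 5), 0.25)

    def test_hand_computed_success_ratio_example(self):
        # ns=[3,1,0,0], nf=[1,1,2,2], eps=0.01 -> s=[0.76,0.51,0.01,0.01]
        mem = StrategyMemory(learning_period=1, epsilon=0.01)
        mem.record_generation(np.array([3, 1, 0, 0]), np.array([1, 1, 2, 2]))
        p = update_probabilities(mem, 2)
        np.testing.assert_allclose(
            p, [0.76 / 1.29, 0.51 / 1.29, 0.01 / 1.29, 0.01 / 1.29], atol=1e-12
        )
        np.testing.assert_allclose(p[:2], [0.5891, 0.3953], atol=5e-5)

    def test_probabilities_sum_to_one_and_stay_positive(self):
        mem = StrategyMemory(learning_period=2, epsilon=0.01)
        mem.record_generation(np.array([4, 0, 0, 0]), np.array([0, 4, 4, 4]))
        mem.record_generation(np.array([4, 0, 0, 0]), np.array([0, 4, 4, 4]))
        p = update_probabilities(mem, 10)
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all(p > 0)


class TestMutation:
    def test_strategy1_with_zero_scale_copies_a_parent(self, rng):
        pop = _pop(rng.normal(size=(8, 4)))
        v = mutate(pop, 0, 1, F=0.0, K=0.5, rng=rng)
        assert any(np.array_equal(v, row) for row in pop.individuals[1:])

    def test_strategy4_with_zero_factors_is_identity(self, rng):
        pop = _pop(rng.normal(size=(8, 4)))
        v = mutate(pop, 2, 4, F=0.0, K=0.0, rng=rng)
        np.testing.assert_array_equal(v, pop.individuals[2])

    def test_strategy1_hand_arithmetic_via_stream_replay(self):
        pop = _pop(np.random.default_rng(3).normal(size=(6, 2)))
        rng1 = np.random.default_rng(17)
        v = mutate(pop, 0, 1, F=0.5, K=0.0, rng=rng1)
        rng2 = np.random.default_rng(17)
        r = rng2.choice(np.delete(np.arange(6), 0), size=3, replace=False)
        t = pop.individuals
        np.testing.assert_allclose(v, t[r[0]] + 0.5 * (t[r[1]] - t[r[2]]))

    def test_strategy2_uses_current_best(self):
        inds = np.zeros((6, 2))
        inds[4] = [5.0, 5.0]  # best individual (lowest fitness below)
        fitness = np.array([1.0, 1.0, 1.0, 1.0, 0.0, 1.0])
        pop = _pop(inds, fitness)
        rng = np.random.default_rng(0)
        v = mutate(pop, 0, 2, F=1.0, K=0.0, rng=rng)
        # all non-best rows are zero, so v = F*(best - t_r1) + ... = best or 0
        assert np.array_equal(v, [5.0, 5.0]) or np.array_equal(v, [0.0, 0.0])

    def test_mutant_clipped_to_bounds(self, rng):
        pop = _pop(np.full((6, 3), 0.9))
        pop.individuals[1] = 2.0
        v = mutate(pop, 0, 1, F=2.0, K=0.0, rng=rng, bounds=(-1.0, 1.0))
        assert np.all(v <= 1.0) and np.all(v >= -1.0)

    def test_population_too_small_for_five_parents(self, rng):
        pop = _pop(np.zeros((5, 2)))
        with pytest.raises(ParameterError):
            mutate(pop, 0, 2, F=0.5, K=0.5, rng=rng)


class TestCrossover:
    def test_cr_zero_copies_parent_except_one_position(self, rng):
        parent = np.zeros(10)
        mutant = np.ones(10)
        u = crossover(parent, mutant, 0.0, rng)
        assert np.sum(u == 1.0) == 1

    def test_cr_near_one_copies_mutant_almost_surely(self):
        rng = np.random.default_rng(1)
        parent = np.zeros(2000)
        mutant = np.ones(2000)
        u = crossover(parent, mutant, 0.999, rng)
        assert np.mean(u) > 0.99

    def test_stream_replay_reproduces_component_rule(self):
        parent = np.arange(5.0)
        mutant = -np.arange(5.0)
        u = crossover(parent, mutant, 0.4, np.random.default_rng(23))
        rng = np.random.default_rng(23)
        j_rand = int(rng.integers(5))
        take = rng.random(5) <= 0.4
        take[j_rand] = True
        np.testing.assert_array_equal(u, np.where(take, mutant, parent))

    def test_length_mismatch_rejected(self, rng):
        from saegbls import DimensionError

        with pytest.raises(DimensionError):
            crossover(np.zeros(3), np.zeros(4), 0.5, rng)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), d=st.integers(1, 30))
    def test_trial_always_contains_a_mutant_component(self, seed, d):
        rng = np.random.default_rng(seed)
        u = crossover(np.zeros(d), np.ones(d), 0.0, rng)
        assert np.any(u == 1.0)


class TestFitness:
    def test_exact_fit_square_state_matrix_gives_zero_rmse(self):
        arch = BLSArchitecture(1, 1, 1, "tanh", "sigmoid")
        rng = np.random.default_rng(0)
        theta = rng.uniform(-1, 1, arch.dim(1))
        X = np.array([[0.3], [-0.8]])  # N = nk + m = 2 -> A square
        Y = np.array([[1.0, 0.0], [0.0, 1.0]])
        L = np.zeros((2, 2))
        rmse, _ = evaluate_individual(theta, X, Y, arch, L, 0.0, 0.0)
        assert rmse <= 1e-8

    def test_rmse_uses_root_mean_square_convention(self, rng, tiny_arch):
        """RMSE equals ||AW - Y||_F / sqrt(N*C), recomputed independently."""
        from saegbls import NodeParameterSet, build_state_matrix, solve_gbls_weights

        X = rng.normal(size=(9, 3))
        Y = (rng.integers(0, 2, size=(9, 2))).astype(float)
        L = np.eye(9) * 0.1
        theta = rng.uniform(-1, 1, tiny_arch.dim(3))
        rmse, wnorm = evaluate_individual(theta, X, Y, tiny_arch, L, 1.0, 0.1)
        params = NodeParameterSet.unflatten(theta, 3, tiny_arch)
        A = build_state_matrix(X, params)
        W = solve_gbls_weights(A, Y, L, 1.0, 0.1)
        assert rmse == pytest.approx(
            np.linalg.norm(A @ W - Y) / np.sqrt(9 * 2), abs=1e-12
        )
        assert wnorm == pytest.approx(np.linalg.norm(W), abs=1e-12)

    def test_rmse_homogeneous_in_targets(self, rng, tiny_arch):
        X = rng.normal(size=(8, 3))
        Y = rng.normal(size=(8, 2))
        L = np.zeros((8, 8))
        theta = rng.uniform(-1, 1, tiny_arch.dim(3))
        r1, _ = evaluate_individual(theta, X, Y, tiny_arch, L, 0.0, 0.5)
        r2, _ = evaluate_individual(theta, X, 3.0 * Y, tiny_arch, L, 0.0, 0.5)
        assert r2 == pytest.approx(3.0 * r1, rel=1e-10)


class TestSurvivorSelection:
    def test_clear_improvement_accepts_trial(self):
        assert select_survivor(0.50, 0.40, 1.0, 1.0, 0.01) == "trial"

    def test_near_tie_with_smaller_norm_accepts_trial(self):
        assert select_survivor(0.500, 0.499, 2.0, 1.0, 0.01) == "trial"

    def test_near_tie_with_larger_norm_keeps_parent(self):
        assert select_survivor(0.500, 0.499, 1.0, 2.0, 0.01) == "parent"

    def test_strictly_worse_trial_rejected(self):
        assert select_survivor(0.40, 0.50, 1.0, 0.1, 0.01) == "parent"


class TestFullRun:
    def _xy(self, n_per_class=15, dim=3, seed=0):
        from saegbls import synth_feature_clusters

        t = synth_feature_clusters(n_per_class, dim, 6.0, seed)
        return t.features, t.labels

    def test_zero_generations_returns_initial_best(self, tiny_arch, graph_spec):
        X, y = self._xy()
        cfg = SaEConfig(population_size=8, max_generations=0, seed=1)
        res = run_sae(cfg, X, y, tiny_arch, graph_spec)
        assert res.best_rmse == res.initial_best_rmse
        assert len(res.trace) == 1

    def test_best_rmse_trace_non_increasing_without_tolerance(
        self, tiny_arch, graph_spec
    ):
        X, y = self._xy()
        cfg = SaEConfig(
            population_size=8, max_generations=10, epsilon_select=0.0, seed=2
        )
        res = run_sae(cfg, X, y, tiny_arch, graph_spec)
        best = res.trace["best_rmse"].to_numpy()
        assert np.all(np.diff(best) <= 1e-14)

    def test_final_rmse_not_worse_than_initial_best(self, tiny_arch, graph_spec):
        X, y = self._xy()
        cfg = SaEConfig(population_size=10, max_generations=20, seed=3)
        res = run_sae(cfg, X, y, tiny_arch, graph_spec)
        assert res.best_rmse <= res.initial_best_rmse + 1e-12

    def test_success_failure_counts_sum_to_population_size(
        self, tiny_arch, graph_spec
    ):
        X, y = self._xy()
        cfg = SaEConfig(population_size=8, max_generations=4, seed=4)
        res = run_sae(cfg, X, y, tiny_arch, graph_spec)
        for ns, nf in zip(res.memory.ns, res.memory.nf):
            assert ns.sum() + nf.sum() == 8

    def test_run_bit_reproducible_under_fixed_seed(self, tiny_arch, graph_spec):
        X, y = self._xy()
        cfg = SaEConfig(population_size=8, max_generations=5, seed=9)
        r1 = run_sae(cfg, X, y, tiny_arch, graph_spec)
        r2 = run_sae(cfg, X, y, tiny_arch, graph_spec)
        np.testing.assert_array_equal(r1.best_theta, r2.best_theta)
        np.testing.assert_array_equal(
            r1.trace.to_numpy(), r2.trace.to_numpy()
        )

    def test_single_class_labels_rejected(self, tiny_arch, graph_spec):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValidationError):
            run_sae(SaEConfig(population_size=8), X, np.zeros(10), tiny_arch, graph_spec)

    def test_fitness_never_jumps_by_more_than_tolerance_factor(
        self, tiny_arch, graph_spec
    ):
        """With eps_sel > 0 a survivor's fitness can rise by at most (1+eps)."""
        X, y = self._xy()
        eps = 0.05
        cfg = SaEConfig(
            population_size=8, max_generations=8, epsilon_select=eps, seed=6
        )
        ops = build_graph_operators(X, y, graph_spec)
        res = run_sae(cfg, X, y, tiny_arch, graph_spec, graph_ops=ops)
        best = res.trace["best_rmse"].to_numpy()
        assert np.all(best[1:] <= best[:-1] * (1 + eps) + 1e-14)
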