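"""Swarm maximizers: mechanism checks and shared-contract properties."""

import numpy as np
import pytest

from swarmbo.swarm import (OPTIMIZERS, SwarmParams, _levy_steps, abc_maximize,
                           hho_maximize, maximize, pso_maximize,
                           random_maximize, sfo_maximize)

ALGOS = ["pso", "abc", "hho", "sfo"]
#: documented per-algorithm evaluation-budget constants
EVAL_BUDGET_C = {"pso": 1, "abc": 3, "hho": 2, "sfo": 2}


def sphere(X):
    return -np.sum((np.atleast_2d(X) - 0.5) ** 2, axis=1)


class TestSharedContract:
    @pytest.mark.parametrize("algo", ALGOS)
    def test_history_monotone_points_in_bounds(self, algo):
        params = SwarmParams(population=12, iterations=25, seed=3)
        r = maximize(algo, sphere, 4, params)
        assert np.all(np.diff(r.history) >= 0)
        assert r.best_value == r.history[-1]
        assert np.all((r.best_point >= 0) & (r.best_point <= 1))
        assert np.all((r.final_population >= 0) & (r.final_population <= 1))

    @pytest.mark.parametrize("algo", ALGOS)
    def test_seeded_determinism(self, algo):
        params = SwarmParams(population=10, iterations=15, seed=42)
        a = maximize(algo, sphere, 3, params)
        b = maximize(algo, sphere, 3, params)
        assert a.best_value == b.best_value
        np.testing.assert_array_equal(a.best_point, b.best_point)
        np.testing.assert_array_equal(a.history, b.history)

    @pytest.mark.parametrize("algo", ALGOS)
    def test_evaluation_budget_bound(self, algo):
        params = SwarmParams(population=10, iterations=20, seed=0, sn=5)
        r = maximize(algo, sphere, 3, params)
        pop = params.sn * 2 if algo == "abc" else params.population
        assert r.evaluations <= pop * (params.iterations + 1) * EVAL_BUDGET_C[algo]

    @pytest.mark.parametrize("algo", ALGOS)
    def test_nonfinite_objective_never_selected(self, algo):
        def f(X):
            X = np.atleast_2d(X)
            y = sphere(X)
            return np.where(X[:, 0] > 0.6, np.nan, y)
        params = SwarmParams(population=10, iterations=20, seed=1)
        r = maximize(algo, f, 2, params)
        assert np.isfinite(r.best_value)
        assert r.best_point[0] <= 0.6

    def test_unknown_optimizer_rejected(self):
        with pytest.raises(ValueError, match="unknown optimizer"):
            maximize("cmaes", sphere, 2, SwarmParams())

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SwarmParams(population=1)
        with pytest.raises(ValueError):
            SwarmParams(iterations=0)


class TestPso:
    def test_population_at_optimum_is_fixed_point(self):
        params = SwarmParams(population=5, iterations=10, seed=0, w=0.7)
        init = np.full((5, 3), 0.5)
        r = pso_maximize(sphere, 3, params, init=init)
        assert r.best_value == 0.0
        assert np.all(r.history == 0.0)

    def test_converges_on_sphere(self):
        params = SwarmParams(population=30, iterations=200, seed=0)
        r = pso_maximize(sphere, 5, params)
        assert r.best_value >= -1e-4


class TestAbc:
    def test_greedy_replacement_on_improving_move(self):
        # strictly increasing 1-D objective: any move toward 1 is kept
        def f(X):
            return np.atleast_2d(X)[:, 0]
        params = SwarmParams(population=10, iterations=30, seed=2, sn=5)
        r = abc_maximize(f, 1, params)
        assert r.best_value > 0.9

    def test_stagnating_sources_are_redrawn_by_scouts(self):
        # constant objective: no move ever improves, so every source must
        # exceed the limit and be re-initialized at least once
        calls = {"n": 0}

        def f(X):
            calls["n"] += len(np.atleast_2d(X))
            return np.zeros(len(np.atleast_2d(X)))

        params = SwarmParams(population=10, iterations=30, seed=7, sn=4, limit=3)
        r = abc_maximize(f, 2, params)
        # scouts add evaluations beyond the employed+onlooker 2*sn per round
        assert r.evaluations > 4 + 30 * 8
        assert calls["n"] == r.evaluations

    def test_converges_on_sphere(self):
        params = SwarmParams(population=30, iterations=200, seed=0, sn=15)
        r = abc_maximize(sphere, 5, params)
        assert r.best_value >= -1e-3


class TestHho:
    def test_final_iteration_has_zero_escape_energy(self):
        # with T = 1, t/T = 1 so E = 0: only exploitation branches fire and
        # every candidate is pulled toward the current best
        params = SwarmParams(population=8, iterations=1, seed=5)
        r = hho_maximize(sphere, 3, params)
        assert np.all(np.diff(r.history) >= 0)

    def test_levy_steps_heavy_tailed(self):
        rng = np.random.default_rng(0)
        steps = np.abs(_levy_steps(rng, 10**5, 1.5))
        assert np.isfinite(steps.mean())
        assert steps.max() / np.median(steps) > 10

    def test_converges_on_sphere(self):
        params = SwarmParams(population=30, iterations=200, seed=0)
        r = hho_maximize(sphere, 5, params)
        assert r.best_value >= -1e-3


class TestSfo:
    def test_attack_power_decays_monotonically(self):
        A, eps = 4.0, 0.001
        ap = [A * (1 - 2 * t * eps) for t in range(1, 201)]
        assert np.all(np.diff(ap) < 0)

    def test_final_population_sorted_best_first(self):
        params = SwarmParams(population=20, iterations=50, seed=4,
                             sailfish_fraction=0.3)
        r = sfo_maximize(sphere, 3, params)
        assert np.all(np.diff(r.final_values) <= 0)
        assert r.best_value >= r.final_values[0]

    def test_converges_on_sphere(self):
        params = SwarmParams(population=30, iterations=200, seed=0)
        r = sfo_maximize(sphere, 5, params)
        assert r.best_value >= -1e-3


class TestRandomBaseline:
    def test_finds_decent_sphere_value(self):
        params = SwarmParams(seed=0, random_samples=1000, polish_steps=50)
        r = random_maximize(sphere, 3, params)
        assert r.best_value >= -0.05
        assert np.all(np.diff(r.history) >= 0)

    def test_registered(self):
        assert set(OPTIMIZERS) == {"pso", "abc", "hho", "sfo", "random"}
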