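"""Trust-region machinery and multi-start behaviour."""

import numpy as np
import pytest

from multit1 import (
    ComponentParameters,
    InversionRecoverySeries,
    MultiStartConfig,
    ParameterBounds,
    SolverConfig,
    forward_signal,
    make_ti_grid,
    multistart_fit,
    sample_starting_points,
    solve_bounded,
)
from multit1.solver import (
    QuadraticModel,
    build_quadratic_model,
    minimize_least_squares,
    solve_subproblem_2d,
    step_quality,
    update_radius,
)


def quadratic(f0, g, hess):
    return build_quadratic_model(f0, np.asarray(g, float), np.asarray(hess, float))


class TestQuadraticModel:
    def test_value_at_zero_is_f0(self):
        m = quadratic(3.5, [1.0, -2.0], np.eye(2))
        assert m(np.zeros(2)) == pytest.approx(3.5)

    def test_exact_on_quadratic_function(self, rng):
        # m(s) == f(x+s) when H is the true Hessian of a quadratic f
        a = rng.normal(size=(3, 3))
        hess = a @ a.T + np.eye(3)
        g = rng.normal(size=3)
        f = lambda s: 1.0 + g @ s + 0.5 * s @ hess @ s
        m = quadratic(1.0, g, hess)
        for _ in range(5):
            s = rng.normal(size=3)
            assert m(s) == pytest.approx(f(s), rel=1e-12)

    def test_linear_case(self):
        m = quadratic(2.0, [3.0], np.zeros((1, 1)))
        assert m(np.array([4.0])) == pytest.approx(2.0 + 12.0)

    def test_nonfinite_entries_abort(self):
        with pytest.raises(FloatingPointError):
            build_quadratic_model(1.0, np.array([np.nan]), np.eye(1))


class TestSubproblem2D:
    def test_boundary_solution_along_negative_gradient(self):
        m = quadratic(0.0, [1.0, 0.0], np.eye(2))
        s = solve_subproblem_2d(m, radius=0.5)
        np.testing.assert_allclose(s, [-0.5, 0.0], atol=1e-12)

    def test_interior_newton_step(self):
        m = quadratic(0.0, [1.0, 0.0], np.eye(2))
        s = solve_subproblem_2d(m, radius=2.0)
        np.testing.assert_allclose(s, [-1.0, 0.0], atol=1e-12)

    def test_zero_gradient_returns_zero_step(self):
        m = quadratic(1.0, [0.0, 0.0], np.eye(2))
        np.testing.assert_array_equal(solve_subproblem_2d(m, radius=1.0), [0.0, 0.0])

    def test_never_worse_than_cauchy_point(self, rng):
        # closed-form optimal step along -g (the Cauchy point) is an upper
        # bound on the model value of the 2D-subspace step
        for _ in range(50):
            dim = 4  # n = 2 components
            a = rng.normal(size=(dim, dim))
            hess = a @ a.T  # PSD like a Gauss-Newton Hessian
            g = rng.normal(size=dim)
            radius = 0.3
            m = quadratic(0.0, g, hess)
            s = solve_subproblem_2d(m, radius)
            assert np.linalg.norm(s) <= radius * (1 + 1e-9)
            gnorm = np.linalg.norm(g)
            ghg = g @ hess @ g
            tau = radius / gnorm
            if ghg > 0:
                tau = min(tau, gnorm**2 / ghg)
            cauchy = -tau * g
            assert m(s) <= m(cauchy) + 1e-12 * abs(m(cauchy))


class TestStepQualityAndRadius:
    def test_exact_quadratic_gives_rho_one(self, rng):
        hess = np.eye(2) * 2.0
        g = np.array([1.0, -1.0])
        f0 = 5.0
        m = quadratic(f0, g, hess)
        s = np.array([-0.3, 0.2])
        f_trial = f0 + g @ s + 0.5 * s @ hess @ s
        assert step_quality(m, f_trial, s) == pytest.approx(1.0)

    def test_increase_at_trial_point_gives_negative_rho(self):
        m = quadratic(1.0, [1.0], np.eye(1))
        s = np.array([-0.5])
        assert step_quality(m, f_trial=2.0, s=s) < 0.0

    def test_nonpositive_predicted_reduction_rejects(self):
        m = quadratic(1.0, [1.0], np.eye(1))
        s = np.array([0.5])  # uphill step: predicted reduction negative
        assert step_quality(m, f_trial=0.9, s=s) == -np.inf

    @pytest.mark.parametrize(
        "rho, step_norm, radius, expect_radius, expect_accept",
        [
            (0.9, 1.0, 1.0, 2.0, True),  # strong boundary step doubles radius
            (0.05, 0.5, 1.0, 0.25, False),  # poor step quarters radius
            (0.5, 0.2, 1.0, 1.0, True),  # middling interior step keeps radius
            (0.9, 0.2, 1.0, 1.0, True),  # strong but interior: no growth
        ],
    )
    def test_radius_policy(self, rho, step_norm, radius, expect_radius, expect_accept):
        cfg = SolverConfig()
        new_radius, accepted = update_radius(cfg, rho, step_norm, radius)
        assert new_radius == pytest.approx(expect_radius)
        assert accepted is expect_accept


def _grid_search_1c(series, m0_range, t1_range, n_grid=2000):
    """Dense grid-search oracle for the single-component problem."""
    y = series.magnitude
    t1s = np.linspace(*t1_range, n_grid)
    m0s = np.linspace(*m0_range, n_grid)
    kernels = np.abs(1 - 2 * np.exp(-series.ti_ms[None, :] / t1s[:, None]))
    kk = np.einsum("ij,ij->i", kernels, kernels)
    ky = kernels @ y
    yy = y @ y
    # f(m0, t1) = yy - 2 m0 ky + m0^2 kk, expanded over the m0 grid
    f = yy - 2 * np.outer(ky, m0s) + np.outer(kk, m0s**2)
    idx = np.unravel_index(np.argmin(f), f.shape)
    return float(f[idx]), float(m0s[idx[1]]), float(t1s[idx[0]])


class TestSolveBounded:
    def test_single_component_recovery(self):
        ti = make_ti_grid(105, 50, 3000)
        truth = ComponentParameters(m0=[100.0], t1_ms=[1000.0])
        series = InversionRecoverySeries(ti_ms=ti, magnitude=forward_signal(truth, ti))
        bounds = ParameterBounds(m0_lower=0.0, m0_upper=200.0)
        result = solve_bounded(series, np.array([80.0, 800.0]), bounds)
        np.testing.assert_allclose(result.x, [100.0, 1000.0], rtol=1e-6)
        # grid-search oracle confirms this is the global minimum basin
        f_grid, m0_g, t1_g = _grid_search_1c(series, (0, 200), (250, 4000))
        assert result.objective <= f_grid + 1e-9

    def test_start_at_optimum_exits_immediately(self):
        ti = make_ti_grid(50, 50, 3000)
        truth = ComponentParameters(m0=[10.0], t1_ms=[900.0])
        series = InversionRecoverySeries(ti_ms=ti, magnitude=forward_signal(truth, ti))
        bounds = ParameterBounds(m0_lower=0.0, m0_upper=20.0)
        result = solve_bounded(series, np.array([10.0, 900.0]), bounds)
        assert result.converged
        assert result.n_iterations <= 2

    def test_rosenbrock_bounded(self):
        def res_jac(x):
            r = np.array([10.0 * (x[1] - x[0] ** 2), 1.0 - x[0]])
            jac = np.array([[-20.0 * x[0], 10.0], [-1.0, 0.0]])
            return r, jac

        result = minimize_least_squares(
            res_jac, np.array([-1.2, 1.0]), np.array([-2.0, -2.0]), np.array([2.0, 2.0])
        )
        np.testing.assert_allclose(result.x, [1.0, 1.0], rtol=1e-6)

    def test_series_shorter_than_2n_rejected(self):
        series = InversionRecoverySeries(ti_ms=[50.0, 100.0, 150.0], magnitude=[1.0, 2.0, 3.0])
        bounds = ParameterBounds(m0_lower=0.0, m0_upper=10.0)
        with pytest.raises(ValueError, match="identify"):
            solve_bounded(series, np.array([1.0, 1.0, 500.0, 600.0]), bounds)

    def test_accepted_objectives_never_increase(self, rng):
        # 100 random seeded single-start problems
        ti = make_ti_grid(40, 50, 3000)
        for seed in range(100):
            local_rng = np.random.default_rng(seed)
            n = int(local_rng.integers(1, 3))
            truth = ComponentParameters(
                m0=local_rng.uniform(5, 100, n), t1_ms=local_rng.uniform(300, 3500, n)
            )
            noise = local_rng.normal(0, 1.0, ti.size)
            series = InversionRecoverySeries(
                ti_ms=ti, magnitude=forward_signal(truth, ti) + noise
            )
            bounds = ParameterBounds(m0_lower=0.0, m0_upper=300.0)
            x0 = local_rng.uniform(*bounds.as_vectors(n))
            result = solve_bounded(series, x0, bounds)
            assert np.all(np.diff(result.objective_history) <= 0.0)

    def test_result_within_bounds(self, rng):
        ti = make_ti_grid(30, 50, 3000)
        truth = ComponentParameters(m0=[50.0], t1_ms=[600.0])
        series = InversionRecoverySeries(
            ti_ms=ti, magnitude=forward_signal(truth, ti) + rng.normal(0, 2, ti.size)
        )
        bounds = ParameterBounds(m0_lower=1.0, m0_upper=40.0, t1_lower_ms=700.0, t1_upper_ms=4000.0)
        result = solve_bounded(series, np.array([20.0, 1500.0]), bounds)
        lb, ub = bounds.as_vectors(1)
        assert np.all(result.x >= lb) and np.all(result.x <= ub)


def _grid_search_2c(series, m0_hi, n_t1=40, n_m0=25):
    """Coarse 4D grid-search oracle for the two-component problem."""
    y = series.magnitude
    t1s = np.linspace(250, 4000, n_t1)
    m0s = np.linspace(0, m0_hi, n_m0)
    kernels = np.abs(1 - 2 * np.exp(-series.ti_ms[None, :] / t1s[:, None]))
    yy = y @ y
    m0a, m0b = np.meshgrid(m0s, m0s, indexing="ij")
    m0a, m0b = m0a.ravel(), m0b.ravel()
    best = np.inf
    for i in range(n_t1):
        ki = kernels[i]
        for j in range(i, n_t1):
            kj = kernels[j]
            gaa, gab, gbb = ki @ ki, ki @ kj, kj @ kj
            ca, cb = ki @ y, kj @ y
            f = (
                yy
                - 2 * (m0a * ca + m0b * cb)
                + m0a**2 * gaa
                + 2 * m0a * m0b * gab
                + m0b**2 * gbb
            )
            best = min(best, float(f.min()))
    return best


class TestMultiStart:
    def test_sampled_points_within_bounds_and_reproducible(self):
        bounds = ParameterBounds(m0_lower=0.0, m0_upper=10.0)
        mcfg = MultiStartConfig(n_starts=100, seed=42, bounds=bounds)
        pts = sample_starting_points(mcfg, n_params=6)
        assert pts.shape == (100, 6)
        lb, ub = bounds.as_vectors(3)
        assert np.all(pts >= lb) and np.all(pts <= ub)
        pts2 = sample_starting_points(mcfg, n_params=6)
        np.testing.assert_array_equal(pts, pts2)

    def test_nested_prefix_property(self):
        bounds = ParameterBounds(m0_lower=0.0, m0_upper=10.0)
        small = sample_starting_points(
            MultiStartConfig(n_starts=5, seed=7, bounds=bounds), n_params=4
        )
        large = sample_starting_points(
            MultiStartConfig(n_starts=20, seed=7, bounds=bounds), n_params=4
        )
        np.testing.assert_array_equal(large[:5], small)

    def test_single_start_reduces_to_solve_bounded(
        self, two_component_truth, noiseless_two_component_series
    ):
        bounds = ParameterBounds(m0_lower=0.0, m0_upper=150.0)
        mcfg = MultiStartConfig(n_starts=1, seed=3, bounds=bounds)
        x0 = sample_starting_points(mcfg, 4)[0]
        single = solve_bounded(noiseless_two_component_series, x0, bounds)
        multi = multistart_fit(
            noiseless_two_component_series, bounds, mcfg, n_components=2
        )
        assert multi.best_objective == pytest.approx(single.objective)
        np.testing.assert_allclose(multi.best_params.as_vector(), single.x)

    def test_best_objective_nonincreasing_in_nested_starts(
        self, noiseless_two_component_series
    ):
        bounds = ParameterBounds(m0_lower=0.0, m0_upper=150.0)
        prev = np.inf
        for n_starts in (1, 5, 20):
            mcfg = MultiStartConfig(n_starts=n_starts, seed=11, bounds=bounds)
            fit = multistart_fit(
                noiseless_two_component_series, bounds, mcfg, n_components=2
            )
            assert fit.best_objective <= prev + 1e-15
            prev = fit.best_objective

    def test_beats_grid_search_oracle_on_one_and_two_components(self, rng):
        ti = make_ti_grid(60, 50, 3000)
        for n in (1, 2):
            truth = ComponentParameters(
                m0=rng.uniform(20, 80, n), t1_ms=rng.uniform(500, 2500, n)
            )
            series = InversionRecoverySeries(
                ti_ms=ti, magnitude=forward_signal(truth, ti)
            )
            m0_hi = 2.0 * float(truth.m0.max())
            bounds = ParameterBounds(m0_lower=0.0, m0_upper=m0_hi)
            mcfg = MultiStartConfig(n_starts=10, seed=5, bounds=bounds)
            fit = multistart_fit(series, bounds, mcfg, n_components=n)
            if n == 1:
                f_grid, *_ = _grid_search_1c(series, (0, m0_hi), (250, 4000), n_grid=500)
            else:
                f_grid = _grid_search_2c(series, m0_hi)
            assert fit.best_objective <= f_grid + 1e-9

    def test_recovery_three_components_noiseless(self):
        # noiseless n-component recovery should be essentially exact
        ti = make_ti_grid(105, 50, 3000)
        truth = ComponentParameters(
            m0=np.array([50.0, 80.0, 30.0]), t1_ms=np.array([700.0, 1200.0, 2000.0])
        )
        series = InversionRecoverySeries(ti_ms=ti, magnitude=forward_signal(truth, ti))
        bounds = ParameterBounds(
            m0_lower=0.0, m0_upper=float(series.magnitude.max())
        )
        mcfg = MultiStartConfig(n_starts=100, seed=2, bounds=bounds)
        fit = multistart_fit(series, bounds, mcfg, n_components=3)
        est = fit.best_params
        order = np.argsort(est.t1_ms)
        np.testing.assert_allclose(est.t1_ms[order], truth.t1_ms, rtol=1e-3 * 1e-2)
        np.testing.assert_allclose(est.m0[order], truth.m0, rtol=1e-3 * 1e-2)

    def test_matches_independent_trf_implementation(self, rng):
        # cross-check the best objective against scipy's trust-region
        # reflective solver started from the same points
        from scipy.optimize import least_squares

        ti = make_ti_grid(60, 50, 3000)
        truth = ComponentParameters(m0=[40.0, 70.0], t1_ms=[800.0, 1600.0])
        noisy = forward_signal(truth, ti) + rng.normal(0, 1.0, ti.size)
        series = InversionRecoverySeries(ti_ms=ti, magnitude=noisy)
        bounds = ParameterBounds(m0_lower=0.0, m0_upper=200.0)
        mcfg = MultiStartConfig(n_starts=15, seed=9, bounds=bounds)
        fit = multistart_fit(series, bounds, mcfg, n_components=2)
        lb, ub = bounds.as_vectors(2)

        def resid(x):
            params = ComponentParameters(m0=x[:2], t1_ms=x[2:])
            return noisy - forward_signal(params, ti)

        best_ref = np.inf
        for x0 in sample_starting_points(mcfg, 4):
            ref = least_squares(resid, x0, bounds=(lb, ub), method="trf")
            best_ref = min(best_ref, 2.0 * ref.cost)
        assert fit.best_objective <= best_ref * (1 + 1e-6) + 1e-12
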