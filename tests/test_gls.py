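import numpy as np
import pytest

from kgreg import (
    GraphFilter,
    KernelSpec,
    NoiseModel,
    SelectionPattern,
    fit_gls_blue,
    fit_gls_kgr,
    fit_gls_naive,
    fit_kgr,
    fit_kgr_naive,
    flip_flop,
    rho_rblw,
    sigma_ml,
    sigma_n_shrinkage,
    sigma_t,
    sigma_t_inv,
    theta_cost,
    theta_map,
)
from kgreg.gls import ar1_bands, gls_cost, _THETA_GRID
from kgreg.graphs import filter_matrix_squared
from kgreg.kgr import gram_matrix
from kgreg.synthetic import SyntheticScenario, make_dataset, sample_matrix_normal_error

from conftest import random_instance, random_spd


class TestAR1:
    def test_theta_zero_identity(self):
        assert np.array_equal(sigma_t(0.0, 4), np.eye(4))
        assert np.allclose(sigma_t_inv(0.0, 4), np.eye(4))

    def test_printed_toeplitz_form(self):
        assert np.allclose(sigma_t(0.5, 2), [[1, 0.5], [0.5, 1]])

    @pytest.mark.parametrize("theta", [-0.8, 0.3, 0.9 - 1e-6])
    @pytest.mark.parametrize("t_prime", [2, 5, 10])
    def test_determinant_closed_form(self, theta, t_prime):
        det = np.linalg.det(sigma_t(theta, t_prime))
        assert det == pytest.approx((1 - theta**2) ** (t_prime - 1), rel=1e-10)

    @pytest.mark.parametrize("theta", np.linspace(-0.9, 0.9, 7))
    @pytest.mark.parametrize("t_prime", [2, 5, 12])
    def test_inverse_is_inverse(self, theta, t_prime):
        prod = sigma_t(theta, t_prime) @ sigma_t_inv(theta, t_prime)
        assert np.abs(prod - np.eye(t_prime)).max() < 1e-10

    def test_inverse_is_tridiagonal(self):
        S = sigma_t_inv(0.7, 6)
        assert np.abs(np.triu(S, k=2)).max() == 0.0

    def test_bands_structure(self):
        b = ar1_bands(5)
        assert np.array_equal(b.b1, b.b1.T) and np.all(np.diag(b.b1) == 0)
        assert b.b2.sum() == 3  # T' - 2 ones

    def test_invalid_theta(self):
        with pytest.raises(ValueError):
            sigma_t(1.0, 4)
        with pytest.raises(ValueError):
            sigma_t_inv(-1.2, 4)


class TestThetaEstimation:
    def test_cost_at_zero_is_trace(self, rng):
        E = rng.standard_normal((4, 6))
        got = theta_cost(0.0, E, np.eye(4), 0.0)
        assert got == pytest.approx(np.trace(E.T @ E), rel=1e-12)

    def test_cost_matches_dense_formula(self, rng):
        E = rng.standard_normal((4, 6))
        Sn = random_spd(rng, 4)
        for th in (-0.6, 0.2, 0.85):
            dense = (
                4 * 5 * np.log(1 - th**2)
                + np.trace(E.T @ np.linalg.inv(Sn) @ E @ sigma_t_inv(th, 6))
                + 4 * 6 * 0.3 / (1 - th**2)
            )
            assert theta_cost(th, E, Sn, 0.3) == pytest.approx(dense, rel=1e-10)

    def test_column_reversal_symmetry(self, rng):
        E = rng.standard_normal((5, 8))
        Sn = random_spd(rng, 5)
        th = np.linspace(-0.9, 0.9, 11)
        assert np.allclose(
            theta_cost(th, E, Sn, 0.1), theta_cost(th, E[:, ::-1], Sn, 0.1)
        )

    def test_alternating_zero_columns_give_zero_root(self, rng):
        E = rng.standard_normal((4, 8))
        E[:, 1::2] = 0.0  # kills the lag-1 cross term b
        assert theta_map(E, np.eye(4), 0.1) == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_cubic_equals_grid_argmin(self, seed):
        r = np.random.default_rng(seed)
        E = r.standard_normal((5, 30))
        Sn = random_spd(r, 5)
        alpha = float(r.uniform(0.001, 1.0))
        th = theta_map(E, Sn, alpha)
        grid_best = _THETA_GRID[np.argmin(theta_cost(_THETA_GRID, E, Sn, alpha))]
        assert th == pytest.approx(grid_best, abs=2e-4)

    def test_finite_difference_stationarity_at_root(self, rng):
        E = rng.standard_normal((6, 40))
        Sn = random_spd(rng, 6)
        th = theta_map(E, Sn, 0.05)
        h = 1e-6
        deriv = (theta_cost(th + h, E, Sn, 0.05) - theta_cost(th - h, E, Sn, 0.05)) / (2 * h)
        scale = abs(theta_cost(th, E, Sn, 0.05))
        assert abs(deriv) < 1e-4 * max(scale, 1.0)

    def test_monte_carlo_recovery(self):
        hits = 0
        for s in range(60):
            E = sample_matrix_normal_error(np.eye(50), 0.6, 50, 400, seed=s)
            th = theta_map(E, np.eye(50), 0.01)
            hits += abs(th - 0.6) <= 0.1
        assert hits >= 57  # >= 95% of runs


class TestSigmaN:
    def test_theta_zero_is_sample_covariance(self, rng):
        E = rng.standard_normal((4, 9))
        assert np.allclose(sigma_ml(E, 0.0), E @ E.T / 9, atol=1e-12)

    def test_banded_formula_matches_dense(self, rng):
        E = rng.standard_normal((5, 8))
        for th in (-0.5, 0.3, 0.8):
            dense = E @ sigma_t_inv(th, 8) @ E.T / 8
            assert np.allclose(sigma_ml(E, th), dense, atol=1e-12)

    def test_zero_residual_zero_matrix(self):
        assert np.all(sigma_ml(np.zeros((3, 5)), 0.4) == 0)

    def test_psd(self, rng):
        E = rng.standard_normal((6, 20))
        assert np.linalg.eigvalsh(sigma_ml(E, 0.7)).min() >= -1e-12

    def test_rblw_identity_degenerate(self):
        assert rho_rblw(np.eye(5), 5, 10) == 1.0

    def test_rblw_spread_spectrum_below_one(self):
        S = np.diag(np.arange(1.0, 9.0))
        rho = rho_rblw(S, 8, 1000)
        assert 0.0 < rho < 1.0

    def test_rblw_independent_transcription(self, rng):
        E = rng.standard_normal((6, 25))
        S = sigma_ml(E, 0.0)
        n, t = 6, 25
        tr, tr2 = np.trace(S), np.trace(S @ S)
        expected = min(((t - 2) / t * tr2 + tr**2) / ((t + 2) * (tr2 - tr**2 / n)), 1.0)
        assert rho_rblw(S, n, t) == pytest.approx(expected, rel=1e-12)

    def test_shrinkage_endpoints_and_trace(self, rng):
        E = rng.standard_normal((5, 12))
        S = sigma_ml(E, 0.2)
        assert np.allclose(sigma_n_shrinkage(E, 0.2, 0.0), S, atol=1e-12)
        assert np.allclose(
            sigma_n_shrinkage(E, 0.2, 1.0), np.trace(S) / 5 * np.eye(5), atol=1e-12
        )
        for rho in (0.0, 0.3, 1.0):
            got = np.trace(sigma_n_shrinkage(E, 0.2, rho))
            assert got == pytest.approx(np.trace(S), rel=1e-10)

    def test_zero_residuals_error(self):
        with pytest.raises(ValueError):
            sigma_n_shrinkage(np.zeros((3, 5)), 0.0, 0.5)


class TestFlipFlop:
    def test_null_recovery(self):
        ok = 0
        for s in range(40):
            E = sample_matrix_normal_error(np.eye(40), 0.0, 40, 300, seed=s)
            nm, it, conv = flip_flop(E, alpha=0.01)
            off = np.abs(nm.sigma_n - np.diag(np.diag(nm.sigma_n))).sum()
            diag = np.abs(np.diag(nm.sigma_n)).sum()
            ok += conv and abs(nm.theta) <= 0.1 and off < diag
        assert ok >= 38  # 95% rate

    def test_fixed_point(self, rng):
        E = sample_matrix_normal_error(np.eye(10), 0.5, 10, 80, seed=1)
        nm, _, conv = flip_flop(E, alpha=0.05, tol=1e-10)
        assert conv
        th2 = theta_map(E, nm.sigma_n, 0.05)
        assert abs(th2 - nm.theta) < 1e-8

    def test_convergence_within_budget(self):
        E = sample_matrix_normal_error(np.eye(20), -0.4, 20, 150, seed=5)
        nm, it, conv = flip_flop(E, alpha=0.1)
        assert conv and it <= 100


class TestGLSBlue:
    def test_identity_covariances_reduce_to_kgr(self, exp_filter, kernel):
        graph, sel, X, Y = random_instance(11)
        F_kgr = fit_kgr(Y, X, graph, exp_filter, 0.5, sel, kernel).f_star
        F_gls, _ = fit_gls_blue(
            Y, X, graph, exp_filter, 0.5,
            np.eye(sel.n_prime), np.eye(sel.t_prime), sel, kernel,
        )
        assert np.abs(F_gls - F_kgr).max() < 1e-10 * max(np.abs(F_kgr).max(), 1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_naive_oracle(self, seed, exp_filter, kernel):
        graph, sel, X, Y = random_instance(seed, n=6, t=8, n_prime=4, t_prime=5)
        r = np.random.default_rng(seed + 500)
        Sn = random_spd(r, 4)
        St = sigma_t(0.4, 5)
        F_fast, _ = fit_gls_blue(Y, X, graph, exp_filter, 0.5, Sn, St, sel, kernel)
        F_slow = fit_gls_naive(Y, X, graph, exp_filter, 0.5, Sn, St, sel, kernel)
        rel = np.abs(F_fast - F_slow).max() / np.abs(F_slow).max()
        assert rel < 1e-8

    def test_joint_rescaling_invariance(self, exp_filter, kernel, rng):
        graph, sel, X, Y = random_instance(13, n=6, t=8, n_prime=4, t_prime=5)
        Sn = random_spd(rng, 4)
        St = sigma_t(0.3, 5)
        F1, _ = fit_gls_blue(Y, X, graph, exp_filter, 1.0, Sn, St, sel, kernel)
        c = 3.7
        F2, _ = fit_gls_blue(Y, X, graph, exp_filter, 1.0 / c, c * Sn, St, sel, kernel)
        assert np.allclose(F1, F2, atol=1e-9 * np.abs(F1).max())

    def test_naive_is_local_minimum_of_cost(self, exp_filter, kernel):
        graph, sel, X, Y = random_instance(17, n=5, t=6, n_prime=4, t_prime=4)
        r = np.random.default_rng(17)
        Sn = random_spd(r, 4)
        St = sigma_t(0.5, 4)
        gamma = 0.8
        F = fit_gls_naive(Y, X, graph, exp_filter, gamma, Sn, St, sel, kernel)
        K = gram_matrix(X, kernel)
        H2 = filter_matrix_squared(graph, exp_filter)
        base = gls_cost(F, Y, K, H2, gamma, Sn, St, sel)
        for _ in range(100):
            dF = 1e-4 * r.standard_normal(F.shape)
            assert gls_cost(F + dF, Y, K, H2, gamma, Sn, St, sel) >= base - 1e-12

    def test_non_spd_covariance_rejected(self, exp_filter, kernel):
        graph, sel, X, Y = random_instance(19)
        Sn = -np.eye(sel.n_prime)
        with pytest.raises(ValueError, match="positive definite"):
            fit_gls_blue(Y, X, graph, exp_filter, 0.5, Sn,
                         np.eye(sel.t_prime), sel, kernel)


class TestGLSKGR:
    def test_frozen_identity_noise_equals_kgr_first_step(self, exp_filter, kernel):
        # with tol huge the loop does one BLUE step at identity covariances
        graph, sel, X, Y = random_instance(23)
        res = fit_gls_kgr(
            Y, X, graph, exp_filter, gamma=0.5, alpha=0.1,
            selection=sel, kernel=kernel, max_outer=1,
        )
        F_kgr = fit_kgr(Y, X, graph, exp_filter, 0.5, sel, kernel).f_star
        assert np.allclose(res.f_star, F_kgr, atol=1e-10)

    def test_synthetic_theta_recovery(self):
        hits = 0
        for s in range(15):
            data = make_dataset(SyntheticScenario(true_theta=0.4, seed=s))
            res = fit_gls_kgr(
                data.y, data.x, data.graph, GraphFilter("exponential", 1.0),
                gamma=1.0, alpha=0.1, selection=data.selection,
                kernel=KernelSpec(sigma=4.0),
            )
            hits += res.converged and abs(res.noise.theta - 0.4) <= 0.15
        assert hits >= 13  # ~90% rate at a reduced replicate count

    def test_reports_history_and_iterations(self, exp_filter, kernel):
        graph, sel, X, Y = random_instance(29)
        res = fit_gls_kgr(Y, X, graph, exp_filter, gamma=0.5, alpha=0.1,
                          selection=sel, kernel=kernel)
        assert res.outer_iterations == len(res.history)
        assert res.total_iterations == res.outer_iterations + res.inner_iterations
        assert np.isfinite(res.final_cost)
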