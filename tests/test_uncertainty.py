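import numpy as np
import pytest

from trajfit import (
    TrajectoryEnsemble,
    WeightMatrix,
    bootstrap_errors,
    ccm_covariance,
    ccm_weights,
    compute_stats,
    fit_ensemble,
    jackknife_fit,
    minimize_chi2,
    model_constant,
    model_linear,
    simulate,
    subsample_times,
    wls_weights,
    wlsece_covariance,
    wlsice_covariance,
)
from trajfit.simulators import ProcessSpec


def random_ensemble(rng, m=60, n=6, slope=2.0):
    t = np.arange(1.0, n + 1.0)
    values = slope * t + rng.standard_normal((m, n)) @ rng.uniform(0.2, 1.0, (n, n))
    return TrajectoryEnsemble(t, values)


class TestClosedFormReductions:
    def test_constant_fit_recovers_stationary_variance_formula(self, rng):
        ens = random_ensemble(rng, m=50, n=8, slope=0.0)
        st = compute_stats(ens)
        sigma2 = np.diag(st.cov_of_mean).mean()
        w = WeightMatrix(np.eye(8) / sigma2, kind="custom")
        fit = minimize_chi2(st, model_constant(), w, ens.times)
        cov = wlsice_covariance(st, model_constant(), w, fit, ens.times)
        expected = st.cov.sum() / (st.M * 8 ** 2)
        assert cov.delta_hat[0, 0] == pytest.approx(expected, rel=1e-10)

    def test_diagonal_sample_covariance_makes_ice_equal_ece(self, rng):
        ens = random_ensemble(rng)
        st = compute_stats(ens)
        st.cov = np.diag(np.diag(st.cov))
        st.cov_of_mean = st.cov / st.M
        w = wls_weights(st)
        fit = minimize_chi2(st, model_linear(), w, ens.times)
        ice = wlsice_covariance(st, model_linear(), w, fit, ens.times)
        ece = wlsece_covariance(st, model_linear(), w, fit, ens.times)
        np.testing.assert_allclose(ice.delta_hat, ece.delta_hat, rtol=1e-12)

    def test_linear_model_matches_propagation_formula(self, rng):
        # independent closed form: theta1_hat = sum w t y / sum w t^2 is
        # linear in ybar, so Var = w t^T (Q/M) w t / (sum w t^2)^2
        ens = random_ensemble(rng)
        st = compute_stats(ens)
        t = ens.times
        w = wls_weights(st)
        wd = np.diag(w.R)
        fit = minimize_chi2(st, model_linear(), w, t)
        cov = wlsice_covariance(st, model_linear(), w, fit, t)
        wt = wd * t
        expected = wt @ (st.cov / st.M) @ wt / (wd * t * t).sum() ** 2
        assert cov.delta_hat[0, 0] == pytest.approx(expected, rel=1e-8)

    def test_ccm_generic_and_reduced_routes_agree(self, rng):
        ens = random_ensemble(rng, m=200, n=6)
        st = compute_stats(ens)
        w = ccm_weights(st)
        fit = minimize_chi2(st, model_linear(), w, ens.times)
        cov = ccm_covariance(st, model_linear(), fit, ens.times)  # internal 1e-8 cross-check
        assert cov.method == "ccm"
        assert np.all(np.linalg.eigvalsh(cov.delta_hat) >= -1e-10 * np.trace(cov.delta_hat))

    def test_ccm_requires_ccm_weights(self, rng):
        ens = random_ensemble(rng)
        st = compute_stats(ens)
        w = wls_weights(st)
        fit = minimize_chi2(st, model_linear(), w, ens.times)
        with pytest.raises(ValueError, match="CCM weights"):
            ccm_covariance(st, model_linear(), fit, ens.times)

    def test_covariance_invariant_under_weight_rescaling(self, rng):
        ens = random_ensemble(rng)
        st = compute_stats(ens)
        t = ens.times
        w = wls_weights(st)
        fit = minimize_chi2(st, model_linear(), w, t)
        base = wlsice_covariance(st, model_linear(), w, fit, t)
        for c in (1e-3, 7.0, 1e4):
            scaled = wlsice_covariance(
                st, model_linear(), WeightMatrix(c * w.R, "custom"), fit, t
            )
            np.testing.assert_allclose(
                scaled.delta_hat, base.delta_hat, rtol=1e-12
            )

    def test_every_delta_is_symmetric_psd(self, rng):
        spec = ProcessSpec("fbm", {"H": 0.75}, times=np.arange(1.0, 16.0), M=100)
        ens = simulate(spec, seed=5)
        from trajfit import model_power_law
        st, fit = fit_ensemble(ens, model_power_law())
        for fn in (wlsice_covariance, wlsece_covariance):
            cov = fn(st, fit.model, fit.weights, fit, ens.times)
            np.testing.assert_allclose(cov.delta_hat, cov.delta_hat.T, atol=1e-14)
            w = np.linalg.eigvalsh(cov.delta_hat)
            assert w.min() >= -1e-10 * np.trace(cov.delta_hat)
            np.testing.assert_allclose(
                cov.delta_hat, cov.phi_hat / st.M, rtol=1e-14
            )


class TestJackknife:
    def test_constant_linear_statistic_unchanged(self, rng):
        # with fixed (identity) weights the constant fit is the grand mean,
        # linear in the data, so jackknifing must return it exactly
        ens = random_ensemble(rng, m=40, n=5, slope=0.0)
        fit_j, _ = jackknife_fit(ens, model_constant(), "identity", g=4, order=1)
        _, fit = fit_ensemble(ens, model_constant(), "identity")
        np.testing.assert_allclose(fit_j.theta_hat, fit.theta_hat, atol=1e-8)

    def test_g_equal_m_matches_delete_one_oracle(self, rng):
        ens = random_ensemble(rng, m=12, n=4)
        m = ens.n_trajectories
        fit_j, _ = jackknife_fit(ens, model_linear(), "identity", g=m, order=1)
        # independent delete-one oracle using the closed-form OLS slope
        t = ens.times

        def ols(values):
            ybar = values.mean(axis=0)
            return (t * ybar).sum() / (t * t).sum()

        full = ols(ens.values)
        loo = np.array([ols(np.delete(ens.values, i, axis=0)) for i in range(m)])
        expected = m * full - (m - 1) * loo.mean()
        assert fit_j.theta_hat[0] == pytest.approx(expected, abs=1e-8)

    def test_second_order_runs_and_reports(self, rng):
        ens = random_ensemble(rng, m=30, n=5)
        fit_j, cov = jackknife_fit(ens, model_linear(), "wls", g=3, order=2)
        assert cov.method == "jackknife2"
        assert np.isfinite(fit_j.theta_hat).all()

    def test_bad_group_counts_rejected(self, rng):
        ens = random_ensemble(rng, m=10, n=4)
        with pytest.raises(ValueError, match="g >= 2"):
            jackknife_fit(ens, model_linear(), "wls", g=1)
        with pytest.raises(ValueError, match="order"):
            jackknife_fit(ens, model_linear(), "wls", g=2, order=3)


class TestBootstrap:
    def test_identical_trajectories_give_zero_sigma(self):
        values = np.tile(2.0 * np.arange(1.0, 6.0), (20, 1))
        ens = TrajectoryEnsemble(np.arange(1.0, 6.0), values)
        cov = bootstrap_errors(ens, model_linear(), "identity", B=20, seed=0)
        np.testing.assert_allclose(cov.sigma_hat, 0.0, atol=1e-10)

    def test_constant_model_matches_stationary_formula(self, rng):
        ens = random_ensemble(rng, m=80, n=6, slope=0.0)
        st = compute_stats(ens)
        cov = bootstrap_errors(ens, model_constant(), "identity", B=300, seed=1)
        expected = st.cov.sum() / (st.M * 6 ** 2)
        # bootstrap MC error on a variance is ~ sqrt(2/B) relative
        assert cov.delta_hat[0, 0] == pytest.approx(expected, rel=0.5)

    def test_bootstrap_and_ice_sigmas_agree_on_bm(self):
        ratios = []
        for seed in (1, 2, 3):
            spec = ProcessSpec("bm", {"D": 1.0, "d": 1},
                               times=np.arange(1.0, 26.0), M=300)
            ens = simulate(spec, seed=seed)
            st, fit = fit_ensemble(ens, model_linear())
            ice = wlsice_covariance(st, fit.model, fit.weights, fit, ens.times)
            boot = bootstrap_errors(ens, model_linear(), "wls", B=100, seed=seed)
            ratios.append(boot.sigma_hat[0] / ice.sigma_hat[0])
        assert abs(np.mean(ratios) - 1.0) < 0.2

    def test_small_B_rejected(self, rng):
        ens = random_ensemble(rng)
        with pytest.raises(ValueError, match="B >= 2"):
            bootstrap_errors(ens, model_linear(), "wls", B=1)


class TestSubsampleTimes:
    def test_identity_and_extremes(self, small_ensemble):
        same = subsample_times(small_ensemble, 1)
        np.testing.assert_array_equal(same.values, small_ensemble.values)
        one = subsample_times(small_ensemble, small_ensemble.n_times)
        assert one.n_times == 1
        assert one.times[0] == small_ensemble.times[0]

    def test_preserves_time_subsequence(self):
        t = np.arange(1.0, 76.0)
        ens = TrajectoryEnsemble(t, np.zeros((2, 75)) + t)
        out = subsample_times(ens, 5)
        assert out.n_times == 15
        np.testing.assert_array_equal(out.times, t[::5])

    def test_too_few_surviving_points_rejected(self, small_ensemble):
        with pytest.raises(ValueError, match="leaves"):
            subsample_times(small_ensemble, 5, min_points=3)
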