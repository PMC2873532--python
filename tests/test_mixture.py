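"""Weibull-Normal mixture: densities, posterior, cutoff rule, MLE."""

import numpy as np
import pytest
from scipy import integrate
from scipy import stats as sps

from onoffcalls import (CutoffRule, MixtureParams, WeibullNormalMixture,
                        cutoff_x, fit_mixture, mixture_pdf, on_density,
                        posterior_off, posterior_on, simulate_z, weibull_pdf,
                        z_transform)
from onoffcalls.mixture import (_log_on_density_grid, _neg_log_likelihood,
                                _transform)


class TestWeibullPdf:
    def test_unit_exponential_values(self):
        assert weibull_pdf(0.0, 1.0, 1.0) == pytest.approx(1.0)
        assert weibull_pdf(1.0, 1.0, 1.0) == pytest.approx(np.exp(-1.0))

    def test_zero_below_support(self):
        assert weibull_pdf(-0.5, 2.0, 1.5) == 0.0

    @pytest.mark.parametrize("mu,alpha", [(1.0, 1.0), (1.96, 1.10)])
    def test_normalizes(self, mu, alpha):
        val, _ = integrate.quad(weibull_pdf, 0, np.inf, args=(mu, alpha))
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            weibull_pdf(1.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            weibull_pdf(1.0, 1.0, 0.0)


class TestOnDensity:
    def test_delta_noise_limit_degenerates_to_weibull(self):
        params = MixtureParams(1.0, 1.0, 0.5, 1e-10)
        for z in (0.5, 1.0, 2.0):
            assert on_density(z, params) == pytest.approx(
                weibull_pdf(z, 1.0, 1.0), rel=1e-3)

    def test_matches_monte_carlo(self):
        """Bin mass around z=1 vs 1e6 simulated draws of T + noise."""
        params = MixtureParams(1.0, 1.0, 0.0, 0.15)
        rng = np.random.default_rng(99)
        n = 1_000_000
        draws = rng.weibull(1.0, n) * 1.0 + rng.normal(0, params.sigma, n)
        lo, hi = 0.98, 1.02
        p_hat = np.mean((draws >= lo) & (draws < hi))
        p_model, _ = integrate.quad(lambda z: on_density(z, params), lo, hi)
        se = np.sqrt(p_model * (1 - p_model) / n)
        assert abs(p_hat - p_model) < 3 * se

    @pytest.mark.parametrize("theta", [(1.00, 1.00, 0.5, 0.15),
                                       (1.96, 1.10, 0.5, 0.13)])
    def test_normalizes_for_reported_fits(self, theta):
        params = MixtureParams(*theta)
        val, _ = integrate.quad(lambda z: on_density(z, params), -6, 60,
                                limit=300)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_fast_grid_agrees_with_quadrature(self):
        zs = np.array([-0.5, 0.0, 0.4, 1.0, 2.5, 5.0])
        for mu, alpha, s2 in [(1.0, 1.0, 0.15), (1.96, 1.1, 0.13),
                              (0.3, 2.5, 0.05), (4.0, 0.6, 0.8)]:
            params = MixtureParams(mu, alpha, 0.5, s2)
            exact = on_density(zs, params)
            fast = np.exp(_log_on_density_grid(zs, mu, alpha, s2))
            keep = exact > 1e-12
            assert np.allclose(fast[keep], exact[keep], rtol=5e-3)


class TestMixturePdf:
    def test_pure_off_is_normal(self):
        params = MixtureParams(1.0, 1.0, 1.0, 0.15)
        assert mixture_pdf(0.0, params) == pytest.approx(
            1.0 / np.sqrt(2 * np.pi * 0.15))

    def test_pure_on_equals_on_density(self):
        params = MixtureParams(1.5, 1.2, 0.0, 0.2)
        zs = np.array([-0.3, 0.5, 2.0])
        assert np.allclose(mixture_pdf(zs, params), on_density(zs, params))

    def test_convex_combination(self):
        params = MixtureParams(1.0, 1.0, 0.35, 0.15)
        z = 0.8
        expected = (0.35 * sps.norm.pdf(z, scale=params.sigma)
                    + 0.65 * on_density(z, params))
        assert mixture_pdf(z, params) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("theta", [(1.0, 1.0, 0.35, 0.15),
                                       (1.96, 1.10, 0.17, 0.13),
                                       (0.5, 2.0, 0.8, 0.4)])
    def test_normalizes(self, theta):
        params = MixtureParams(*theta)
        val, _ = integrate.quad(lambda z: mixture_pdf(z, params), -10, 60,
                                limit=400)
        assert val == pytest.approx(1.0, abs=1e-6)


class TestPosterior:
    def test_degenerate_mixture_rates(self):
        on_only = MixtureParams(1.0, 1.0, 0.0, 0.15)
        off_only = MixtureParams(1.0, 1.0, 1.0, 0.15)
        zs = np.array([-2.0, 0.0, 3.0])
        assert np.allclose(posterior_on(zs, on_only), 1.0)
        assert np.allclose(posterior_on(zs, off_only), 0.0)

    @pytest.mark.parametrize("theta", [(1.00, 1.00, 0.35, 0.15),
                                       (1.96, 1.10, 0.17, 0.13)])
    def test_monotone_and_bounded_on_grid(self, theta):
        params = MixtureParams(*theta)
        grid = np.linspace(-4.0, 6.0, 1000)
        post = posterior_on(grid, params)
        assert np.all((post >= 0.0) & (post <= 1.0))
        assert np.all(np.diff(post) >= -1e-12)

    def test_complement(self):
        params = MixtureParams(1.0, 1.0, 0.35, 0.15)
        zs = np.array([-1.0, 0.3, 2.0, 8.0])
        assert np.allclose(posterior_on(zs, params) + posterior_off(zs, params),
                           1.0, atol=1e-12)

    def test_extreme_scores_never_nan(self):
        # note the On/Off likelihood ratio decays only like sigma2/(mu|z|)
        # as z -> -inf, so the left limit is small but not exponentially so
        params = MixtureParams(1.0, 1.0, 0.35, 0.15)
        post = posterior_on(np.array([-50.0, 50.0]), params)
        assert np.all(np.isfinite(post))
        assert post[0] < 0.02 and post[1] > 1 - 1e-9


class TestCutoff:
    def test_spikein_cutoff_16_pairs(self, u95_params):
        assert cutoff_x(u95_params, j=16, level=0.10) == 11

    @pytest.mark.parametrize("sigma2", [0.13, 0.14])
    def test_neuroblastoma_cutoff_11_pairs(self, sigma2):
        params = MixtureParams(1.96, 1.10, 0.17, sigma2)
        assert cutoff_x(params, j=11, level=0.10) == 7

    def test_median_level_gives_first_positive_z(self, u95_params):
        assert cutoff_x(u95_params, j=16, level=0.5) == 9

    def test_monotone_in_level_and_sigma2(self):
        levels = [0.01, 0.05, 0.10, 0.25, 0.5]
        xcs = [cutoff_x(MixtureParams(1, 1, 0.5, 0.15), 16, lv) for lv in levels]
        assert np.all(np.diff(xcs) <= 0)
        sigmas = [0.05, 0.10, 0.15, 0.30, 0.60]
        xcs = [cutoff_x(MixtureParams(1, 1, 0.5, s2), 16, 0.10) for s2 in sigmas]
        assert np.all(np.diff(xcs) >= 0)

    def test_no_qualifying_count_encoded_as_j_plus_one(self):
        assert cutoff_x(MixtureParams(1, 1, 0.5, 50.0), j=2, level=0.01) == 3

    def test_rule_object_consistency(self, u95_params):
        rule = CutoffRule.from_params(u95_params, 0.10)
        assert rule.x_c(16) == 11
        assert rule.x_c_table([16, 11]) == {11: cutoff_x(u95_params, 11, 0.10),
                                            16: 11}
        assert rule.z_c == pytest.approx(
            sps.norm.isf(0.10, scale=np.sqrt(0.15)))
        assert z_transform(11, 16) > rule.z_c > z_transform(10, 16)


class TestFitMixture:
    def test_recovers_parameters_moderate_n(self):
        theta = (1.00, 1.00, 0.35, 0.15)
        z, _ = simulate_z(MixtureParams(*theta), 12_000, seed=21)
        fit = fit_mixture(z, random_state=5)
        assert fit.converged
        for true, est in zip(theta, fit.params.as_tuple()):
            assert est == pytest.approx(true, abs=0.1)

    def test_deterministic_given_seed(self):
        z, _ = simulate_z(MixtureParams(1, 1, 0.35, 0.15), 3000, seed=8)
        f1 = fit_mixture(z, random_state=11)
        f2 = fit_mixture(z, random_state=11)
        assert f1.params == f2.params
        assert f1.log_likelihood == f2.log_likelihood

    def test_loglik_at_estimate_beats_truth(self):
        theta = (1.0, 1.0, 0.35, 0.15)
        z, _ = simulate_z(MixtureParams(*theta), 5000, seed=13)
        fit = fit_mixture(z, random_state=2)
        w = np.ones_like(z)
        nll_hat = _neg_log_likelihood(_transform(*fit.params.as_tuple()), z, w)
        nll_true = _neg_log_likelihood(_transform(*theta), z, w)
        assert nll_hat <= nll_true + 1e-6

    def test_consistency_error_shrinks_with_n(self):
        """Median absolute error over replicates decreases from n=500 to 8000."""
        theta = np.array([1.0, 1.0, 0.35, 0.15])
        med_err = {}
        for n in (500, 8000):
            errs = []
            for rep in range(4):
                z, _ = simulate_z(MixtureParams(*theta), n, seed=100 * n + rep)
                fit = fit_mixture(z, n_restarts=1, random_state=rep)
                errs.append(np.abs(np.array(fit.params.as_tuple()) - theta))
            med_err[n] = np.median(np.array(errs), axis=0)
        assert med_err[8000].sum() < med_err[500].sum()
        assert np.all(med_err[8000] < 0.1)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_mixture(np.full(500, 1.3))

    def test_small_sample_warns(self):
        z, _ = simulate_z(MixtureParams(1, 1, 0.4, 0.2), 60, seed=1)
        with pytest.warns(UserWarning, match="100"):
            fit_mixture(z, n_restarts=1)


class TestEstimatorInterface:
    def test_sklearn_params_round_trip(self):
        est = WeibullNormalMixture(level=0.05, n_restarts=2)
        assert est.get_params()["level"] == 0.05
        est.set_params(random_state=42)
        assert est.random_state == 42

    def test_fit_predict_proba_predict(self):
        z, labels = simulate_z(MixtureParams(1.5, 1.0, 0.5, 0.1), 8000, seed=3)
        est = WeibullNormalMixture(n_restarts=2, random_state=0).fit(z[:, None])
        proba = est.predict_proba(z[:500])
        assert proba.shape == (500, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        pred = est.predict(z)
        acc = np.mean((pred == 1) == (labels == "On"))
        assert acc > 0.8  # near the Bayes rate for this overlap

    def test_fitted_attributes_and_cutoff(self):
        z, _ = simulate_z(MixtureParams(1, 1, 0.35, 0.15), 6000, seed=4)
        est = WeibullNormalMixture(n_restarts=2, random_state=0).fit(z)
        for attr in ("mu_", "alpha_", "xi_", "sigma2_", "log_likelihood_",
                     "converged_", "n_obs_"):
            assert hasattr(est, attr)
        assert est.cutoff().x_c(16) in range(0, 18)

    def test_unfitted_raises(self):
        with pytest.raises(AttributeError, match="not fitted"):
            WeibullNormalMixture().predict_proba([0.0])
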