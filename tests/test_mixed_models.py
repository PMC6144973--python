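"""Mixed-model engine: likelihood correctness, smooths, R^2, concurvity."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from ovoscope import ecostats
from ovoscope._lmm import (
    MixedModelFit,
    RandomBlock,
    aicc,
    concurvity,
    fit_mixed,
    r2_nakagawa,
    smooth_design,
)


def simulate_lmm(rng, n_sites=10, per_site=4, beta=(1.0, 0.5),
                 sigma_a=1.0, sigma_e=1.0):
    n = n_sites * per_site
    site = np.repeat(np.arange(n_sites), per_site)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = (
        X @ np.asarray(beta)
        + rng.normal(0, sigma_a, n_sites)[site]
        + rng.normal(0, sigma_e, n)
    )
    return y, X, site


class TestFitLMM:
    def test_profiled_matches_dense_likelihood(self, rng):
        """The profiled algorithm's loglik equals a brute-force marginal
        multivariate-normal density at the estimates (n <= 50)."""
        for rep in range(5):
            y, X, site = simulate_lmm(rng, n_sites=8, per_site=5)
            fit = ecostats.fit_lmm(y, X, site, "ML")
            Z = np.eye(8)[site]
            V = fit.sigma2_eps * (
                np.eye(len(y))
                + (fit.sigma2_alpha / fit.sigma2_eps) * Z @ Z.T
            )
            dense = multivariate_normal.logpdf(y, X @ fit.beta, V)
            assert fit.loglik == pytest.approx(dense, abs=1e-6)

    def test_no_between_site_structure_reduces_to_ols(self, rng):
        n = 60
        site = np.arange(n) % 12
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        e = rng.normal(0, 1.0, n)
        for s in range(12):  # centering removes between-site structure
            e[site == s] -= e[site == s].mean()
        y = X @ [2.0, 1.0] + e
        fit = ecostats.fit_lmm(y, X, site, "ML")
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert fit.at_boundary
        np.testing.assert_allclose(fit.beta, ols, atol=1e-6)

    @pytest.mark.parametrize("criterion", ["ML", "REML"])
    def test_matches_statsmodels(self, rng, criterion):
        import statsmodels.api as sm

        y, X, site = simulate_lmm(rng, n_sites=12, per_site=5)
        ours = ecostats.fit_lmm(y, X, site, criterion)
        ref = sm.MixedLM(y, X, groups=site).fit(reml=criterion == "REML")
        np.testing.assert_allclose(ours.beta, ref.fe_params, atol=1e-6)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_simulation_recovery_unbiased(self):
        """Mean estimate over replicates within 2 Monte-Carlo SE of truth."""
        rng = np.random.default_rng(77)
        slopes = []
        for _ in range(300):
            y, X, site = simulate_lmm(rng, n_sites=30, per_site=4,
                                      beta=(1.0, 0.5))
            slopes.append(ecostats.fit_lmm(y, X, site, "ML").beta[1])
        slopes = np.asarray(slopes)
        mcse = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - 0.5) < 2 * mcse

    def test_too_few_sites_rejected(self, rng):
        y, X, _ = simulate_lmm(rng)
        with pytest.raises(ValueError, match="2 sites"):
            ecostats.fit_lmm(y, X, np.zeros(len(y)), "ML")

    def test_mixed_criterion_comparison_rejected(self, rng):
        y, X, site = simulate_lmm(rng)
        a = ecostats.fit_lmm(y, X, site, "ML")
        b = ecostats.fit_lmm(y, X, site, "REML")
        with pytest.raises(ValueError, match="mix"):
            ecostats.compare([a, b])


class TestSmoothTerm:
    def test_linear_truth_gives_edf_one(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 500)
        y = 2 * x + rng.normal(0, 0.5, 500)
        fit = ecostats.fit_smooth_term(y, x)
        assert fit.smooth_terms[0].edf == pytest.approx(1.0, abs=0.2)

    def test_infinite_penalty_is_least_squares_line(self):
        # noiseless linear data drive the wiggle variance to zero: the fit
        # must coincide with the least-squares line exactly
        x = np.linspace(0, 1, 80)
        y = 3.0 * x + 1.0
        fit = ecostats.fit_smooth_term(y, x)
        line = np.column_stack([np.ones_like(x), x])
        coef = np.linalg.lstsq(line, y, rcond=None)[0]
        np.testing.assert_allclose(fit.fitted_fixed, line @ coef, atol=1e-6)

    def test_quartic_truth_recovered(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0.4, 0.95, 500)
        z = (x - x.mean()) / x.std()
        truth = 0.5 * z - 0.4 * z**2 - 0.3 * z**3 + 0.35 * z**4
        y = truth + rng.normal(0, 0.3, 500)
        fit = ecostats.fit_smooth_term(y, x)
        pred = fit.contributions["s(x)"]
        pred = pred - pred.mean()
        target = truth - truth.mean()
        rmse = np.sqrt(np.mean((pred - target) ** 2))
        assert rmse < 0.1 * np.ptp(truth)

    def test_few_distinct_values_reduces_basis(self):
        x = np.repeat([0.0, 0.5, 1.0, 1.5], 10)
        with pytest.warns(UserWarning, match="reducing"):
            smooth_design(x, n_basis=5)

    def test_edf_bounded_by_basis_dimension(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, 400)
        y = np.sin(9 * x) + rng.normal(0, 0.2, 400)
        fit = ecostats.fit_smooth_term(y, x)
        assert 1.0 <= fit.smooth_terms[0].edf <= 5.0


class TestAICc:
    def test_direct_formula_values(self):
        assert aicc(0.0, 0, 10) == 0.0
        assert aicc(-100.0, 5, 110) == pytest.approx(210 + 60 / 104)

    def test_reduces_to_aic_for_large_n(self):
        assert aicc(-50.0, 5, 10**6) == pytest.approx(100 + 10, abs=1e-3)

    def test_undefined_when_saturated(self):
        with pytest.raises(ValueError):
            aicc(-5.0, 10, 11)

    def test_weight_shift_invariance(self):
        d = np.array([0.0, 1.3, 2.8, 7.0])
        w1 = ecostats.akaike_weights(d)
        w2 = ecostats.akaike_weights(d + 123.4)
        np.testing.assert_allclose(w1, w2)
        assert w1.sum() == pytest.approx(1.0)


class TestR2Nakagawa:
    @staticmethod
    def _constructed_fit(var_f=2.0, s2a=1.0, s2e=1.0, n=4000):
        rng = np.random.default_rng(0)
        fitted = rng.normal(0, np.sqrt(var_f), n)
        fitted *= np.sqrt(var_f) / fitted.std()
        return MixedModelFit(
            response="y", design="", term_names=[], beta=np.zeros(1),
            se=np.zeros(1), sigma2_alpha=s2a, sigma2_eps=s2e,
            smooth_terms=[], loglik=0.0, criterion="ML", k=3, n=n,
            fitted_fixed=fitted,
        )

    def test_arithmetic_on_definition(self):
        r2m, r2c = r2_nakagawa(self._constructed_fit())
        assert r2m == pytest.approx(0.5, abs=1e-6)
        assert r2c == pytest.approx(0.75, abs=1e-6)

    def test_equal_when_no_site_variance(self):
        r2m, r2c = r2_nakagawa(self._constructed_fit(s2a=0.0))
        assert r2m == pytest.approx(r2c)

    def test_large_sample_recovery(self):
        rng = np.random.default_rng(8)
        n_sites, per = 60, 20
        site = np.repeat(np.arange(n_sites), per)
        x = rng.normal(size=n_sites * per)
        y = (
            np.sqrt(2.0) * x
            + rng.normal(0, 1.0, n_sites)[site]
            + rng.normal(0, 1.0, n_sites * per)
        )
        fit = ecostats.fit_lmm(
            y, np.column_stack([np.ones_like(x), x]), site, "ML"
        )
        r2m, r2c = r2_nakagawa(fit)
        assert r2m == pytest.approx(0.5, abs=0.05)
        assert r2c == pytest.approx(0.75, abs=0.05)


class TestConcurvity:
    def test_self_projection_is_total(self, rng):
        x = rng.normal(size=200)
        assert concurvity(2.0 * x, x[:, None]) == pytest.approx(1.0)

    def test_independent_covariates_low(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=2000)
        b = rng.normal(size=2000)
        assert concurvity(a, b[:, None]) < 0.05

    def test_correlated_linear_bases_r_squared(self):
        rng = np.random.default_rng(11)
        n = 1000
        xa = rng.normal(size=n)
        xb = 0.7 * xa + np.sqrt(1 - 0.49) * rng.normal(size=n)
        assert concurvity(xa, xb[:, None]) == pytest.approx(0.49, abs=0.05)

    def test_constant_contribution_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            concurvity(np.ones(50), np.arange(50.0)[:, None])
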