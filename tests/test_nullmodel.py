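import numpy as np
import pytest

from starqt import nullmodel, simgen
from starqt.ascertain import select_extremes
from starqt.nullmodel import (
    compute_residuals,
    fit_conditional_secondary,
    fit_null_joint,
    fit_truncated_primary,
    naive_bias,
)

from conftest import make_matrix


def _simulate_selected(rng, beta_p=0.5, rho=0.6, n_cohort=100_000, n_sel=5_000, maf=0.05):
    """Cohort with one scalar coding effect on y1, tail-selected."""
    g = rng.binomial(2, maf, n_cohort).astype(float)
    eps1 = rng.standard_normal(n_cohort)
    y1 = beta_p * g + eps1
    y2 = rho * eps1 + np.sqrt(1 - rho**2) * rng.standard_normal(n_cohort)
    asc = select_extremes(y1, n_sel)
    i = asc.indices
    return y1[i], y2[i], g[i], asc.region


class TestTruncatedPrimary:
    def test_no_truncation_equals_ols(self, rng):
        x = rng.binomial(2, 0.2, 2_000).astype(float)
        y = 1.0 + 0.5 * x + rng.standard_normal(2_000)
        pf = fit_truncated_primary(y, None, x, None)
        D = np.column_stack([np.ones(2_000), x])
        ols = np.linalg.lstsq(D, y, rcond=None)[0]
        assert pf.gamma1[0] == pytest.approx(ols[0], rel=1e-6)
        assert pf.beta_p_hat == pytest.approx(ols[1], rel=1e-6)
        assert pf.converged

    def test_beta_recovery_under_truncation(self):
        # tail selection wildly biases OLS; the truncated MLE stays centred
        rng = np.random.default_rng(1)
        est = []
        for _ in range(200):
            y1, _, g, region = _simulate_selected(rng, n_cohort=20_000, n_sel=1_000)
            pf = fit_truncated_primary(y1, None, g, region)
            est.append(pf.beta_p_hat)
        est = np.array(est)
        se = est.std(ddof=1) / np.sqrt(est.size)
        assert abs(est.mean() - 0.5) < 3 * se

    def test_constant_coding_dropped(self, rng):
        y = rng.standard_normal(100)
        with pytest.warns(UserWarning, match="non-identifiable"):
            pf = fit_truncated_primary(y, None, np.zeros(100), None)
        assert np.isnan(pf.beta_p_hat)

    def test_out_of_region_observation_rejected(self, rng):
        from starqt.ascertain import SelectionRegion
        y = np.array([-3.0, 0.0, 3.0])
        with pytest.raises(ValueError, match="outside the region"):
            fit_truncated_primary(y, None, None, SelectionRegion(-2.0, 2.0))


class TestConditionalSecondary:
    def test_tau_recovery(self):
        rng = np.random.default_rng(2)
        taus = []
        for _ in range(200):
            y1, y2, g, region = _simulate_selected(rng, n_cohort=20_000, n_sel=1_000)
            pf = fit_truncated_primary(y1, None, g, region)
            fit, _ = fit_conditional_secondary(y2, None, y1, pf.mu1)
            taus.append(fit.tau_hat)
        taus = np.array(taus)
        se = taus.std(ddof=1) / np.sqrt(taus.size)
        assert abs(taus.mean() - 0.6) < 3 * se  # tau -> rho*sigma2/sigma1

    def test_tau_zero_when_independent(self):
        rng = np.random.default_rng(3)
        taus = []
        for _ in range(100):
            y1, y2, g, region = _simulate_selected(rng, rho=0.0, n_cohort=20_000, n_sel=1_000)
            pf = fit_truncated_primary(y1, None, g, region)
            fit, _ = fit_conditional_secondary(y2, None, y1, pf.mu1)
            taus.append(fit.tau_hat)
        taus = np.array(taus)
        assert abs(taus.mean()) < 3 * taus.std(ddof=1) / np.sqrt(taus.size)

    def test_residuals_have_zero_mean(self, rng):
        y1, y2, g, region = _simulate_selected(rng, n_cohort=10_000, n_sel=500)
        pf = fit_truncated_primary(y1, None, g, region)
        _, resid = fit_conditional_secondary(y2, None, y1, pf.mu1)
        assert abs(resid.e.mean()) < 1e-10

    def test_collinearity_rejected(self, rng):
        y = rng.standard_normal(100)
        X = np.ones((100, 1))  # duplicates the intercept
        with pytest.raises(ValueError, match="collinear"):
            fit_conditional_secondary(y, X, y, np.zeros(100))


class TestComputeResiduals:
    def test_joint_matches_two_stage_without_primary_effect(self):
        # when the gene does not affect y1 the two estimators agree closely
        rng = np.random.default_rng(4)
        y1, y2, g, region = _simulate_selected(rng, beta_p=0.0, n_cohort=20_000, n_sel=1_000)
        G = make_matrix(rng.binomial(2, 0.01, (1_000, 5)))
        fit_j, res_j = compute_residuals(y1, y2, None, None, G, None, region, method="joint")
        fit_t, res_t = compute_residuals(y1, y2, None, None, G, None, region, method="two-stage")
        assert fit_j.tau_hat == pytest.approx(fit_t.tau_hat, abs=0.05)
        assert np.corrcoef(res_j.e, res_t.e)[0, 1] > 0.99

    def test_degenerate_coding_reduces_to_plain_regression(self, rng):
        # constant coding: residuals equal those of y2 ~ 1 + y1 up to centring
        y1, y2, g, region = _simulate_selected(rng, beta_p=0.0, n_cohort=5_000, n_sel=400)
        with pytest.warns(UserWarning):
            pf = fit_truncated_primary(y1, None, np.zeros(400), region)
        _, resid = fit_conditional_secondary(y2, None, y1, pf.mu1)
        D = np.column_stack([np.ones(400), y1])
        coef, *_ = np.linalg.lstsq(D, y2, rcond=None)
        assert np.allclose(resid.e, y2 - D @ coef, atol=1e-10)

    def test_residuals_decorrelated_from_burden_coding(self):
        # under the null, corr(e, coding) is centred at zero; naive residuals are not
        rng = np.random.default_rng(5)
        star_corr, naive_corr = [], []
        for _ in range(100):
            y1, y2, g, region = _simulate_selected(rng, n_cohort=20_000, n_sel=1_000)
            pf = fit_truncated_primary(y1, None, g, region)
            _, resid = fit_conditional_secondary(y2, None, y1, pf.mu1)
            star_corr.append(np.corrcoef(resid.e, g)[0, 1])
            naive_corr.append(np.corrcoef(y2 - y2.mean(), g)[0, 1])
        star_corr, naive_corr = np.array(star_corr), np.array(naive_corr)
        se = star_corr.std(ddof=1) / np.sqrt(star_corr.size)
        assert abs(star_corr.mean()) < 3 * se
        # naive bias carries sign(tau * beta_p): carriers of a +primary allele
        # are over-represented in the upper tail, where y2 is high
        assert naive_corr.mean() > 3 * naive_corr.std(ddof=1) / np.sqrt(naive_corr.size)

    def test_joint_fit_reports_parameters(self, rng):
        y1, y2, g, region = _simulate_selected(rng, n_cohort=20_000, n_sel=1_000)
        fit, resid = fit_null_joint(y1, y2, None, None, g, region)
        assert fit.sigma1_hat > 0 and fit.sigma_cond_hat > 0
        assert fit.converged
        assert 0.3 < fit.tau_hat < 0.9
        assert resid.e.size == 1_000


class TestNaiveBias:
    def test_exact_zeros(self):
        assert naive_bias(0.5, 0.0) == 0.0
        assert naive_bias(0.0, 0.6) == 0.0

    def test_odd_in_rho(self):
        b = naive_bias(0.5, 0.6, coding_variance=0.5)
        assert naive_bias(0.5, -0.6, coding_variance=0.5) == pytest.approx(-b, rel=1e-12)

    def test_approximately_linear_in_small_beta(self):
        # rare-variant coding scale: deviation from the secant through the
        # origin and beta_p=0.5 stays under 10%
        v = 0.02
        b_half = naive_bias(0.5, 0.6, coding_variance=v)
        for b in (0.1, 0.25, 0.4):
            secant = b_half * b / 0.5
            assert abs(naive_bias(b, 0.6, coding_variance=v) - secant) < 0.10 * abs(secant)

    def test_against_monte_carlo_oracle(self):
        # brute force: simulate the cohort, select the 5% tails, fit the
        # naive OLS slope of y2 on the coding under the true null
        rng = np.random.default_rng(6)
        n = 10_000_000
        x = rng.standard_normal(n)
        e1 = rng.standard_normal(n)
        y1 = 0.5 * x + e1
        y2 = 0.6 * e1 + np.sqrt(1 - 0.36) * rng.standard_normal(n)
        lo, hi = np.quantile(y1, [0.05, 0.95])
        sel = (y1 <= lo) | (y1 >= hi)
        xs, ys = x[sel], y2[sel]
        xs = xs - xs.mean()
        oracle = xs @ ys / (xs @ xs)
        assert naive_bias(0.5, 0.6, 0.05, 0.95, 1.0) == pytest.approx(oracle, rel=0.02)

    def test_standard_adjustments_do_not_remove_bias(self):
        # tail-stratified analysis and a tail-indicator covariate both keep
        # a non-zero asymptotic bias when beta_p != 0 and rho != 0
        rng = np.random.default_rng(7)
        n = 2_000_000
        x = rng.standard_normal(n)
        e1 = rng.standard_normal(n)
        y1 = 0.5 * x + e1
        y2 = 0.6 * e1 + 0.8 * rng.standard_normal(n)
        lo, hi = np.quantile(y1, [0.05, 0.95])
        low, high = y1 <= lo, y1 >= hi

        def ols_slope(mask):
            xs = x[mask] - x[mask].mean()
            return xs @ y2[mask] / (xs @ xs), xs @ xs

        b_lo, w_lo = ols_slope(low)
        b_hi, w_hi = ols_slope(high)
        meta = (w_lo * b_lo + w_hi * b_hi) / (w_lo + w_hi)
        sel = low | high
        D = np.column_stack([np.ones(sel.sum()), high[sel].astype(float), x[sel]])
        covar = np.linalg.lstsq(D, y2[sel], rcond=None)[0][2]
        se = 1.0 / np.sqrt(w_lo + w_hi)  # rough scale of the estimates
        assert abs(meta) > 5 * se
        assert abs(covar) > 5 * se

    def test_input_validation(self):
        with pytest.raises(ValueError):
            naive_bias(0.5, 0.6, 0.9, 0.1)
        with pytest.raises(ValueError):
            naive_bias(0.5, 0.6, coding_variance=0.0)
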