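"""Meta-correlation, meta-regression and the predicted upper confidence limit."""

import math

import numpy as np
import pandas as pd
import pytest

from stageshift import (
    InsufficientDataError,
    RegressionFit,
    SingularDesignError,
    analyze_meta,
    fit_meta_regression,
    pearson_correlation,
    predicted_upper_ci,
)
from stageshift.meta import Z_975


def trial_frame(x, y, v=None, n_per_arm=50_000, adjusted=None) -> pd.DataFrame:
    x = np.asarray(x, dtype=float)
    v = np.full(x.size, 0.01) if v is None else np.asarray(v, dtype=float)
    return pd.DataFrame({
        "log_rr_advanced": x,
        "log_rr_mortality": np.asarray(y, dtype=float),
        "var_log_rr_mortality": v,
        "n_per_arm": np.full(x.size, n_per_arm),
        "zero_cell_adjusted": np.zeros(x.size, bool) if adjusted is None else adjusted,
    })


FIXTURE_X = np.array([-0.30, -0.22, -0.10, 0.00, 0.08])
FIXTURE_Y = np.array([-0.25, -0.10, -0.12, 0.02, 0.03])
FIXTURE_V = np.array([0.020, 0.010, 0.015, 0.008, 0.012])


def normal_equations(x, y, w=None):
    """Brute-force (weighted) least-squares oracle: solve X'WX b = X'Wy and
    return (alpha, beta, covariance) with cov = sigma2 * (X'WX)^-1,
    sigma2 = weighted RSS / (n - 2)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    w = np.ones_like(x) if w is None else np.asarray(w, float)
    X = np.column_stack([np.ones_like(x), x])
    XtWX = X.T @ (w[:, None] * X)
    XtWy = X.T @ (w * y)
    beta = np.linalg.solve(XtWX, XtWy)
    resid = y - X @ beta
    sigma2 = (w * resid**2).sum() / (x.size - 2)
    return beta[0], beta[1], sigma2 * np.linalg.inv(XtWX)


class TestPearsonCorrelation:
    def test_perfect_collinearity(self):
        x = np.array([-0.2, 0.0, 0.3, 0.5])
        assert pearson_correlation(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_correlation(x, -2 * x + 1) == pytest.approx(-1.0)

    def test_equal_weights_reduce_to_unweighted(self):
        r_u = pearson_correlation(FIXTURE_X, FIXTURE_Y)
        r_w = pearson_correlation(FIXTURE_X, FIXTURE_Y, weights=np.full(5, 3.7))
        assert r_w == pytest.approx(r_u, rel=1e-12)

    def test_matches_moment_oracle(self):
        xs = np.array([-0.2, -0.1, 0.0, 0.1])
        ys = np.array([-0.15, -0.12, 0.02, 0.05])
        mx, my = xs.mean(), ys.mean()
        r_expect = ((xs - mx) * (ys - my)).sum() / math.sqrt(
            ((xs - mx) ** 2).sum() * ((ys - my) ** 2).sum())
        assert pearson_correlation(xs, ys) == pytest.approx(r_expect, rel=1e-12)

    def test_weighted_matches_moment_oracle(self):
        w = 1.0 / FIXTURE_V
        wn = w / w.sum()
        mx, my = wn @ FIXTURE_X, wn @ FIXTURE_Y
        cov = wn @ ((FIXTURE_X - mx) * (FIXTURE_Y - my))
        r_expect = cov / math.sqrt((wn @ (FIXTURE_X - mx) ** 2) * (wn @ (FIXTURE_Y - my) ** 2))
        assert pearson_correlation(FIXTURE_X, FIXTURE_Y, weights=w) == pytest.approx(
            r_expect, rel=1e-12)

    def test_zero_variance_is_nan_sentinel(self):
        assert math.isnan(pearson_correlation([1.0, 1.0, 1.0], [0.1, 0.2, 0.3]))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            pearson_correlation([0.1, 0.2], [0.1, 0.2])


class TestFitMetaRegression:
    def test_ols_matches_normal_equations(self):
        fit = fit_meta_regression(trial_frame(FIXTURE_X, FIXTURE_Y, FIXTURE_V))
        a, b, cov = normal_equations(FIXTURE_X, FIXTURE_Y)
        assert fit.alpha_hat == pytest.approx(a, rel=1e-10)
        assert fit.beta_hat == pytest.approx(b, rel=1e-10)
        assert fit.var_alpha == pytest.approx(cov[0, 0], rel=1e-10)
        assert fit.var_beta == pytest.approx(cov[1, 1], rel=1e-10)
        assert fit.cov_alpha_beta == pytest.approx(cov[0, 1], rel=1e-10)

    def test_wls_matches_normal_equations(self):
        fit = fit_meta_regression(trial_frame(FIXTURE_X, FIXTURE_Y, FIXTURE_V), weighted=True)
        a, b, cov = normal_equations(FIXTURE_X, FIXTURE_Y, w=1.0 / FIXTURE_V)
        assert fit.weighted
        assert fit.alpha_hat == pytest.approx(a, rel=1e-10)
        assert fit.beta_hat == pytest.approx(b, rel=1e-10)
        assert fit.var_beta == pytest.approx(cov[1, 1], rel=1e-10)
        assert fit.cov_alpha_beta == pytest.approx(cov[0, 1], rel=1e-10)

    def test_collinear_points_have_zero_variance(self):
        x = np.array([-0.2, 0.0, 0.2])
        fit = fit_meta_regression(trial_frame(x, 0.5 * x - 0.01))
        assert fit.beta_hat == pytest.approx(0.5)
        assert fit.var_alpha == pytest.approx(0.0, abs=1e-15)
        assert fit.var_beta == pytest.approx(0.0, abs=1e-15)

    def test_constant_response_gives_zero_slope(self):
        fit = fit_meta_regression(trial_frame([-0.2, 0.0, 0.1, 0.3], [0.05] * 4))
        assert fit.beta_hat == pytest.approx(0.0, abs=1e-14)

    def test_too_few_trials_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_meta_regression(trial_frame([0.1, 0.2], [0.1, 0.2]))

    def test_singular_design_rejected(self):
        with pytest.raises(SingularDesignError):
            fit_meta_regression(trial_frame([0.1] * 4, [0.0, 0.1, 0.2, 0.3]))

    def test_covariance_is_valid(self):
        fit = fit_meta_regression(trial_frame(FIXTURE_X, FIXTURE_Y))
        assert fit.var_alpha >= 0 and fit.var_beta >= 0
        assert abs(fit.cov_alpha_beta) <= math.sqrt(fit.var_alpha * fit.var_beta) + 1e-15


class TestPredictedUpperCI:
    def fit(self, **kw):
        base = dict(alpha_hat=0.0, beta_hat=1.0, var_alpha=0.0, var_beta=0.0,
                    cov_alpha_beta=0.0, n_trials=10, weighted=False)
        base.update(kw)
        return RegressionFit(**base)

    def test_point_prediction_limit(self):
        assert predicted_upper_ci(self.fit(), 0.85) == pytest.approx(0.85, rel=1e-12)

    def test_unit_surrogate_rr(self):
        assert predicted_upper_ci(self.fit(beta_hat=-3.0), 1.0) == pytest.approx(1.0)

    def test_closed_form_with_intercept_variance(self):
        uci = predicted_upper_ci(self.fit(beta_hat=0.0, var_alpha=0.01), 0.85)
        assert uci == pytest.approx(math.exp(Z_975 * 0.1), rel=1e-10)

    def test_full_formula_arithmetic(self):
        fit = self.fit(alpha_hat=-0.01, beta_hat=0.8, var_alpha=0.004,
                       var_beta=0.02, cov_alpha_beta=0.005)
        lr = math.log(0.85)
        expect = math.exp(-0.01 + 0.8 * lr
                          + Z_975 * math.sqrt(0.004 + 2 * 0.005 * lr + 0.02 * lr**2))
        assert predicted_upper_ci(fit, 0.85) == pytest.approx(expect, rel=1e-12)

    def test_monotone_in_each_variance_term(self):
        base = self.fit(var_alpha=0.01, var_beta=0.01, cov_alpha_beta=0.0)
        u0 = predicted_upper_ci(base)
        assert predicted_upper_ci(self.fit(var_alpha=0.02, var_beta=0.01)) > u0
        assert predicted_upper_ci(self.fit(var_alpha=0.01, var_beta=0.02)) > u0

    def test_bad_surrogate_rr_rejected(self):
        with pytest.raises(ValueError):
            predicted_upper_ci(self.fit(), 1.5)


class TestAnalyzeMeta:
    def test_composition_of_component_operations(self):
        """analyze_meta must equal running correlation, regression and the
        CI formula independently on the same trials."""
        frame = trial_frame(FIXTURE_X, FIXTURE_Y, FIXTURE_V)
        res = analyze_meta(frame)
        assert res.corr_unweighted == pytest.approx(
            pearson_correlation(FIXTURE_X, FIXTURE_Y), rel=1e-12)
        assert res.corr_weighted == pytest.approx(
            pearson_correlation(FIXTURE_X, FIXTURE_Y, weights=1 / FIXTURE_V), rel=1e-12)
        fit = fit_meta_regression(frame)
        assert res.fit == fit
        assert res.upper_ci_at_085 == pytest.approx(predicted_upper_ci(fit, 0.85), rel=1e-12)
        assert (res.n_trials_used, res.n_trials_dropped) == (5, 0)

    def test_size_cap_filter_can_exhaust_trials(self):
        frame = trial_frame(FIXTURE_X, FIXTURE_Y, n_per_arm=60_000)
        with pytest.raises(InsufficientDataError, match="25000"):
            analyze_meta(frame, small_trial_cap=25_000)

    def test_undefined_log_rr_dropped_and_counted(self):
        x = np.append(FIXTURE_X, np.nan)
        y = np.append(FIXTURE_Y, 0.1)
        v = np.append(FIXTURE_V, 0.01)
        res = analyze_meta(trial_frame(x, y, v))
        assert (res.n_trials_used, res.n_trials_dropped) == (5, 1)

    def test_zero_cell_drop_option(self):
        adjusted = np.array([False, False, False, False, True])
        res = analyze_meta(trial_frame(FIXTURE_X, FIXTURE_Y, FIXTURE_V, adjusted=adjusted),
                           zero_cell="drop")
        assert (res.n_trials_used, res.n_trials_dropped) == (4, 1)

    def test_weighted_equals_unweighted_with_equal_variances(self):
        frame = trial_frame(FIXTURE_X, FIXTURE_Y, v=np.full(5, 0.01))
        res = analyze_meta(frame)
        assert res.corr_weighted == pytest.approx(res.corr_unweighted, rel=1e-12)
        fit_w = analyze_meta(frame, weighted=True).fit
        assert fit_w.beta_hat == pytest.approx(res.fit.beta_hat, rel=1e-10)
        assert fit_w.var_beta == pytest.approx(res.fit.var_beta, rel=1e-10)


class TestParameterRecovery:
    def test_regression_recovers_known_relationship(self):
        """Synthetic trials generated from y = alpha + beta*x + noise recover
        (alpha, beta) within Monte-Carlo tolerance."""
        rng = np.random.default_rng(17)
        alpha, beta, n = -0.02, 0.6, 400
        x = rng.normal(-0.2, 0.15, n)
        y = alpha + beta * x + rng.normal(0, 0.05, n)
        fit = fit_meta_regression(trial_frame(x, y, np.full(n, 0.0025)))
        assert fit.alpha_hat == pytest.approx(alpha, abs=3 * math.sqrt(fit.var_alpha))
        assert fit.beta_hat == pytest.approx(beta, abs=3 * math.sqrt(fit.var_beta))
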