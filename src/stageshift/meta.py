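"""Trial-level meta-analysis of the surrogate and true endpoints.

Across a set of trials, the screening effect on each endpoint is summarised
by a log relative risk; trial-level surrogacy is then probed with

* the Pearson correlation between the two log relative risks (unweighted,
  and weighted by inverse variance of the mortality log RR as a
  sensitivity analysis), and
* a linear meta-regression of the mortality log RR on the advanced-stage
  log RR, from which the upper 95% confidence limit of the expected
  mortality relative risk at a given surrogate relative risk (default
  0.85) is predicted:

      exp{ a + b*ln(r) + z_0.975 * sqrt(va + 2*cab*ln(r) + vb*ln(r)^2) }

  where (a, b) are the fitted intercept and slope, (va, vb, cab) their
  estimated variances and covariance, and z_0.975 = 1.959964.  This is a
  confidence interval for the regression mean, not a prediction interval
  for a single new trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "Z_975",
    "RegressionFit",
    "MetaAnalysisResult",
    "MetaError",
    "InsufficientDataError",
    "SingularDesignError",
    "pearson_correlation",
    "fit_meta_regression",
    "predicted_upper_ci",
    "analyze_meta",
]

#: 97.5% standard-normal quantile, as printed in the CI formula.
Z_975 = 1.959964


class MetaError(ValueError):
    """Base class for meta-analysis input errors."""


class InsufficientDataError(MetaError):
    """Fewer than three usable trials remain after filtering."""


class SingularDesignError(MetaError):
    """All surrogate log RRs identical; the slope is not identified."""


@dataclass(frozen=True)
class RegressionFit:
    """Intercept/slope of log RR mortality on log RR advanced, with covariance."""

    alpha_hat: float
    beta_hat: float
    var_alpha: float
    var_beta: float
    cov_alpha_beta: float
    n_trials: int
    weighted: bool


@dataclass(frozen=True)
class MetaAnalysisResult:
    """Correlations, regression fit and predicted upper CI for one trial set."""

    corr_unweighted: float
    corr_weighted: float
    fit: RegressionFit
    upper_ci_at_085: float
    n_trials_used: int
    n_trials_dropped: int


def pearson_correlation(xs, ys, weights=None) -> float:
    """Pearson correlation of paired values, optionally weighted.

    The weighted variant uses weighted first and second moments (weights
    normalised to sum 1); with equal weights it reduces exactly to the
    unweighted correlation.  Returns NaN if either coordinate has zero
    variance.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise MetaError("xs and ys must be 1-d and the same length")
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 pairs, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise MetaError("xs and ys must be finite")
    if weights is None:
        w = np.full(x.size, 1.0 / x.size)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != x.shape or np.any(w <= 0) or not np.isfinite(w).all():
            raise MetaError("weights must be positive, finite and match xs")
        w = w / w.sum()
    mx, my = w @ x, w @ y
    cov = w @ ((x - mx) * (y - my))
    vx = w @ ((x - mx) ** 2)
    vy = w @ ((y - my) ** 2)
    if vx <= 0 or vy <= 0:
        return math.nan
    return float(cov / math.sqrt(vx * vy))


def _endpoint_arrays(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = trials["log_rr_advanced"].to_numpy(dtype=float)
    y = trials["log_rr_mortality"].to_numpy(dtype=float)
    v = trials["var_log_rr_mortality"].to_numpy(dtype=float)
    return x, y, v


def fit_meta_regression(trials: pd.DataFrame, weighted: bool = False) -> RegressionFit:
    """OLS (or inverse-variance WLS) fit of log RR mortality on log RR advanced.

    Returns coefficient estimates together with the full 2x2 covariance of
    (intercept, slope), which the predicted-CI formula needs.  Weights are
    ``1 / var(log RR mortality)``.
    """
    x, y, v = _endpoint_arrays(trials)
    if x.size < 3:
        raise InsufficientDataError(f"meta-regression needs >= 3 trials, got {x.size}")
    if np.ptp(x) == 0:
        raise SingularDesignError("all advanced-stage log RRs are identical")
    X = sm.add_constant(x)
    if weighted:
        if np.any(v <= 0) or not np.isfinite(v).all():
            raise MetaError("weighted fit requires positive finite mortality variances")
        res = sm.WLS(y, X, weights=1.0 / v).fit()
    else:
        res = sm.OLS(y, X).fit()
    cov = res.cov_params()
    cov = cov.to_numpy() if hasattr(cov, "to_numpy") else np.asarray(cov)
    return RegressionFit(
        alpha_hat=float(res.params[0]),
        beta_hat=float(res.params[1]),
        var_alpha=float(cov[0, 0]),
        var_beta=float(cov[1, 1]),
        cov_alpha_beta=float(cov[0, 1]),
        n_trials=int(x.size),
        weighted=weighted,
    )


def predicted_upper_ci(fit: RegressionFit, rr_surrogate: float = 0.85) -> float:
    """Upper 95% confidence limit of the expected mortality RR at a surrogate RR.

    Evaluates ``exp(a + b*ln(r) + z_0.975*sqrt(va + 2*cab*ln(r) + vb*ln(r)^2))``.
    The variance expression is the delta-method variance of the fitted mean
    at ``ln(r)``; a negative value (possible only through numerical
    degeneracy of the supplied covariance) raises.
    """
    if not (0 < rr_surrogate <= 1):
        raise MetaError(f"rr_surrogate must be in (0, 1], got {rr_surrogate}")
    lr = math.log(rr_surrogate)
    var = fit.var_alpha + 2 * fit.cov_alpha_beta * lr + fit.var_beta * lr * lr
    if var < 0:
        if var > -1e-12:  # roundoff from an exactly singular fit
            var = 0.0
        else:
            raise MetaError(f"negative variance expression ({var}) at rr_surrogate={rr_surrogate}")
    return math.exp(fit.alpha_hat + fit.beta_hat * lr + Z_975 * math.sqrt(var))


def analyze_meta(
    trials: pd.DataFrame,
    rr_surrogate: float = 0.85,
    weighted: bool = False,
    small_trial_cap: int | None = None,
    zero_cell: str = "adjust",
) -> MetaAnalysisResult:
    """Full trial-level meta-analysis of one set of simulated trials.

    Applies the optional per-arm size cap, drops trials whose log RRs are
    undefined (and, with ``zero_cell="drop"``, any zero-cell-adjusted
    trial), then computes both correlations, the regression fit and the
    predicted upper CI at ``rr_surrogate``.
    """
    if zero_cell not in ("adjust", "drop"):
        raise MetaError(f"zero_cell must be 'adjust' or 'drop', got {zero_cell!r}")
    if len(trials) == 0:
        raise InsufficientDataError("empty trial set")
    n_total = len(trials)
    if small_trial_cap is not None:
        trials = trials[trials["n_per_arm"] <= small_trial_cap]
        if len(trials) < 3:
            raise InsufficientDataError(
                f"fewer than 3 trials with n_per_arm <= {small_trial_cap} "
                f"({len(trials)} of {n_total})"
            )
    x, y, v = _endpoint_arrays(trials)
    usable = np.isfinite(x) & np.isfinite(y) & np.isfinite(v) & (v > 0)
    if zero_cell == "drop":
        usable &= ~trials["zero_cell_adjusted"].to_numpy(dtype=bool)
    trials = trials[usable]
    n_used = len(trials)
    if n_used < 3:
        raise InsufficientDataError(
            f"fewer than 3 usable trials after dropping undefined/zero-cell log RRs "
            f"({n_used} of {n_total})"
        )
    x, y, v = _endpoint_arrays(trials)
    fit = fit_meta_regression(trials, weighted=weighted)
    return MetaAnalysisResult(
        corr_unweighted=pearson_correlation(x, y),
        corr_weighted=pearson_correlation(x, y, weights=1.0 / v),
        fit=fit,
        upper_ci_at_085=predicted_upper_ci(fit, rr_surrogate),
        n_trials_used=n_used,
        n_trials_dropped=n_total - n_used,
    )
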