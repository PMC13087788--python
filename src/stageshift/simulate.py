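"""Stochastic simulation of screening-trial outcomes and per-trial statistics.

Each simulated trial draws one shared cohort per arm: participants fall
into diagnosis categories via a multinomial draw and deaths are then drawn
binomially conditional on the realised stage counts.  Because the mortality
endpoint is generated from the same realised stage counts as the stage
endpoint, the two endpoints are correlated within a trial even under the
null — the mechanism behind the non-zero trial-level meta-correlations of
an invalid surrogate.

Per-trial inference uses a pooled two-proportion Z-test without continuity
correction (two-sided p from the normal approximation) and log relative
risks with the standard delta-method variance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .presets import SitePreset
from .scenario import ScenarioSpec, TrialParameters, draw_trial_parameters

__all__ = [
    "ArmCounts",
    "TrialSummary",
    "two_proportion_z",
    "log_rr_with_variance",
    "simulate_trial",
    "simulate_trials",
    "simulate_trial_batch",
    "write_batch",
]


def two_proportion_z(x1, n1, x2, n2):
    """Pooled two-proportion Z-test without continuity correction.

    Returns ``(z, p_two_sided)`` with
    ``z = (x1/n1 - x2/n2) / sqrt(phat(1-phat)(1/n1 + 1/n2))`` and pooled
    ``phat = (x1+x2)/(n1+n2)``; negative z means fewer events in arm 1.
    When the pooled proportion is 0 or 1 the test is undefined and a NaN
    sentinel is returned for both values.  Accepts scalars or arrays.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any((x1 < 0) | (x1 > n1) | (x2 < 0) | (x2 > n2)):
        raise ValueError("counts must satisfy 0 <= x_i <= n_i")
    pooled = (x1 + x2) / (n1 + n2)
    defined = (pooled > 0) & (pooled < 1)
    se = np.sqrt(np.where(defined, pooled * (1 - pooled) * (1 / n1 + 1 / n2), np.nan))
    z = np.where(defined, (x1 / n1 - x2 / n2) / se, np.nan)
    p = np.where(defined, 2 * stats.norm.sf(np.abs(z)), np.nan)
    if z.ndim == 0:
        return float(z), float(p)
    return z, p


def log_rr_with_variance(x1, n1, x2, n2, zero_rule: str = "haldane"):
    """Log relative risk (arm 1 vs arm 2) with its delta-method variance.

    ``log RR = log((x1/n1)/(x2/n2))``; ``var = 1/x1 - 1/n1 + 1/x2 - 1/n2``.
    If either numerator is zero the configured ``zero_rule`` applies:
    ``"haldane"`` (default) adds 0.5 to both numerators and 1 to both
    denominators; ``"none"`` returns NaN for the affected trials.  Returns
    ``(log_rr, var, adjusted_flag)``; accepts scalars or arrays.
    """
    if zero_rule not in ("haldane", "none"):
        raise ValueError(f"zero_rule must be 'haldane' or 'none', got {zero_rule!r}")
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any((n1 <= 0) | (n2 <= 0)):
        raise ValueError("n_i must be positive")
    if np.any((x1 < 0) | (x1 > n1) | (x2 < 0) | (x2 > n2)):
        raise ValueError("counts must satisfy 0 <= x_i <= n_i")
    adjusted = (x1 == 0) | (x2 == 0)
    if zero_rule == "haldane":
        a1 = np.where(adjusted, x1 + 0.5, x1)
        a2 = np.where(adjusted, x2 + 0.5, x2)
        d1 = np.where(adjusted, n1 + 1.0, n1)
        d2 = np.where(adjusted, n2 + 1.0, n2)
    else:
        a1 = np.where(adjusted, np.nan, x1)
        a2 = np.where(adjusted, np.nan, x2)
        d1, d2 = n1, n2
    with np.errstate(invalid="ignore", divide="ignore"):
        log_rr = np.log((a1 / d1) / (a2 / d2))
        var = 1 / a1 - 1 / d1 + 1 / a2 - 1 / d2
    if log_rr.ndim == 0:
        return float(log_rr), float(var), bool(adjusted)
    return log_rr, var, adjusted


@dataclass(frozen=True)
class ArmCounts:
    """Realised diagnosis and death counts for one arm of one trial."""

    n: int
    count_advanced: int
    count_early: int        # early at diagnosis; includes down-staged cancers
    count_down_staged: int
    count_deaths: int


@dataclass(frozen=True)
class TrialSummary:
    """One simulated trial: per-arm counts plus both endpoints' statistics."""

    params: TrialParameters
    screening: ArmCounts
    control: ArmCounts
    log_rr_mortality: float
    var_log_rr_mortality: float
    log_rr_advanced: float
    var_log_rr_advanced: float
    z_mortality: float
    z_advanced: float
    p_two_sided_mortality: float
    p_two_sided_advanced: float
    favors_screening_mortality: bool
    favors_screening_advanced: bool
    zero_cell_adjusted: bool


_COLUMNS = [
    "site", "scenario", "n_per_arm", "p_a", "p_e", "theta", "f_a", "f_e",
    "adv_screen", "down_staged_screen", "early_screen", "deaths_screen",
    "adv_control", "early_control", "deaths_control",
    "log_rr_advanced", "var_log_rr_advanced",
    "log_rr_mortality", "var_log_rr_mortality",
    "z_advanced", "p_advanced", "z_mortality", "p_mortality",
    "favors_screening_advanced", "favors_screening_mortality",
    "zero_cell_adjusted",
]


def simulate_trials(params: list[TrialParameters], rng: np.random.Generator,
                    zero_rule: str = "haldane") -> pd.DataFrame:
    """Vectorised shared-cohort simulation of explicit trial designs.

    Unlike :func:`simulate_trial_batch` this does not draw designs from a
    preset: every trial's parameters are supplied (repeats allowed, e.g.
    for Monte-Carlo replicates at fixed parameters).  Returns one row per
    trial.
    """
    n = np.array([p.n_per_arm for p in params], dtype=np.int64)
    p_a = np.array([p.p_a for p in params])
    p_e = np.array([p.p_e for p in params])
    theta = np.array([p.theta for p in params])
    f_a = np.array([p.f_a for p in params])
    f_e = np.array([p.f_e for p in params])
    invalid = np.array([p.scenario_id == "invalid" for p in params])

    # control arm: three diagnosis categories
    pv_c = np.stack([p_a, p_e, 1 - p_a - p_e], axis=-1)
    if np.any(pv_c < 0):
        raise ValueError("category probabilities outside the simplex")
    counts_c = rng.multinomial(n, pv_c)
    adv_c, early_c = counts_c[:, 0], counts_c[:, 1]
    deaths_c = rng.binomial(adv_c, f_a) + rng.binomial(early_c, f_e)

    # screening arm: advanced, down-staged, early, none
    pv_s = np.stack([theta * p_a, (1 - theta) * p_a, p_e, 1 - p_a - p_e], axis=-1)
    if np.any(pv_s < 0):
        raise ValueError("category probabilities outside the simplex")
    counts_s = rng.multinomial(n, pv_s)
    adv_s, down_s, early_s = counts_s[:, 0], counts_s[:, 1], counts_s[:, 2]
    # down-staged cancers keep advanced-stage fatality only when the
    # surrogate is invalid
    f_down = np.where(invalid, f_a, f_e)
    deaths_s = rng.binomial(adv_s, f_a) + rng.binomial(down_s, f_down) + rng.binomial(early_s, f_e)

    lr_adv, v_adv, adj_adv = log_rr_with_variance(adv_s, n, adv_c, n, zero_rule)
    lr_mor, v_mor, adj_mor = log_rr_with_variance(deaths_s, n, deaths_c, n, zero_rule)
    z_adv, p_adv = two_proportion_z(adv_s, n, adv_c, n)
    z_mor, p_mor = two_proportion_z(deaths_s, n, deaths_c, n)

    return pd.DataFrame({
        "site": [p.site_name for p in params],
        "scenario": [p.scenario_id for p in params],
        "n_per_arm": n, "p_a": p_a, "p_e": p_e, "theta": theta, "f_a": f_a, "f_e": f_e,
        "adv_screen": adv_s, "down_staged_screen": down_s,
        "early_screen": early_s + down_s, "deaths_screen": deaths_s,
        "adv_control": adv_c, "early_control": early_c, "deaths_control": deaths_c,
        "log_rr_advanced": lr_adv, "var_log_rr_advanced": v_adv,
        "log_rr_mortality": lr_mor, "var_log_rr_mortality": v_mor,
        "z_advanced": z_adv, "p_advanced": p_adv,
        "z_mortality": z_mor, "p_mortality": p_mor,
        "favors_screening_advanced": adv_s < adv_c,
        "favors_screening_mortality": deaths_s < deaths_c,
        "zero_cell_adjusted": adj_adv | adj_mor,
    }, columns=_COLUMNS)


def simulate_trial(params: TrialParameters, rng: np.random.Generator,
                   zero_rule: str = "haldane") -> TrialSummary:
    """Simulate one trial from its realised design parameters."""
    row = simulate_trials([params], rng, zero_rule).iloc[0]
    screening = ArmCounts(
        n=params.n_per_arm,
        count_advanced=int(row.adv_screen),
        count_early=int(row.early_screen),
        count_down_staged=int(row.down_staged_screen),
        count_deaths=int(row.deaths_screen),
    )
    control = ArmCounts(
        n=params.n_per_arm,
        count_advanced=int(row.adv_control),
        count_early=int(row.early_control),
        count_down_staged=0,
        count_deaths=int(row.deaths_control),
    )
    return TrialSummary(
        params=params,
        screening=screening,
        control=control,
        log_rr_mortality=float(row.log_rr_mortality),
        var_log_rr_mortality=float(row.var_log_rr_mortality),
        log_rr_advanced=float(row.log_rr_advanced),
        var_log_rr_advanced=float(row.var_log_rr_advanced),
        z_mortality=float(row.z_mortality),
        z_advanced=float(row.z_advanced),
        p_two_sided_mortality=float(row.p_mortality),
        p_two_sided_advanced=float(row.p_advanced),
        favors_screening_mortality=bool(row.favors_screening_mortality),
        favors_screening_advanced=bool(row.favors_screening_advanced),
        zero_cell_adjusted=bool(row.zero_cell_adjusted),
    )


def simulate_trial_batch(
    preset: SitePreset,
    scenario: ScenarioSpec,
    n_trials: int,
    rng: np.random.Generator,
    zero_rule: str = "haldane",
) -> pd.DataFrame:
    """Simulate a batch of independent trials from one site preset.

    Trial designs (per-arm size, P_a, theta) are re-drawn independently for
    every trial.  Returns one row per trial with counts and both endpoints'
    statistics; run metadata (preset, scenario, theta model, zero rule) is
    attached in ``DataFrame.attrs["meta"]``.  Deterministic given the rng
    state.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    params = draw_trial_parameters(preset, scenario, rng, n_trials)
    frame = simulate_trials(params, rng, zero_rule)
    frame.attrs["meta"] = {
        "site": preset.site_name,
        "scenario": scenario.scenario_id,
        "theta_range": list(scenario.theta_range),
        "n_trials": n_trials,
        "zero_rule": zero_rule,
    }
    return frame


def write_batch(frame: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    """Write a batch as tidy CSV (one row per trial per endpoint) + JSON sidecar."""
    path = Path(path)
    keep = ["site", "scenario", "n_per_arm", "p_a", "p_e", "theta", "f_a", "f_e",
            "zero_cell_adjusted"]
    rows = []
    for endpoint, prefix in (("advanced", "advanced"), ("mortality", "mortality")):
        events = "adv" if endpoint == "advanced" else "deaths"
        part = frame[keep].copy()
        part.insert(2, "endpoint", endpoint)
        part["events_screen"] = frame[f"{events}_screen"]
        part["events_control"] = frame[f"{events}_control"]
        part["log_rr"] = frame[f"log_rr_{prefix}"]
        part["var_log_rr"] = frame[f"var_log_rr_{prefix}"]
        part["z"] = frame[f"z_{prefix}"]
        part["p_two_sided"] = frame[f"p_{prefix}"]
        part["favors_screening"] = frame[f"favors_screening_{prefix}"]
        rows.append(part)
    tidy = pd.concat(rows).sort_index(kind="stable").reset_index(names="trial")
    tidy.to_csv(path, index=False)
    meta = dict(frame.attrs.get("meta", {}))
    if seed is not None:
        meta["seed"] = seed
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")
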