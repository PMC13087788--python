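"""Orchestration of the full simulation study.

Two experiment families are run over the site presets and surrogacy
scenarios:

* **power/size** — many independent trials per (site, scenario); the
  proportion rejecting the null in favour of screening gives the empirical
  power (under the alternatives) and the one-sided size (under the null,
  nominally 2.5%).
* **meta-analysis** — repeated meta-analyses of a small number of trials
  per site; the trial-level correlation between the two endpoints' log
  relative risks and the predicted upper 95% CI of the mortality RR at a
  surrogate RR of 0.85 are averaged over meta-replicates.

The "all combined" row pools trials across sites: for power/size it pools
the rejection tally; for the meta statistics it pools every site's trials
within a meta-replicate before computing the statistic (the correlation of
a pooled scatter is not the mean of per-site correlations).

Every table cell runs on its own deterministic random substream derived
from the master seed, so cells are independently re-runnable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .meta import InsufficientDataError, analyze_meta
from .presets import SitePreset, load_presets
from .scenario import DEFAULT_THETA_RANGE, SCENARIOS, ScenarioSpec
from .simulate import simulate_trial_batch

__all__ = ["ExperimentConfig", "run_power_size", "run_meta_experiment", "render_tables"]

_POWER_STREAM, _META_STREAM = 1, 2


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of a full simulation experiment.

    Defaults reproduce the study design: theta uniform on (0.55, 0.90)
    under the alternatives, 10 trials per meta-analysis, 1,000
    meta-replicates, 20,000 power/size replicates, surrogate RR 0.85.
    """

    presets: tuple[SitePreset, ...] = None  # type: ignore[assignment]
    scenarios: tuple[str, ...] = SCENARIOS
    n_trials_per_meta: int = 10
    n_meta_replicates: int = 1000
    n_power_replicates: int = 20_000
    theta_range: tuple[float, float] = DEFAULT_THETA_RANGE
    rr_surrogate: float = 0.85
    weighted: bool = False
    small_trial_cap: int | None = None
    zero_cell: str = "adjust"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.presets is None:
            object.__setattr__(self, "presets", tuple(load_presets()))
        for name in ("n_trials_per_meta", "n_meta_replicates", "n_power_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for s in self.scenarios:
            if s not in SCENARIOS:
                raise ValueError(f"unknown scenario {s!r}")

    def scenario_spec(self, scenario_id: str) -> ScenarioSpec:
        return ScenarioSpec(scenario_id, self.theta_range if scenario_id != "null" else (1.0, 1.0))

    def cell_rng(self, stream: int, preset_idx: int, scenario_idx: int) -> np.random.Generator:
        """Independent generator for one table cell, derived from the master seed."""
        return np.random.default_rng([self.seed, stream, preset_idx, scenario_idx])


def _binomial_se(p: float, n: int) -> float:
    return float(np.sqrt(max(p * (1 - p), 1e-12) / n))


def run_power_size(config: ExperimentConfig) -> pd.DataFrame:
    """Empirical rejection proportions per (site, scenario), plus pooled row.

    Each replicate is an independent trial with freshly drawn design
    parameters.  A rejection requires a two-sided p < 0.05 *and* fewer
    events in the screening arm; under the null this is the one-sided size
    (nominal 2.5%), under the alternatives the power.  Trials whose test is
    undefined (no events in either arm) count as non-rejections.
    """
    rows = []
    for k, scenario_id in enumerate(config.scenarios):
        spec = config.scenario_spec(scenario_id)
        pooled = {"mortality": 0, "advanced": 0, "n": 0}
        for j, preset in enumerate(config.presets):
            rng = config.cell_rng(_POWER_STREAM, j, k)
            frame = simulate_trial_batch(preset, spec, config.n_power_replicates, rng)
            rej = {}
            for endpoint in ("mortality", "advanced"):
                hit = (frame[f"p_{endpoint}"] < 0.05) & frame[f"favors_screening_{endpoint}"]
                rej[endpoint] = int(hit.fillna(False).sum())
                pooled[endpoint] += rej[endpoint]
            pooled["n"] += len(frame)
            rows.append({
                "site": preset.site_name, "scenario": scenario_id,
                "n_replicates": len(frame),
                "reject_mortality": rej["mortality"] / len(frame),
                "reject_advanced": rej["advanced"] / len(frame),
                "se_mortality": _binomial_se(rej["mortality"] / len(frame), len(frame)),
                "se_advanced": _binomial_se(rej["advanced"] / len(frame), len(frame)),
            })
        rows.append({
            "site": "all_combined", "scenario": scenario_id,
            "n_replicates": pooled["n"],
            "reject_mortality": pooled["mortality"] / pooled["n"],
            "reject_advanced": pooled["advanced"] / pooled["n"],
            "se_mortality": _binomial_se(pooled["mortality"] / pooled["n"], pooled["n"]),
            "se_advanced": _binomial_se(pooled["advanced"] / pooled["n"], pooled["n"]),
        })
    out = pd.DataFrame(rows)
    out.attrs["config"] = config
    return out


def _summarise_replicates(site: str, scenario_id: str, results: list, n_failed: int) -> dict:
    corr_u = np.array([r.corr_unweighted for r in results])
    corr_w = np.array([r.corr_weighted for r in results])
    uci = np.array([r.upper_ci_at_085 for r in results])
    ok_u, ok_w = np.isfinite(corr_u), np.isfinite(corr_w)
    n = len(results)
    return {
        "site": site, "scenario": scenario_id,
        "n_replicates": n, "n_replicates_failed": n_failed,
        "mean_corr_unweighted": float(np.mean(corr_u[ok_u])) if ok_u.any() else np.nan,
        "mean_corr_weighted": float(np.mean(corr_w[ok_w])) if ok_w.any() else np.nan,
        "mean_upper_ci": float(np.mean(uci)) if n else np.nan,
        "se_corr_unweighted": float(np.std(corr_u[ok_u], ddof=1) / np.sqrt(ok_u.sum())) if ok_u.sum() > 1 else np.nan,
        "se_upper_ci": float(np.std(uci, ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
        "mean_trials_dropped": float(np.mean([r.n_trials_dropped for r in results])) if n else np.nan,
    }


def run_meta_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Average meta-correlation and predicted upper CI per (site, scenario).

    For every scenario, each site contributes ``n_meta_replicates``
    meta-analyses of ``n_trials_per_meta`` trials.  The all-combined row
    re-analyses, within each replicate, the union of all sites' trials for
    that replicate.  Replicates where the meta-analysis is undefined (e.g.
    too few usable trials after filtering) are counted and reported, never
    silently dropped.
    """
    rows = []
    for k, scenario_id in enumerate(config.scenarios):
        spec = config.scenario_spec(scenario_id)
        per_site_frames = []
        for j, preset in enumerate(config.presets):
            rng = config.cell_rng(_META_STREAM, j, k)
            n_total = config.n_meta_replicates * config.n_trials_per_meta
            frame = simulate_trial_batch(preset, spec, n_total, rng, zero_rule="haldane")
            frame["replicate"] = np.repeat(np.arange(config.n_meta_replicates),
                                           config.n_trials_per_meta)
            per_site_frames.append(frame)
            results, n_failed = [], 0
            for _, sub in frame.groupby("replicate", sort=True):
                try:
                    results.append(analyze_meta(sub, config.rr_surrogate, config.weighted,
                                                config.small_trial_cap, config.zero_cell))
                except InsufficientDataError:
                    n_failed += 1
            rows.append(_summarise_replicates(preset.site_name, scenario_id, results, n_failed))
        combined = pd.concat(per_site_frames, ignore_index=True)
        results, n_failed = [], 0
        for _, sub in combined.groupby("replicate", sort=True):
            try:
                results.append(analyze_meta(sub, config.rr_surrogate, config.weighted,
                                            config.small_trial_cap, config.zero_cell))
            except InsufficientDataError:
                n_failed += 1
        rows.append(_summarise_replicates("all_combined", scenario_id, results, n_failed))
    out = pd.DataFrame(rows)
    out.attrs["config"] = config
    return out


def _pivot(df: pd.DataFrame, value: str, columns: dict[str, str]) -> pd.DataFrame:
    """Site-by-scenario layout with a fixed site order."""
    order = [s for s in df["site"].unique() if s != "all_combined"] + ["all_combined"]
    wide = df.pivot(index="site", columns="scenario", values=value).reindex(order)
    wide = wide[[c for c in columns if c in wide.columns]].rename(columns=columns)
    wide.index.name = "site"
    return wide


def render_tables(power: pd.DataFrame, meta: pd.DataFrame, outdir: str | Path) -> dict[str, Path]:
    """Write the three result tables (CSV + aligned text) to ``outdir``.

    Layout mirrors the study's presentation: power and one-sided size per
    endpoint; mean trial-level correlation per scenario; mean upper 95% CI
    of the mortality RR at the surrogate RR.  Monte-Carlo standard errors
    are appended as extra columns.  Output is byte-deterministic for a
    given summary.
    """
    if len(power) == 0 or len(meta) == 0:
        raise ValueError("cannot render tables from an empty summary")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    pw = power[power["scenario"] == "valid_effective"].set_index("site")
    sz = power[power["scenario"] == "null"].set_index("site")
    t2 = pd.DataFrame({
        "power_mortality": pw["reject_mortality"],
        "power_advanced": pw["reject_advanced"],
        "size_mortality_one_sided": sz["reject_mortality"],
        "size_advanced_one_sided": sz["reject_advanced"],
        "se_power_mortality": pw["se_mortality"],
        "se_power_advanced": pw["se_advanced"],
        "se_size_mortality": sz["se_mortality"],
        "se_size_advanced": sz["se_advanced"],
    })

    t3 = _pivot(meta, "mean_corr_unweighted", {
        "valid_effective": "corr_valid_effective",
        "null": "corr_valid_null",
        "invalid": "corr_invalid",
    })
    for scen, col in (("valid_effective", "se_valid_effective"), ("null", "se_valid_null"),
                      ("invalid", "se_invalid")):
        sub = meta[meta["scenario"] == scen].set_index("site")["se_corr_unweighted"]
        if len(sub):
            t3[col] = sub

    t4 = _pivot(meta, "mean_upper_ci", {
        "valid_effective": "upper_ci_valid",
        "invalid": "upper_ci_invalid",
    })
    for scen, col in (("valid_effective", "se_valid"), ("invalid", "se_invalid")):
        sub = meta[meta["scenario"] == scen].set_index("site")["se_upper_ci"]
        if len(sub):
            t4[col] = sub

    for name, table in (("power_size", t2), ("correlation", t3), ("upper_ci", t4)):
        csv_path = outdir / f"table_{name}.csv"
        table.to_csv(csv_path, float_format="%.6f")
        txt_path = outdir / f"table_{name}.txt"
        txt_path.write_text(table.to_string(float_format=lambda v: f"{v:.4f}") + "\n")
        paths[name] = csv_path
    return paths
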