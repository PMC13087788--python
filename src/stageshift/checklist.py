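"""Go/no-go verification framework for a candidate surrogate endpoint.

Five evidence checks, each mapping pre-computed summary statistics to a
three-valued verdict (``go`` / ``no_go`` / ``indeterminate``):

1. **Stage-specific survival** — is advanced-stage disease materially more
   fatal than early-stage disease?
2. **Attributable mortality** — do advanced-stage cancers account for a
   substantial share of cancer deaths?
3. **Screen-detectability and prognosis** — is stage-specific survival
   similar in screen-detectable and non-detectable cancers?
4. **Trial endpoint evidence** — do the trial's surrogate and predicted-
   mortality results jointly support a benefit?
5. **Modelled benefit** — does the modelled mortality effect reach a
   clinically meaningful reduction?

The published go and no-go clauses are heuristic and deliberately do not
partition the input space, hence the explicit ``indeterminate`` outcome.
Thresholds written with ``>=`` are inclusive; ``<`` is strict.  Two further
audit items (time-to-treatment, treatment quality) carry no verdict logic
and are represented as free-text audit records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "Verdict",
    "ChecklistVerdict",
    "FatalityContrast",
    "AttributableMortality",
    "DetectabilityRates",
    "TrialEvidence",
    "AuditRecord",
    "step1_survival_differential",
    "step2_attributable_mortality",
    "step3_detectability",
    "step4_trial_endpoint",
    "step5_modelled_benefit",
    "generate_checklist_fixtures",
]

Verdict = Literal["go", "no_go", "indeterminate"]


@dataclass(frozen=True)
class ChecklistVerdict:
    step: int
    verdict: str
    triggered_rule: str
    partial: bool = False  # some inputs missing; only evaluable clauses applied


def _prob(name: str, v: float) -> float:
    if not (0 <= v <= 1):
        raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
    return float(v)


@dataclass(frozen=True)
class FatalityContrast:
    """5-year net fatality of advanced vs not-advanced (early) stage disease."""

    fatality_advanced_5yr: float
    fatality_early_5yr: float

    def __post_init__(self) -> None:
        _prob("fatality_advanced_5yr", self.fatality_advanced_5yr)
        _prob("fatality_early_5yr", self.fatality_early_5yr)

    @property
    def difference(self) -> float:
        return self.fatality_advanced_5yr - self.fatality_early_5yr

    @property
    def ratio(self) -> float | None:
        if self.fatality_early_5yr <= 0:
            return None
        return self.fatality_advanced_5yr / self.fatality_early_5yr


@dataclass(frozen=True)
class AttributableMortality:
    """Proportion of cancer deaths (within 5 and 10 years) from advanced stage."""

    prop_deaths_from_advanced_5yr: float
    prop_deaths_from_advanced_10yr: float

    def __post_init__(self) -> None:
        _prob("prop_deaths_from_advanced_5yr", self.prop_deaths_from_advanced_5yr)
        _prob("prop_deaths_from_advanced_10yr", self.prop_deaths_from_advanced_10yr)


@dataclass(frozen=True)
class DetectabilityRates:
    """Death rates by stage and screen-detectability (events per person-time).

    All four rates must be in the same units.  ``min_followup_ok`` asserts
    at least one year of follow-up behind the rates.
    """

    rate_early_detectable: float
    rate_early_not_detectable: float
    rate_advanced_detectable: float
    rate_advanced_not_detectable: float
    min_followup_ok: bool = True

    def __post_init__(self) -> None:
        for name in ("rate_early_detectable", "rate_early_not_detectable",
                     "rate_advanced_detectable", "rate_advanced_not_detectable"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TrialEvidence:
    """Trial (or meta-analysis) results on the surrogate and predicted mortality.

    CIs are on the relative-risk scale.  Predicted-mortality fields may be
    None, in which case only the surrogate-side clauses are evaluated and
    the verdict is flagged partial.
    """

    p_advanced_2sided: float
    one_sided_p_advanced: float
    ci_surrogate: tuple[float, float]
    powered_reduction_rr: float
    p_predicted_mortality_2sided: float | None = None
    one_sided_p_predicted: float | None = None
    ci_predicted_mortality: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        _prob("p_advanced_2sided", self.p_advanced_2sided)
        _prob("one_sided_p_advanced", self.one_sided_p_advanced)
        if self.ci_surrogate[0] > self.ci_surrogate[1]:
            raise ValueError("ci_surrogate lower bound exceeds upper bound")
        if self.ci_predicted_mortality is not None and \
                self.ci_predicted_mortality[0] > self.ci_predicted_mortality[1]:
            raise ValueError("ci_predicted_mortality lower bound exceeds upper bound")
        if self.p_predicted_mortality_2sided is not None:
            _prob("p_predicted_mortality_2sided", self.p_predicted_mortality_2sided)
        if self.one_sided_p_predicted is not None:
            _prob("one_sided_p_predicted", self.one_sided_p_predicted)


@dataclass(frozen=True)
class AuditRecord:
    """Audit item without verdict logic (steps 6–7: treatment timeliness/quality)."""

    step: int
    description: str
    notes: str = ""


def step1_survival_differential(inp: FatalityContrast) -> ChecklistVerdict:
    """Stage-specific survival differential.

    Go: difference >= 0.30, or (difference >= 0.10 and ratio >= 2).
    No-go: difference < 0.10 and ratio < 2.
    """
    d, r = inp.difference, inp.ratio
    if d >= 0.30:
        return ChecklistVerdict(1, "go", "difference in 5-year net fatality >= 30%")
    if r is not None and d >= 0.10 and r >= 2:
        return ChecklistVerdict(1, "go", "difference >= 10% and relative fatality >= 2")
    if r is None:
        # early fatality 0: ratio undefined; difference alone cannot trigger
        # the remaining clauses
        return ChecklistVerdict(1, "indeterminate",
                                "fatality ratio undefined (early-stage fatality is 0) "
                                "and difference < 30%")
    if d < 0.10 and r < 2:
        return ChecklistVerdict(1, "no_go", "difference < 10% and ratio < 2")
    return ChecklistVerdict(1, "indeterminate", "between go and no-go clause boundaries")


def step2_attributable_mortality(inp: AttributableMortality) -> ChecklistVerdict:
    """Share of cancer deaths originating from advanced-stage cancers.

    Go: 5-year proportion >= 0.50.  No-go: both 5- and 10-year < 0.25.
    """
    if inp.prop_deaths_from_advanced_5yr >= 0.50:
        return ChecklistVerdict(2, "go", "proportion of 5-year cancer deaths from advanced stage >= 50%")
    if inp.prop_deaths_from_advanced_5yr < 0.25 and inp.prop_deaths_from_advanced_10yr < 0.25:
        return ChecklistVerdict(2, "no_go", "5- and 10-year proportions both < 25%")
    return ChecklistVerdict(2, "indeterminate", "between go and no-go clause boundaries")


def step3_detectability(inp: DetectabilityRates) -> ChecklistVerdict:
    """Prognostic significance of screen-detectability.

    No-go: the death rate in screen-detectable early-stage cancers is no
    better than in screen-detectable advanced-stage cancers.  Go: within
    each stage the detectable/not-detectable rate ratio is < 1.2 (and not
    no-go).
    """
    if not inp.min_followup_ok:
        raise ValueError("step 3 requires rates with at least 1-year follow-up")
    if inp.rate_early_detectable >= inp.rate_advanced_detectable:
        return ChecklistVerdict(3, "no_go",
                                "average death rate in screen-detectable early stage is "
                                "no better than in screen-detectable advanced stage")
    ratios = []
    for det, notdet in ((inp.rate_early_detectable, inp.rate_early_not_detectable),
                        (inp.rate_advanced_detectable, inp.rate_advanced_not_detectable)):
        if notdet == 0:
            if det > 0:
                return ChecklistVerdict(3, "indeterminate",
                                        "detectable/not-detectable rate ratio undefined "
                                        "(zero rate in not-screen-detectable cancers)")
            ratios.append(0.0)  # 0/0: no deaths in either group of the stage
        else:
            ratios.append(det / notdet)
    if all(r < 1.2 for r in ratios):
        return ChecklistVerdict(3, "go", "each stage's screen-detectable death rate < 1.2x "
                                         "the not-screen-detectable rate")
    return ChecklistVerdict(3, "indeterminate", "a stage's rate ratio >= 1.2 but no-go clause not met")


def step4_trial_endpoint(inp: TrialEvidence) -> ChecklistVerdict:
    """Trial evidence on the surrogate and predicted-mortality endpoints.

    Go: either endpoint significant at two-sided p < 0.05 and both
    one-sided p < 0.2 in favour of screening.  No-go: the surrogate's 95%
    CI excludes any reduction (lower bound >= 1); or it excludes the
    reduction the trial was powered for (lower bound > powered RR) while
    the predicted-mortality CI excludes any reduction.  No-go takes
    precedence on contradictory inputs.
    """
    partial = inp.ci_predicted_mortality is None or inp.p_predicted_mortality_2sided is None \
        or inp.one_sided_p_predicted is None
    if inp.ci_surrogate[0] >= 1:
        return ChecklistVerdict(4, "no_go", "95% CI for the surrogate excludes any reduction",
                                partial=partial)
    if not partial and inp.ci_surrogate[0] > inp.powered_reduction_rr \
            and inp.ci_predicted_mortality[0] >= 1:
        return ChecklistVerdict(
            4, "no_go",
            "surrogate CI excludes the powered reduction and predicted-mortality CI "
            "excludes any reduction", partial=partial)
    if partial:
        if inp.p_advanced_2sided < 0.05 and inp.one_sided_p_advanced < 0.2:
            return ChecklistVerdict(4, "go",
                                    "surrogate significant at 2-sided p < 0.05 and 1-sided "
                                    "p < 0.2 (predicted mortality unavailable)", partial=True)
        return ChecklistVerdict(4, "indeterminate",
                                "surrogate-only evidence inconclusive "
                                "(predicted mortality unavailable)", partial=True)
    two_sided_ok = inp.p_advanced_2sided < 0.05 or inp.p_predicted_mortality_2sided < 0.05
    one_sided_ok = inp.one_sided_p_advanced < 0.2 and inp.one_sided_p_predicted < 0.2
    if two_sided_ok and one_sided_ok:
        return ChecklistVerdict(4, "go",
                                "an endpoint significant at 2-sided p < 0.05 and both "
                                "1-sided p < 0.2 in favour of screening")
    return ChecklistVerdict(4, "indeterminate", "between go and no-go clause boundaries")


def step5_modelled_benefit(point_estimate_rr: float, best_case_rr: float,
                           meaningful_rr_threshold: float) -> ChecklistVerdict:
    """Modelled mortality benefit against a clinically meaningful threshold.

    Go: the point-estimate RR reaches the threshold.  No-go: even the
    best-case RR misses it.  The threshold (< 1) is supplied by the user.
    """
    if not (0 < meaningful_rr_threshold < 1):
        raise ValueError(f"meaningful_rr_threshold must be in (0, 1), got {meaningful_rr_threshold}")
    if point_estimate_rr <= 0 or best_case_rr <= 0:
        raise ValueError("relative risks must be positive")
    if point_estimate_rr <= meaningful_rr_threshold:
        return ChecklistVerdict(5, "go", "modelled point estimate reaches a clinically "
                                         "meaningful mortality reduction")
    if best_case_rr > meaningful_rr_threshold:
        return ChecklistVerdict(5, "no_go", "even the best-case scenario excludes a clinically "
                                            "meaningful reduction")
    return ChecklistVerdict(5, "indeterminate", "point estimate misses the threshold but the "
                                                "best case reaches it")


def generate_checklist_fixtures(rng: np.random.Generator, profile: str) -> dict:
    """Synthetic, schema-valid checklist inputs with verdicts known by construction.

    Profiles: ``favourable`` (every step go), ``unfavourable`` (steps 1 and
    2 no-go), ``boundary`` (values placed exactly on the printed thresholds
    to pin the inclusive->go / strict->no-go conventions).
    """
    if profile == "favourable":
        return {
            1: FatalityContrast(fatality_advanced_5yr=float(rng.uniform(0.55, 0.9)),
                                fatality_early_5yr=float(rng.uniform(0.05, 0.2))),
            2: AttributableMortality(prop_deaths_from_advanced_5yr=float(rng.uniform(0.5, 0.9)),
                                     prop_deaths_from_advanced_10yr=float(rng.uniform(0.5, 0.9))),
            3: DetectabilityRates(rate_early_detectable=0.05, rate_early_not_detectable=0.05,
                                  rate_advanced_detectable=0.40, rate_advanced_not_detectable=0.38),
            4: TrialEvidence(p_advanced_2sided=0.01, one_sided_p_advanced=0.005,
                             ci_surrogate=(0.7, 0.95), powered_reduction_rr=0.85,
                             p_predicted_mortality_2sided=0.15, one_sided_p_predicted=0.075,
                             ci_predicted_mortality=(0.8, 1.05)),
            5: {"point_estimate_rr": 0.80, "best_case_rr": 0.70, "meaningful_rr_threshold": 0.90},
        }
    if profile == "unfavourable":
        return {
            1: FatalityContrast(fatality_advanced_5yr=0.28, fatality_early_5yr=0.22),
            2: AttributableMortality(prop_deaths_from_advanced_5yr=float(rng.uniform(0.05, 0.2)),
                                     prop_deaths_from_advanced_10yr=float(rng.uniform(0.05, 0.2))),
            3: DetectabilityRates(rate_early_detectable=0.42, rate_early_not_detectable=0.10,
                                  rate_advanced_detectable=0.40, rate_advanced_not_detectable=0.40),
            4: TrialEvidence(p_advanced_2sided=0.5, one_sided_p_advanced=0.25,
                             ci_surrogate=(1.01, 1.20), powered_reduction_rr=0.85,
                             p_predicted_mortality_2sided=0.9, one_sided_p_predicted=0.45,
                             ci_predicted_mortality=(0.95, 1.30)),
            5: {"point_estimate_rr": 1.0, "best_case_rr": 0.95, "meaningful_rr_threshold": 0.90},
        }
    if profile == "boundary":
        return {
            # difference exactly 0.30 -> go (>= inclusive)
            1: FatalityContrast(fatality_advanced_5yr=0.40, fatality_early_5yr=0.10),
            # 5-year proportion exactly 0.50 -> go
            2: AttributableMortality(prop_deaths_from_advanced_5yr=0.50,
                                     prop_deaths_from_advanced_10yr=0.50),
            # equal average rates in detectable early vs advanced -> no-go
            # ("no better than" is inclusive)
            3: DetectabilityRates(rate_early_detectable=0.40, rate_early_not_detectable=0.40,
                                  rate_advanced_detectable=0.40, rate_advanced_not_detectable=0.40),
            # surrogate CI lower bound exactly 1 -> no-go (excludes any reduction)
            4: TrialEvidence(p_advanced_2sided=0.05, one_sided_p_advanced=0.025,
                             ci_surrogate=(1.0, 1.2), powered_reduction_rr=0.85,
                             p_predicted_mortality_2sided=0.5, one_sided_p_predicted=0.25,
                             ci_predicted_mortality=(0.9, 1.2)),
            # point estimate exactly at the threshold -> go (<= inclusive)
            5: {"point_estimate_rr": 0.90, "best_case_rr": 0.80, "meaningful_rr_threshold": 0.90},
        }
    raise ValueError(f"profile must be 'favourable', 'unfavourable' or 'boundary', got {profile!r}")
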