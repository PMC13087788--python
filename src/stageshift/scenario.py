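"""Parametric model of a two-arm cancer screening trial with binary endpoints.

The model tracks, per randomised participant, whether they are diagnosed
with advanced-stage cancer, early-stage cancer, or no cancer, and whether a
diagnosed cancer proves fatal.  Screening acts only through a stage shift:
a fraction ``1 - theta`` of would-be advanced cancers in the screening arm
are instead detected at early stage (``theta`` is the relative risk of
advanced-stage diagnosis).  Three surrogacy scenarios are modelled:

``valid_effective``
    Stage-specific fatality is unaffected by screening, so the stage shift
    carries through to mortality (advanced stage is a complete mediator and
    screening is effective whenever ``theta < 1``).
``null``
    ``theta = 1``: screening moves nothing; both endpoints are null.
``invalid``
    Down-staged cancers keep their advanced-stage fatality, so screening
    reduces advanced-stage incidence without touching mortality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .presets import SitePreset

__all__ = [
    "SCENARIOS",
    "ScenarioSpec",
    "TrialParameters",
    "ArmExpectations",
    "relative_mortality_valid",
    "expected_arm_proportions",
    "uptake_relative_mortality",
    "draw_trial_parameters",
]

ScenarioId = Literal["valid_effective", "null", "invalid"]
SCENARIOS: tuple[str, ...] = ("valid_effective", "null", "invalid")

#: default range for the advanced-stage relative risk under the alternative,
#: allowing for trials with an attenuated effect (non-compliance,
#: contamination); configurable per run.
DEFAULT_THETA_RANGE: tuple[float, float] = (0.55, 0.90)


@dataclass(frozen=True)
class ScenarioSpec:
    """A surrogacy scenario plus the distribution of the stage effect theta.

    The null scenario forces ``theta = 1`` exactly; under the other two
    scenarios theta is uniform over ``theta_range`` (sub-interval of (0, 1]).
    """

    scenario_id: str
    theta_range: tuple[float, float] = DEFAULT_THETA_RANGE

    def __post_init__(self) -> None:
        if self.scenario_id not in SCENARIOS:
            raise ValueError(f"scenario_id must be one of {SCENARIOS}, got {self.scenario_id!r}")
        if self.scenario_id == "null":
            object.__setattr__(self, "theta_range", (1.0, 1.0))
        lo, hi = self.theta_range
        if not (0 < lo <= hi <= 1):
            raise ValueError(f"theta_range must be a sub-interval of (0, 1], got {self.theta_range}")

    def sample_theta(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.scenario_id == "null":
            return np.ones(size)
        lo, hi = self.theta_range
        return rng.uniform(lo, hi, size=size)


@dataclass(frozen=True)
class TrialParameters:
    """One simulated trial's realised design parameters (equal-sized arms)."""

    n_per_arm: int
    p_a: float
    p_e: float
    theta: float
    f_a: float
    f_e: float
    scenario_id: str
    site_name: str = ""

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if not (0 < self.theta <= 1):
            raise ValueError(f"theta must be in (0, 1], got {self.theta}")
        if self.scenario_id == "null" and self.theta != 1.0:
            raise ValueError("null scenario requires theta = 1")
        for name in ("p_a", "p_e", "f_a", "f_e"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        # screening-arm category masses must fit on the simplex
        if self.p_e + (1 - self.theta) * self.p_a + self.theta * self.p_a > 1:
            raise ValueError("total cancer proportion exceeds 1")


@dataclass(frozen=True)
class ArmExpectations:
    """Expected per-participant probabilities for one arm."""

    p_advanced: float
    p_early: float          # early at diagnosis, including down-staged cancers
    p_down_staged: float    # subset of p_early that was down-staged by screening
    p_death: float


def relative_mortality_valid(theta: float, p_a: float, p_e: float, f_a: float, f_e: float) -> float:
    """Mortality relative risk ``psi`` when advanced stage fully mediates screening.

    With stage-specific fatalities unchanged by screening,

        psi = (theta*P_a*F_a + [P_e + (1-theta)*P_a]*F_e) / (P_a*F_a + P_e*F_e).

    ``psi = 1`` iff ``theta = 1`` or ``F_a = F_e``; ``psi < 1`` whenever the
    stage shift moves mass to a genuinely less fatal stage.
    """
    denom = p_a * f_a + p_e * f_e
    if denom <= 0:
        raise ValueError("expected control-arm death proportion is zero; psi undefined")
    num = theta * p_a * f_a + (p_e + (1 - theta) * p_a) * f_e
    return num / denom


def expected_arm_proportions(params: TrialParameters) -> dict[str, ArmExpectations]:
    """Expected event probabilities in each arm, by scenario.

    Control arm: advanced with probability ``p_a`` (fatality ``f_a``), early
    with ``p_e`` (fatality ``f_e``).  Screening arm: advanced ``theta*p_a``;
    the down-staged mass ``(1-theta)*p_a`` is early at diagnosis and dies
    with fatality ``f_e`` under the valid scenarios but retains ``f_a``
    under the invalid scenario — which makes the expected death proportion
    identical in the two arms for every theta.
    """
    p = params
    control = ArmExpectations(
        p_advanced=p.p_a,
        p_early=p.p_e,
        p_down_staged=0.0,
        p_death=p.p_a * p.f_a + p.p_e * p.f_e,
    )
    down = (1 - p.theta) * p.p_a
    f_down = p.f_a if p.scenario_id == "invalid" else p.f_e
    screening = ArmExpectations(
        p_advanced=p.theta * p.p_a,
        p_early=p.p_e + down,
        p_down_staged=down,
        p_death=p.theta * p.p_a * p.f_a + down * f_down + p.p_e * p.f_e,
    )
    return {"control": control, "screening": screening}


def uptake_relative_mortality(psi: float, s1: float) -> float:
    """Mortality relative risk diluted by partial screening uptake.

    If screening multiplies mortality risk by ``psi`` in the fraction ``s1``
    of the screening arm actually screened (and uptake is independent of
    underlying risk), the arm-level relative risk is ``psi*s1 + 1 - s1`` —
    affine in uptake with intercept 1 and slope ``psi - 1``.
    """
    if not (0 < psi <= 1):
        raise ValueError(f"psi must be in (0, 1], got {psi}")
    if not (0 <= s1 <= 1):
        raise ValueError(f"s1 must be in [0, 1], got {s1}")
    return psi * s1 + 1 - s1


def draw_trial_parameters(
    preset: SitePreset,
    scenario: ScenarioSpec,
    rng: np.random.Generator,
    size: int,
) -> list[TrialParameters]:
    """Draw `size` independent trial designs from a site preset.

    The per-arm size and ``P_a`` are uniform over the preset ranges (the
    size model may be a mixture); ``P_e`` is deterministic given ``P_a``;
    theta follows the scenario's model.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    n = preset.n_model.sample(rng, size)
    p_a = rng.uniform(*preset.p_adv_range, size=size)
    theta = scenario.sample_theta(rng, size)
    return [
        TrialParameters(
            n_per_arm=int(n[i]),
            p_a=float(p_a[i]),
            p_e=float(p_a[i] * preset.p_early_multiplier),
            theta=float(theta[i]),
            f_a=preset.f_adv,
            f_e=preset.f_early,
            scenario_id=scenario.scenario_id,
            site_name=preset.site_name,
        )
        for i in range(size)
    ]
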