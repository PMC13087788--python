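"""Site parameter presets for the screening-trial simulator.

Each preset describes one cancer site as used by the simulation study: a
per-arm trial-size model, a range for the control-arm advanced-stage
proportion ``P_a``, a multiplier giving the early-stage proportion
``P_e = m * P_a``, and stage-specific case fatalities ``F_a`` and ``F_e``.

Presets are shipped as a versioned YAML data file and validated at load
time; user overrides may be supplied as a YAML file with the same schema.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "SizeModel",
    "SitePreset",
    "PresetError",
    "load_presets",
    "preset_by_name",
]


class PresetError(ValueError):
    """A preset file or override failed validation; the message names the field."""


@dataclass(frozen=True)
class SizeModel:
    """Per-arm trial-size distribution: a mixture of uniform components.

    A plain uniform is a single-component mixture.  Sizes are in persons;
    draws are continuous uniforms rounded to the nearest integer.
    """

    weights: tuple[float, ...]
    lows: tuple[float, ...]
    highs: tuple[float, ...]

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.weights), 1.0):
            raise PresetError(f"n_model mixture weights must sum to 1, got {self.weights}")
        for w, lo, hi in zip(self.weights, self.lows, self.highs):
            if w <= 0:
                raise PresetError(f"n_model component weight must be positive, got {w}")
            if not (0 < lo <= hi):
                raise PresetError(f"n_model component range invalid: [{lo}, {hi}]")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw `size` per-arm trial sizes (integer persons)."""
        comp = rng.choice(len(self.weights), size=size, p=self.weights)
        lo = np.asarray(self.lows)[comp]
        hi = np.asarray(self.highs)[comp]
        return np.rint(rng.uniform(lo, hi)).astype(np.int64)

    @property
    def max_size(self) -> float:
        return max(self.highs)


@dataclass(frozen=True)
class SitePreset:
    """One cancer site's simulation parameters.

    Attributes
    ----------
    site_name : str
    n_model : SizeModel
        Per-arm number of randomised participants.
    p_adv_range : (float, float)
        Uniform range for the control-arm advanced-stage proportion ``P_a``.
    p_early_multiplier : float
        ``P_e = p_early_multiplier * P_a``.
    f_adv, f_early : float
        Stage-specific fatalities ``F_a`` and ``F_e`` (probabilities).
    """

    site_name: str
    n_model: SizeModel
    p_adv_range: tuple[float, float]
    p_early_multiplier: float
    f_adv: float
    f_early: float

    def __post_init__(self) -> None:
        lo, hi = self.p_adv_range
        if not (0 < lo <= hi < 1):
            raise PresetError(f"{self.site_name}: p_adv_range must satisfy 0 < lo <= hi < 1, got {self.p_adv_range}")
        if self.p_early_multiplier <= 0:
            raise PresetError(f"{self.site_name}: p_early_multiplier must be > 0, got {self.p_early_multiplier}")
        for field in ("f_adv", "f_early"):
            v = getattr(self, field)
            if not (0 <= v <= 1):
                raise PresetError(f"{self.site_name}: {field} must be a probability in [0, 1], got {v}")
        if self.f_adv < self.f_early:
            # the valid-surrogate mediation logic requires F_a >= F_e
            raise PresetError(f"{self.site_name}: f_adv ({self.f_adv}) must be >= f_early ({self.f_early})")
        # total cancer proportion must stay below 1 across the whole range
        if hi * (1 + self.p_early_multiplier) >= 1:
            raise PresetError(f"{self.site_name}: P_a + P_e may reach 1 at the top of p_adv_range")
        if lo * self.f_adv + lo * self.p_early_multiplier * self.f_early <= 0:
            raise PresetError(f"{self.site_name}: expected death proportion is 0 at the bottom of the range")

    @property
    def p_early_range(self) -> tuple[float, float]:
        lo, hi = self.p_adv_range
        return (lo * self.p_early_multiplier, hi * self.p_early_multiplier)


def _parse_size_model(raw: dict) -> SizeModel:
    kind = raw.get("kind")
    if kind == "uniform":
        return SizeModel(weights=(1.0,), lows=(float(raw["lo"]),), highs=(float(raw["hi"]),))
    if kind == "mixture":
        comps = raw["components"]
        return SizeModel(
            weights=tuple(float(c["weight"]) for c in comps),
            lows=tuple(float(c["lo"]) for c in comps),
            highs=tuple(float(c["hi"]) for c in comps),
        )
    raise PresetError(f"n_model.kind must be 'uniform' or 'mixture', got {kind!r}")


def _parse_preset(raw: dict) -> SitePreset:
    try:
        return SitePreset(
            site_name=str(raw["site_name"]),
            n_model=_parse_size_model(raw["n_model"]),
            p_adv_range=(float(raw["p_adv_range"][0]), float(raw["p_adv_range"][1])),
            p_early_multiplier=float(raw["p_early_multiplier"]),
            f_adv=float(raw["f_adv"]),
            f_early=float(raw["f_early"]),
        )
    except KeyError as exc:  # pragma: no cover - exercised via malformed-override test
        raise PresetError(f"preset {raw.get('site_name', '<unnamed>')}: missing field {exc}") from exc


def load_presets(
    config: str | Path | None = None,
    *,
    include_variants: bool = False,
) -> list[SitePreset]:
    """Load the shipped site presets, or a user override file.

    Parameters
    ----------
    config
        Optional path to a YAML file with the shipped schema; replaces the
        built-in presets entirely.
    include_variants
        Also return the sensitivity variants (e.g. the breast preset with a
        larger early-stage proportion) after the default sites.
    """
    if config is None:
        text = resources.files("stageshift.data").joinpath("presets.yaml").read_text()
    else:
        text = Path(config).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise PresetError(f"could not parse preset file: {exc}") from exc
    if not isinstance(doc, dict) or "presets" not in doc:
        raise PresetError("preset file must contain a top-level 'presets' list")
    presets = [_parse_preset(p) for p in doc["presets"]]
    if include_variants:
        presets += [_parse_preset(p) for p in doc.get("variants", [])]
    names = [p.site_name for p in presets]
    if len(set(names)) != len(names):
        raise PresetError(f"duplicate site_name in preset file: {names}")
    return presets


def preset_by_name(name: str, presets: Sequence[SitePreset] | None = None) -> SitePreset:
    """Look up one preset by site name (searches variants too by default)."""
    if presets is None:
        presets = load_presets(include_variants=True)
    for p in presets:
        if p.site_name == name:
            return p
    raise KeyError(f"no preset named {name!r}; available: {[p.site_name for p in presets]}")
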