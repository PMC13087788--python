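# Site parameter presets for the screening-trial simulator.
#
# Units: per-arm trial sizes in persons; proportions and fatalities as
# probabilities.  `p_adv_range` is the control-arm proportion of randomised
# participants diagnosed with advanced-stage cancer (P_a); the early-stage
# proportion is P_e = p_early_multiplier * P_a.  `f_adv` / `f_early` are the
# stage-specific case fatalities (probability a diagnosed case dies of the
# cancer).
#
# version: 1
presets:
  - site_name: bowel
    n_model: {kind: uniform, lo: 14000, hi: 85000}
    p_adv_range: [0.005, 0.011]
    p_early_multiplier: 1.0
    f_adv: 0.65
    f_early: 0.20
  - site_name: breast
    n_model: {kind: uniform, lo: 18000, hi: 80000}
    p_adv_range: [0.004, 0.010]
    p_early_multiplier: 2.0
    f_adv: 0.40
    f_early: 0.10
  - site_name: liver
    n_model: {kind: uniform, lo: 2000, hi: 25000}
    p_adv_range: [0.004, 0.025]
    p_early_multiplier: 0.75
    f_adv: 0.95
    f_early: 0.85
  - site_name: lung
    # 15% of trials are small, 85% large (two uniform components, persons).
    n_model:
      kind: mixture
      components:
        - {weight: 0.15, lo: 900, hi: 27000}
        - {weight: 0.85, lo: 65000, hi: 80000}
    p_adv_range: [0.007, 0.033]
    p_early_multiplier: 0.5
    f_adv: 0.90
    f_early: 0.10
  - site_name: ovary
    n_model: {kind: uniform, lo: 10000, hi: 155000}
    p_adv_range: [0.004, 0.010]
    p_early_multiplier: 0.4
    f_adv: 0.70
    f_early: 0.25
  - site_name: prostate
    n_model: {kind: uniform, lo: 7500, hi: 220000}
    p_adv_range: [0.008, 0.035]
    p_early_multiplier: 3.0
    f_adv: 0.28
    f_early: 0.04
  - site_name: prostate_short_followup
    n_model: {kind: uniform, lo: 9000, hi: 225000}
    p_adv_range: [0.005, 0.020]
    p_early_multiplier: 4.0
    f_adv: 0.10
    f_early: 0.015

# Sensitivity variants, selectable by flag; not part of the default seven.
variants:
  - site_name: breast_more_early
    # Illustrative variant with a higher proportion of early-stage breast
    # cancer, reflecting the secular increase in symptomatic stage-I
    # diagnoses relative to the historical trials.
    n_model: {kind: uniform, lo: 18000, hi: 80000}
    p_adv_range: [0.004, 0.010]
    p_early_multiplier: 3.0
    f_adv: 0.40
    f_early: 0.10
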