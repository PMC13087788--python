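"""Run the five-step go/no-go surrogate verification checklist.

Evaluates the checklist on bowel-cancer-like registry and trial summary
statistics, then on a deliberately unfavourable profile from the fixture
generator, printing each step's verdict and the clause that fired.
"""

import numpy as np

from stageshift import (
    AttributableMortality,
    DetectabilityRates,
    FatalityContrast,
    TrialEvidence,
    generate_checklist_fixtures,
    step1_survival_differential,
    step2_attributable_mortality,
    step3_detectability,
    step4_trial_endpoint,
    step5_modelled_benefit,
)

print("bowel-cancer-like evidence profile:")
verdicts = [
    step1_survival_differential(FatalityContrast(fatality_advanced_5yr=0.65,
                                                 fatality_early_5yr=0.20)),
    step2_attributable_mortality(AttributableMortality(prop_deaths_from_advanced_5yr=0.70,
                                                       prop_deaths_from_advanced_10yr=0.65)),
    step3_detectability(DetectabilityRates(rate_early_detectable=0.05,
                                           rate_early_not_detectable=0.05,
                                           rate_advanced_detectable=0.40,
                                           rate_advanced_not_detectable=0.38)),
    step4_trial_endpoint(TrialEvidence(p_advanced_2sided=0.01, one_sided_p_advanced=0.005,
                                       ci_surrogate=(0.72, 0.95), powered_reduction_rr=0.85,
                                       p_predicted_mortality_2sided=0.12,
                                       one_sided_p_predicted=0.06,
                                       ci_predicted_mortality=(0.82, 1.02))),
    step5_modelled_benefit(point_estimate_rr=0.82, best_case_rr=0.74,
                           meaningful_rr_threshold=0.90),
]
for v in verdicts:
    print(f"  step {v.step}: {v.verdict:13s} - {v.triggered_rule}")

print("\nunfavourable fixture profile (generator-built):")
fx = generate_checklist_fixtures(np.random.default_rng(0), "unfavourable")
for v in (step1_survival_differential(fx[1]), step2_attributable_mortality(fx[2])):
    print(f"  step {v.step}: {v.verdict:13s} - {v.triggered_rule}")
print("  (a no-go at steps 1-2 means advanced stage should not be pursued as a")
print("   surrogate for this cancer before any trial is designed around it)")
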