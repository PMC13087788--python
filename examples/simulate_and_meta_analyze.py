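"""Simulate one batch of screening trials and meta-analyse the two endpoints.

Draws 10 bowel-cancer-like trials under the valid-surrogate scenario,
prints each trial's log relative risks, then the trial-level correlation,
the meta-regression fit, and the predicted upper 95% CI of the mortality
RR if the surrogate RR were 0.85.
"""

import numpy as np

from stageshift import ScenarioSpec, analyze_meta, preset_by_name, simulate_trial_batch

rng = np.random.default_rng(2)
batch = simulate_trial_batch(preset_by_name("bowel"),
                             ScenarioSpec("valid_effective", (0.55, 0.90)),
                             n_trials=10, rng=rng)

cols = ["n_per_arm", "theta", "adv_screen", "adv_control",
        "deaths_screen", "deaths_control", "log_rr_advanced", "log_rr_mortality"]
print(batch[cols].round(3).to_string(index=False))

res = analyze_meta(batch, rr_surrogate=0.85)
print(f"\ntrial-level Pearson correlation (unweighted): {res.corr_unweighted:.3f}")
print(f"meta-regression: intercept {res.fit.alpha_hat:+.4f}, slope {res.fit.beta_hat:.3f}")
print(f"predicted upper 95% CI of mortality RR at surrogate RR 0.85: "
      f"{res.upper_ci_at_085:.3f}")
print("(a value below 1 means this trial set would predict a genuine mortality "
      "benefit from a 15% advanced-stage reduction)")
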