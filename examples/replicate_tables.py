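"""Scaled-down replication of the full simulation study tables.

Runs all seven site presets under the three surrogacy scenarios with
reduced replicate counts (2,000 power replicates and 200 meta-replicates
per cell; the package defaults are 20,000 and 1,000) and prints the three
result tables: power/one-sided size per endpoint, mean trial-level
correlation, and mean upper 95% CI of the mortality RR at surrogate RR
0.85.
"""

import tempfile
from pathlib import Path

from stageshift import ExperimentConfig, render_tables, run_meta_experiment, run_power_size

cfg = ExperimentConfig(seed=0, n_power_replicates=2000, n_meta_replicates=200)
print("simulating power/size cells (7 sites x 3 scenarios x 2,000 trials)...")
power = run_power_size(cfg)
print("simulating meta-analysis cells (7 sites x 3 scenarios x 200 x 10 trials)...")
meta = run_meta_experiment(cfg)

outdir = Path(tempfile.mkdtemp(prefix="stageshift_tables_"))
paths = render_tables(power, meta, outdir)
for name, path in paths.items():
    print(f"\n=== {name} ({path}) ===")
    print(path.with_suffix(".txt").read_text())

print("Reading guide: size columns should sit near the nominal 2.5%; the")
print("advanced-stage endpoint has greater power than mortality everywhere;")
print("the invalid-surrogate correlation stays well above 0 (shared-cohort")
print("confounding) and its upper CI at 0.85 exceeds 1.00 for every site.")
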