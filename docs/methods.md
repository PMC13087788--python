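# Methods

## Model and assumptions

`stageshift` models a two-arm screening RCT with *binary* endpoints: each
randomised participant either is or is not diagnosed with advanced-stage
cancer, and either does or does not die of the cancer, within the trial's
horizon. This deliberately abstracts away the time-to-event structure of
real screening trials — lead time, length bias, censoring between
diagnosis and death, non-proportional hazards and secular treatment trends
are all out of scope. The abstraction is adequate for studying
*trial-level surrogacy*: both endpoints are rare, so proportion-based
tests behave like their person-time counterparts, and the phenomena the
package studies (endpoint correlation induced by a shared cohort,
mediation versus non-mediation of the screening effect) do not depend on
event timing. Overdiagnosis is also excluded: it affects neither
cancer-specific mortality nor the *rate* of advanced-stage diagnoses among
randomised participants (the endpoint simulated here), though it would
invalidate the "proportion of diagnosed cancers that are advanced"
endpoint, which this package does not implement.

A trial draws one cohort per arm. Control arm: a three-category
multinomial over (advanced `P_a`, early `P_e`, neither), then deaths
`Binomial(advanced, F_a) + Binomial(early, F_e)` conditional on the
realised stage counts. Screening arm: a four-category multinomial over
(advanced `θP_a`, down-staged `(1 − θ)P_a`, early `P_e`, neither).
Down-staged cancers count as *early* for the stage endpoint in every
scenario; their fatality is `F_e` under the valid scenarios and `F_a`
under the invalid scenario. Multinomial (rather than independent binomial)
category draws keep counts within `n` exactly; for the rare-event regimes
simulated the two are practically indistinguishable. Sampling both
endpoints from the same realised stage counts is essential: it produces
the within-trial endpoint correlation that makes even an invalid surrogate
correlate with mortality across trials.

Under the invalid scenario the expected death proportion is arm-identical
for every `θ` — an exact algebraic identity, since the down-staged mass
keeps its fatality — so any apparent mortality benefit in a trial is pure
noise, yet it co-varies with that trial's stage-endpoint noise.

## Site presets

Seven presets (data file `src/stageshift/data/presets.yaml`, version 1)
give per-arm size ranges, the control-arm advanced-stage proportion range,
the early:advanced multiplier and stage-specific fatalities for trials
resembling bowel, breast, liver, lung, ovary and prostate (long and short
follow-up) screening trials. Sizes are uniform in persons over the printed
range (lung is a 15%/85% mixture of small U(900, 27,000) and large
U(65,000, 80,000) trials). Per trial, `P_a` is drawn uniformly over its
range and `P_e` is the deterministic multiple of `P_a`; whether the
original study drew `P_a` uniformly or on a log scale is unknown, and
uniform is assumed. A breast variant with a larger early-stage share is
shipped for sensitivity analyses (`load_presets(include_variants=True)`).
Presets are validated at load: fatalities are probabilities with
`F_a ≥ F_e` (required for the mediation logic), the total cancer
proportion stays below 1, and mixture weights sum to 1.

## Stage-effect distribution θ

Under the alternative scenarios `θ` is uniform on **(0.55, 0.90)** per
trial, accommodating trials with attenuated effects (non-compliance,
contamination); the null forces `θ = 1`. This range is a documented
assumption — the originating study does not print its θ distribution —
and every run records it in output metadata. The choice matters: the
invalid-scenario meta-correlation falls steeply as the θ spread grows
(between-trial θ variance inflates the stage endpoint's spread without
touching mortality), and power rises as θ moves away from 1. Cells that
average over θ (power, invalid-scenario correlations, upper-CI levels) are
therefore reproduced in structure but not to printed precision, whereas
θ-free quantities (null sizes, null correlations) reproduce tightly.
Diagnostics during development showed per-site null-scenario correlations
matching the published values to ≈0.02 while no single uniform θ range
matched all published invalid-scenario values, so the default range was
fixed once and retained.

## Per-trial statistics

* **Two-proportion Z-test**, pooled variance, no continuity correction;
  two-sided p from the normal approximation. If no events (or all events)
  occur in the pooled arms the test is undefined and a NaN sentinel is
  returned; such trials count as non-rejections in power/size tallies.
* **Log relative risk** (screening/control) with delta-method variance
  `1/x₁ − 1/n₁ + 1/x₂ − 1/n₂`. Zero cells get the Haldane–Anscombe
  adjustment (0.5 to both numerators, 1 to both denominators), flagged;
  configuration can instead drop flagged trials from meta-analysis.
  Trials whose log RR is still undefined are excluded from
  correlation/regression but retained in power/size tallies.
* "Favours screening" means strictly fewer events in the screening arm.

## Meta-analysis

Pearson correlation of the two log RRs, unweighted by default; the
weighted variant uses weighted moments with weights ∝ 1/var(log RR
mortality) and reduces exactly to the unweighted form under equal weights.
Meta-regression of log RR mortality on log RR advanced is OLS (WLS with
the same weights as sensitivity), fitted via statsmodels; the full 2×2
coefficient covariance feeds the predicted upper 95% confidence limit at
surrogate RR `r`:

`exp{α̂ + β̂·ln r + z₀.₉₇₅·√(σ̂²_α + 2σ̂_αβ·ln r + σ̂²_β·ln² r)}`,
`z₀.₉₇₅ = 1.959964`.

The radical applies to the whole variance expression (dimensional
consistency requires it, and typography of the source formula leaves the
root implicit); a normal rather than t quantile is used, matching the
printed constant. This is a confidence limit for the *expected* mortality
effect given the surrogate effect, not a prediction interval for a single
new trial. At least 3 usable trials are required; a design with all
surrogate log RRs identical is rejected as singular.

## Experiment design and defaults

* `n_power_replicates = 20,000` per site × scenario — binomial MC SE
  ≈ 0.1 percentage points on a 2.5% size cell.
* `n_meta_replicates = 1,000` meta-analyses of `n_trials_per_meta = 10`
  trials per site; the "all combined" row pools each replicate's trials
  across the seven sites (70 trials) before computing the statistic —
  pooling the scatter, not averaging per-site statistics, which matters
  because between-site heterogeneity in mortality effects deflates the
  pooled correlation below the per-site mean.
* Trial designs are redrawn independently for every replicate. Every
  table cell runs on its own substream of the master seed
  (`default_rng([seed, stream, site, scenario])`), so cells are
  independently re-runnable and all outputs are bit-reproducible from
  `(config, seed)`.
* Replicates whose meta-analysis is undefined after filtering are counted
  and reported, never silently dropped.

These replicate counts balance Monte-Carlo error (correlation cells carry
SE ≈ 0.01, upper-CI cells ≈ 0.005) against desk-scale runtimes (the full
three-scenario experiment runs in well under a minute on one CPU).

## Checklist semantics

The five verification steps return a three-valued verdict. Published go
and no-go clauses do not partition the input space, so `indeterminate` is
an explicit outcome, not an error. Thresholds written `≥` are inclusive,
`<` strict; "no better than" (step 3) is inclusive. Percent thresholds in
step 1 are absolute differences in fatality probabilities. Step 3's
average rates are the supplied per-stage screen-detectable rates (the
intended weighting — by person-time or by stage — is unspecified; inputs
are expected to be person-time rates). Step 4 evaluates its no-go CI
clauses before the go clause, so internally inconsistent inputs (p-values
contradicting the CIs they summarise) resolve conservatively; for
coherent inputs the clauses are provably disjoint, which the test suite
audits over 10⁵ randomised inputs per step. Steps 6–7 (treatment
timeliness and quality) carry no formal criteria and are represented as
audit records only. The fixture generator produces favourable,
unfavourable and boundary profiles whose verdicts are known by
construction; the boundary profile places values exactly on thresholds to
pin the inclusivity conventions.

## Known limitations

* Binary endpoints: no lead time, length bias, censoring or secular
  trends; results speak to endpoint *logic*, not to absolute effect sizes
  in any real programme.
* Full or zero mediation only; partial mediation (down-staged cancers
  with intermediate fatality) is not modelled.
* θ-dependent cells reproduce published values only up to the unknown θ
  distribution (see above); the structural orderings (greater power for
  the stage endpoint; valid > invalid correlation; invalid upper CI > 1)
  are the robust findings and are what the test suite asserts per site.
* The checklist consumes pre-computed summary statistics; it does not
  estimate survival or predicted mortality from registry microdata.
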