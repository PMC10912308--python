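# Methods

## The evaluation problem

A serum biomarker panel for early cancer detection is judged by its
sensitivity at a *fixed, design-derived* specificity, not by global ROC
summaries. The operating point comes from a benefit–harm argument: if at
most ten screen-indicated surgeries per detected cancer are acceptable, the
positive predictive value of a screen-positive must reach about 20%. At an
annual prevalence of 1/2500 this requires a 500-fold enrichment across the
screening cascade; with transvaginal ultrasound removing 10 of every 11
blood-test false positives (a 10-fold reduction), the blood test itself
must supply 50-fold enrichment — a false-positive rate of 2%, i.e. 98%
specificity. Against benign pelvic masses (symptomatic patients, higher
pre-test probability) the package defaults to 95% specificity instead.
These conversions assume near-perfect sensitivity; no sensitivity-adjusted
PPV variant is applied.

## Positivity rules

`specificity_cutoff` chooses the smallest *observed* control value `c` such
that the fraction of controls strictly above `c` is at most `1 − target`.
Positivity is strict (`value > c`) everywhere, matching clinical phrasing
such as "> 35 U/ml"; ties at the threshold are negative. Because the
threshold is an observed order statistic rather than an interpolated
quantile, the achieved specificity is exact and auditable on the defining
controls and is ≥ the target by construction. Interpolated quantiles were
rejected for that reason. For tables of the study type, cutoffs are
computed on the *pooled* healthy controls (the convention of defining 98%
cutoffs "in the combined data set"), which leaks information relative to a
train-only rule; train-only computation is available by passing the
training controls instead.

`mean_plus_2sd_cutoff` implements the autoantibody seropositivity
convention, control mean + 2 standard deviations, with the sample (n−1)
standard deviation — the field convention where the population/sample
choice is unstated. `clinical_rule` carries externally fixed thresholds.

Per-group sensitivity tables report benign, early (stage I–II), late
(stage III–IV) and all-cases (= early ∪ late) rows; empty groups yield NaN
sensitivity rather than an error. Complementarity is the fraction of
reference-negative cases in a group that a candidate marker calls positive.
The OR rule calls a sample positive if any member marker is positive; its
specificity is measured on the designated control group.

## Split, forest, and sensitivity at specificity

`split_cohort` assigns train/validation within each stratum (group, by
default) by a seeded permutation, with `round(fraction·n)` to training, so
counts are within one of the target fraction. Stratifying by group makes
the validation case count deterministic (e.g. 32 + 93 = 125 cases from a
64 + 186 cohort at 50:50). Whether the original analyses stratified by
accrual site as well is unknowable from the design alone; group-only
stratification is the default and site can be added via `strata`.

`PanelForest` wraps a bagged decision-tree ensemble (scikit-learn's
`RandomForestClassifier`, 2,000 fully grown trees by default, fixed seed)
and scores a sample by the *fraction of trees voting case*, giving a score
in [0, 1]. The forest is a contract — bagged axis-aligned trees with
majority-vote probability — not a bit-exact reference; all downstream
checks are statistical.

`sensitivity_at_specificity` re-uses the cutoff rule on the score scale:
the threshold is set on the evaluated controls (validation controls by
default), matching ROC-style reporting of "sensitivity at 98% specificity
on the validation set". Because which set fixed the operating point is
genuinely open, `threshold_on="train"` switches to training controls.

### Tied scores at the ceiling — a known limitation

Vote fractions are discrete, and single-feature forests can assign several
controls the maximal score 1.0. When the number of evaluation controls is
small (so that 1 − specificity allows only a couple of exceedances), the
threshold is then forced to the ceiling and sensitivity collapses to 0 —
an operating-point artifact, not a property of the marker. Adding *any*
continuous feature dithers the ties and appears to "gain" sensitivity.
Comparisons against single-marker baselines are therefore only meaningful
with an adequately large control pool (the packaged study-composition
cohort provides 251 validation controls) and enough trees to refine the
score grid; the test suite exercises exactly this configuration.

## Permutation inference

The null distribution of a sensitivity gain is built by re-running the
whole pipeline per permutation: shuffle the group-label vector over the
cases plus the designated control group (preserving group sizes, destroying
label–marker association), re-split 50:50, re-train every panel on the
permuted training half, re-evaluate on the permuted validation half.
Per-permutation seeds derive deterministically from the master seed, so a
run is exactly reproducible. Degenerate permutations (a single class in a
training stratum) are redrawn with a logged count.

The default statistic is the panel-minus-baseline difference in validation
sensitivity, because the substantive claims are about *differences*; the
raw panel sensitivity is available via `statistic="sensitivity"`, since a
percentile-of-sensitivity reading of the procedure is also defensible.
The p-value is the add-one upper tail, p = (1 + #{null ≥ obs}) / (1 + B) —
never exactly zero, exact under exchangeability — rather than the literal
percentile. The test is one-sided (improvement). B defaults to 500 in the
CLI for desk-scale runs; study-scale runs use `--b 10000`.

Any statistic with the `(cohort, split) -> float` signature can be injected
in place of the forest pipeline. This is how the calibration checks work:
with a continuous plug-in statistic on a no-signal cohort, the p-values are
uniform on {1/(B+1), …, 1}, which the suite verifies by a
Kolmogorov–Smirnov test over 100 replicates and by exhaustive enumeration
of all label assignments on an 8-sample cohort.

## Power calculus

`sensitivity_power` uses the one-sided normal approximation without
continuity correction, with the variance under the null for the critical
value and under the alternative for the power. This specific variant is
designated the primary method because it reproduces the canonical design
numbers for n = 125 validated cases to three decimals (97.8% for 60%→75%,
77.9% for 65%→75%, 93.5% for 62%→75%); the derivation of those numbers was
not published alongside them, so the designation is an inference from exact
numeric agreement. The exact-binomial method (smallest critical count whose
null tail is ≤ α) is the statistically preferable alternative and
cross-check; being conservative under discreteness, its power can sit up to
~8 points below the approximation for n ≈ 100 and mid-range sensitivities,
and within 3 points at the design configuration itself.

## Site QC

Within each clinical group, a Welch (unequal-variance) two-sample t-test
compares mean log concentration between the two accrual sites. Welch is
chosen over the pooled-variance test as the safer default where the
convention is unstated; the natural log is used, and the base cancels in
t. No multiple-testing correction is applied — this is a QC screen, and
adjusting would change its role. No batch correction is performed.

## Synthetic cohorts

No public deposit of the underlying serum measurements exists, so the
generator emulates the cohort's statistical structure:

* **Composition** — the study's group-by-site counts: 64 early (21/43),
  186 late (107/79), 200 benign (56/144), 502 healthy (131/371) across
  two accrual sites.
* **Marginals** — log-normal concentrations: positive, right-skewed, and
  consistent with analysing "means on the log scale". The true marker
  distributions are unknown; log-normality is an assumption, not an
  estimate.
* **Calibration** — under equal-sd Gaussian logs, a case shift of
  δ = σ(z_spec + z_sens) yields the target sensitivity at the target
  specificity; `calibrate_shift` inverts this so fixtures hit stated
  sensitivities (e.g. a CA125-like marker at 62.5% early-stage sensitivity
  at 98% specificity).
* **Correlation** — pairwise Gaussian copula on the log scale; the
  simplest structure sufficient to exercise panel behaviour.
* **Complementarity** — a marker with a `complement_target` applies its
  group shift only to the half of each elevated group below the partner's
  within-group median; the other half reverts to the healthy marginal.
  This reproduces "elevated preferentially in CA125-negative cases"
  without joint-distribution bookkeeping, at a cost: a gated marker's
  marginal sensitivity is capped near 51% (half the cases never shift).
  The `edrn_like` fixture therefore clips the within-gate sensitivity at
  0.995 where a nominal target exceeds the cap (the HE4-like marker's
  late-stage value) and `fixture_expected_sensitivity` reports the
  analytically implied marginals that the tests check against.
* **Not simulated** — age (used only for control matching, never computed
  on), assay physics (bead fluorescence, RLU ratios, plate effects),
  longitudinal lead-time structure, and inter-site batch effects. Passing
  tests therefore demonstrate correctness of the *machinery* under the
  stated statistical assumptions, not performance of any real marker panel.

Fixture profiles: `edrn_like` (study composition, four calibrated
markers), `null` (160 samples, no group effects — permutation
calibration), `complementary` (300 samples, a marker informative only in
partner-negative cases), `tiny` (8 samples — exhaustive enumeration).

## Problem sizes and numerical choices

Desk-scale defaults keep full runs cheap while preserving the statistical
contracts: forests of 200 trees for the cohort-level panel comparisons
(2,000 remains the library default for single fits), B = 99–500
permutations for calibration runs and p-value reporting at the 1/(B+1)
floor, 20-seed replication for Monte-Carlo assertions. Percentages in
written reports are printed to one decimal place. Determinism is
end-to-end: every random step (generation, splitting, bagging,
permutation) derives from an explicit seed, and derived seeds stay below
2³¹.

## Open design choices, resolved

* Operating threshold from validation vs training controls: both
  implemented; validation-side is the default.
* Permutation statistic (difference vs raw sensitivity): both implemented;
  difference is the default.
* Pooled- vs split-based cutoffs for marker tables: pooled is the default.
* Welch vs pooled t for site QC: Welch.
* The group-label permutation shuffles early/late identity together with
  case/control status, preserving subgroup sizes for the stratified
  re-split.
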