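# Methods

## Signal model and ingestion

A trial is a 10 s isometric toe-extension effort sampled at 50 Hz: 500
rows of `(time_s, force)` in a plain-text file, force in kilograms as
the device records it. The reader auto-detects comma or whitespace
delimiters, skips `#` comments and one optional header line, and
accepts either time origin convention (first sample at 0.00 s or at one
sampling interval, 0.02 s); the convention found is recorded in the
trial's flags. The sampling rate is inferred from the median time step
and compared with the nominal 50 Hz; a deviation beyond 1% is a warning
(the time column is still trusted), not an error.

The only missingness these devices produce is a truncated tail:
recordings that stop a few samples short of 500. Gaps strictly shorter
than `max_end_gap` (default 10 samples) are filled with the last
observed value; this conserves the observed prefix, is idempotent, and
the imputed count is carried in the trial metadata. A gap of 10 or more
samples, or any non-finite value in the interior of a trial, is an
error — interior drop-outs would bias every curve parameter and are not
a failure mode of the device this pipeline targets.

Forces are converted to newtons with standard gravity g = 9.80665 m/s²
(configurable) before any analysis.

## Curve parameters

With `F` the 500 force samples and `F_peak = max(F)`:

* **rise time** `t_80`: elapsed time from trial start to the first
  sample with `F >= 0.8*F_peak`. Samples are treated as the ends of
  their sampling intervals, so `t_80 = t[i*] - t[0] + dt`. Two
  consequences: the value is independent of the file's time origin, and
  a trial whose first sample already meets the threshold gets
  `t_80 = dt` (one interval, 0.02 s), never zero — which keeps the RFD
  finite. Such trials are flagged `rise_floor`. Ties at the peak are
  resolved by the *first* crossing of the threshold, not the peak's own
  index.
* **average after threshold** `F̄_80`: arithmetic mean from the crossing
  (inclusive) to the trial end, computed with compensated summation
  (`math.fsum`) so the mean is correctly rounded — this matters because
  the next parameter counts samples `>=` that mean, and a last-ulp
  error in a near-constant tail can otherwise flip counts.
* **percent above average**: `100 * #{F >= F̄_80} / 500`. The
  denominator is all samples in the trial. Which average anchors this
  parameter is genuinely ambiguous (the post-threshold mean is the only
  average defined alongside it, and is the default); the whole-trial
  mean is available via `pct_reference="whole_trial"` and flagged in
  the output.
* **RFD**: `0.8*F_peak / t_80`, exactly, by construction.

Rise time is measured from trial start rather than from a detected
force onset: the effort begins at the start cue, no onset-detection
rule is part of the parameter definitions, and onset detectors would
add a tunable the five parameters do not need. No smoothing or
filtering is applied to the signal.

Degenerate trials (no strictly positive sample) yield no features; the
table builder lists them separately instead of dropping them.

## Synthetic cohorts

The generator exists to give the pipeline data with known ground truth.
Its model is the minimal shape exhibiting what the parameters measure:

    force(t) = plateau * (1 - exp(-t/tau)) * (1 + eps_t),  eps_t ~ N(0, cv) i.i.d.,

clipped at zero, sampled at t = 0.02, 0.04, …, 10.00 s. For the
noiseless curve the 80%-of-peak crossing is at
`t* = -tau*ln(1 - 0.8*(1 - e^(-10/tau)))`, which reduces to `tau*ln 5`
when `tau << 10 s`; `t*` is the analytic oracle the rise-time tests
use, since for `tau` beyond ~1.8 s the finite-duration saturation
correction exceeds one sampling interval. A logistic rise is available
behind `shape="logistic"` as a shape-robustness check.

Defaults are calibrated to the published summaries of a 31-adult
reference cohort (17 older, 14 younger; 9 male, 22 female), bundled in
`toecurve.reference`: per (age, sex) cell, `plateau` mean/SD are taken
from the peak-force summary and `tau` = rise-time / ln 5. Only the
marginal counts of the 2×2 cells are published; the defaults use
older 4M/13F and younger 5M/9F, which reproduce all four margins.
Subject weight and height come from the sex-stratified summaries (BMI
is computed, keeping the record internally consistent) and grip
strength from the (age, sex) cell summary. All draws are truncated
normals (resampled until positive). Published SDs are treated as
between-subject variability; `noise_cv` (default 0.05, a realistic
fluctuation level for an unfiltered strain-gauge force signal) is the
within-trial sample-to-sample noise.

`induce_correlation` rewrites one subject covariate as a ρ-correlated
Gaussian copy of the per-subject true plateau while preserving the
covariate's marginal mean and SD, so correlation-recovery tests have an
exact target.

What the generator does **not** emulate: physiological tremor spectra
(its noise is white), fatigue-related force decline within the 10 s,
effort onset delays, within-subject repeat variability, or any
covariance between plateau and tau beyond what the cell structure
induces. Passing tests therefore demonstrate that the pipeline recovers
what it is supposed to recover from curves of this class — not that
real recordings satisfy the model.

A known consequence of the peak-as-maximum definition under i.i.d.
multiplicative noise: the extracted peak is the maximum of ~500
perturbed samples, so it sits above the noiseless curve by roughly
`cv * E[max of N standard normals]` — about 5% of the plateau at
cv = 0.02. This is a property of the estimator, not an implementation
artifact; peak comparisons across groups are unaffected (the bias is
common), but absolute peak values are inflated at high noise.

## Statistical analyses

* Descriptives are mean and sample SD (n−1). Empty cells are reported
  missing; single-observation cells have undefined SD and are flagged.
* Two-group comparisons default to Welch's unequal-variance t-test —
  the sex groups are 9 vs 22, and assuming equal variances there is
  gratuitous — with Student's pooled test behind `equal_var=True`.
* The two-way age×sex ANOVA uses type-II sums of squares (via
  `statsmodels` OLS), the standard choice for an unbalanced factorial
  when the interaction is of secondary interest; in a balanced design
  type II coincides with type I, which the tests verify.
* Correlations are Pearson r with two-sided p, overall and within age
  strata, with a Shapiro–Wilk flag per variable per stratum (Spearman
  available via config).
* Significance marks: `*` at p < 0.05, `^` ("trending") at p < 0.10.
  No multiple-testing correction is applied; every report says so.
* Group contrasts are signed differences of group means with the
  convention in the column names (`male_minus_female`,
  `younger_minus_older`).

Null calibration (type-I error within ±0.02 of α = 0.05 at 1000
replicates, ≈3 binomial standard errors) is checked by simulation at
the reference cohort's exact group sizes.

## Classification

The classifiers see the raw 500-sample newton curves, not the extracted
parameters. Models: k-NN (k ∈ {5, 10}, Euclidean), SVM (RBF kernel,
default regularization), random forest (100 trees). Columns are
standardized with statistics fit on the training portion only (k-NN and
SVM are scale-sensitive); toggleable.

Evaluation designs: a single stratified train/validation/test split,
defaulting to 45/25/30 — on 31 subjects that yields 8 validation and
9–10 test subjects, so split accuracies move in ~12.5- and ~11-point
steps — and stratified 3- or 5-fold cross-validation with per-fold
accuracy and the AUC pooled over held-out scores. Continuous scores for
the AUC are the positive-class neighbor fraction (k-NN), vote fraction
(RF), and decision-function value (SVM).

The AUC is computed as the rank-based (Mann–Whitney) statistic with
midranks for ties — `P(score_pos > score_neg) + ½P(tie)` — and is
cross-checked in the tests against both an exhaustive pairwise count
and `sklearn.metrics.roc_auc_score`. A warning is emitted whenever the
minority class is below 35%: with a 9-vs-22 imbalance and single-digit
test sets, accuracy can sit at the majority rate while the AUC reveals
chance-level discrimination, and AUC estimates themselves carry large
sampling error.

## Determinism and problem sizes

Every stochastic step takes an explicit seed; cohort generation and
both evaluation designs are pure functions of their inputs and seed,
and the CLI stamps every output with the config hash and seed. The
bundled verification runs use 1000 random trials for the
oracle-equivalence check, 100 taus for rise-time recovery, 200 trials
for peak recovery, 1000 replicates for each null-calibration rate,
~1000 subjects for correlation recovery, and 200 label permutations
for the chance-level classifier check — sizes at which the Monte-Carlo
error of each quantity is comfortably inside the band being asserted.
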