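# Methods

This note documents the statistical procedures implemented in `mirscreen`,
the parameters that matter, the semantics of the synthetic-data generator,
and the numerical and design choices made where the underlying procedure
left room for interpretation.

## Array quality control

A sample is excluded when the coefficient of variation of its
negative-control probe signals exceeds `cv_max` (default 0.15, linear scale)
or its scanner-flagged probe count exceeds `flag_max` (default 10). The CV
uses the sample (n−1) standard deviation — the conventional estimator for QC
summaries — and is computed on **all** negative controls, without removing
extremes. Both exclusion rules are strict inequalities: a sample at exactly
CV = 0.15 or 10 flags is retained. A sample whose negative-control mean is
zero cannot have a meaningful CV and fails with reason "degenerate
controls". QC is idempotent and partitions the input samples.

## Detection call, background, floor

Per sample, with negative-control signals c₁…cₙ (n ≥ 4):

- **Detection threshold** = mean + 2·sd of the controls after removing
  exactly one minimum and one maximum (n−1 sd). A probe is detected iff its
  raw signal strictly exceeds this threshold.
- **Background** = mean of the controls after trimming `floor(0.05·n)`
  values per side, ranked by intensity (stable sort, so ties resolve in
  input order). Detected signals have the background subtracted and are
  log2-transformed.
- **Floor**: probes that are undetected, or whose corrected signal is ≤ 0,
  receive the constant 0.1 on the log2 scale and are flagged in the
  detection mask. Note that with both trims acting on the same control set
  the threshold can never be below the background, so the ≤ 0 branch is a
  boundary case rather than a common path.

## Internal-control normalization

Arrays are aligned by a per-sample log2 shift `preset − mean(log2 of the
internal controls)`, i.e. a multiplicative rescaling of linear signals. The
internal controls are miR-149-3p, miR-2861 and miR-4463; the preset value
defaults to 8.0 log2 units (the original vendor constant is not public, and
any constant only changes all indices by a panel-dependent offset). The
mean is taken over internal controls that were detected; floored values
(0.1) are exempt from the shift so that "undetected" remains a fixed
sentinel across arrays. Floor-then-normalize (rather than the reverse) was
chosen for exactly this reason. A sample whose internal controls are all
floored cannot be normalized and is a hard error.

After normalization the per-sample mean of detected internal controls equals
the preset value to 1e−9, and the transform is strictly monotone in the raw
signal for detected probes.

## Candidate filters

- **Exosome presence**: keep miRNAs detected in ≥ `min_lines` (default 1) of
  the 12 ovarian-cancer cell lines, from a precomputed presence table.
  Detection calls on the cell-line arrays themselves are upstream of this
  package.
- **Serum prevalence**: keep miRNAs whose log2 signal strictly exceeds 6
  (raw > 2⁶) in strictly more than 50% of the cohort samples. The cohort is
  the ovarian-cancer serum samples — in the pipeline, the *discovery-half*
  cancer samples, so the validation set never influences marker selection;
  the cohort is configurable. Both inequalities are strict, and raising
  either threshold can only shrink the candidate set.

## Pivot miRNAs and qRT-PCR gates

Single-marker AUC is the tie-corrected Mann–Whitney statistic
AUC = P(X_case > X_control) + ½·P(equal), computed from midranks; it is
invariant under strictly increasing transforms and equals a brute-force
count over all case×control pairs. Markers are ranked by the oriented AUC
`max(AUC, 1−AUC)` so down-regulated miRNAs compete equally (panel
coefficients may take either sign); ties break to the lexicographically
smaller id. The top `n_pivots` (default 10) are the pivots.

The qRT-PCR gates are two Pearson correlations: dilution-series linearity
(pass iff r > 0.9, strict — the boundary value itself fails) and
array-vs-PCR concordance. PCR abundance is reported as Ct, an inverse
scale, so concordance passes iff r < 0; a flag flips the convention for
abundance-scale readouts. Zero variance in either coordinate fails the gate
with an explicit reason.

## Fisher discriminant and panel search

For panel matrix X and labels y ∈ {0,1} (1 = ovarian cancer):

- weights `w = S⁻¹(μ₁ − μ₀)` with S the pooled within-class covariance
  (denominator n − 2);
- intercept `b = −w·(μ₀ + μ₁)/2`, i.e. equal class priors. The index is a
  screening score with a fixed 0 threshold, so the boundary must not depend
  on cohort prevalence (the discovery sets are highly imbalanced in the
  emulated studies);
- singular S gets a ridge of `1e−6 · trace(S)/p` on the diagonal, with a
  warning; identical class means are a hard "degenerate separation" error.

The panel search enumerates **every** subset of the pivot miRNAs of size
1..`max_panel` (default 10; 1023 subsets for 10 pivots, capped at 20 pivots)
and scores each by exact leave-one-out cross-validation: each sample is
classified by the sign of an index fit on the remaining n−1. The selection
metric defaults to **balanced accuracy**; plain accuracy is available but
with imbalanced discovery sets it rewards the trivial all-negative
classifier. The winner is chosen by the deterministic chain (higher metric,
smaller panel, higher training AUC, lexicographically smaller panel) and
refit on the full discovery set. LOOCV selects among *subsets*; the
coefficients of the winner come from the full-discovery refit.

LOOCV is computed without per-fold refits: class means and scatter matrices
are downdated for the held-out sample and the pooled-scatter inverse is
updated by a rank-1 Sherman–Morrison step, making each fold O(p²). The
plain per-fold refit loop is retained as the reference implementation (the
two are tested for exact agreement) and as the fallback whenever the total
scatter is not positive definite or a downdate turns numerically singular
(denominator < 1e−10). A fold whose training set contains a single class
counts as misclassified, with a warning.

## Published indices

The three published models are stored in a versioned TSV inside the package
(panel, coefficients, intercepts −9.375, −25.0, −7.2) and verified against a
SHA-256 checksum at load time, guarding against transcription errors. The
score is the plain linear form over normalized log2 signals with the ≥ 0
decision rule; an index of exactly 0 is a positive call. **Caveat**: the
original scale convention of these coefficients (in particular whether
inputs were standardized) is not documented; this package applies them to
its own normalized log2 signals, which reproduces the formulas exactly but
makes no claim about reproducing the original cohort AUCs, which would
require the original array data.

## Evaluation

ROC curves enumerate all distinct score thresholds; AUC is the same rank
statistic as the marker AUC, so the two agree exactly on identical inputs.
Sensitivity, specificity and accuracy are reported at the fixed 0 threshold;
a Youden-optimal threshold is available for synthetic studies. Subgroup
tables report the positive-call rate for case groups (all FIGO stages;
ovarian-cancer and non-epithelial class labels) and the negative-call rate
for control groups, plus the group mean index. Logistic odds ratios per unit
index are maximum-likelihood fits by IRLS (statsmodels GLM, binomial
family, ≤ 100 iterations), without and with an age covariate; confidence
intervals are Wald, `exp(β ± 1.96·se)` — the CI method of the emulated
report is not stated, and Wald matches its symmetric style. Complete
separation and non-convergence are hard errors rather than silently huge
estimates.

## Synthetic-data generator

The generator emulates the structure the analysis assumes, not any real
array platform:

- target log2 signals i.i.d. Normal(`baseline_mean` = 7.0,
  `baseline_sd` = 1.0); informative miRNAs additionally shifted by
  `effect_size` (default 2.0 log2 units = 2 sd, all positive: the candidate
  cascade is designed around tumor-released, serum-abundant markers)
  multiplied by a stage factor (0.5 / 0.75 / 1.0 for stages I / II /
  III–IV); stages drawn with probabilities (0.25, 0.10, 0.65), matching the
  stage mix of the emulated cohorts;
- default cohort 300 cancer + 300 non-cancer samples and 200 target
  miRNAs with 10 informative; other tumor classes (other-cancer,
  borderline, benign) available with attenuated effect fractions (0, 0.5,
  0.25) and default count 0;
- institute batch effects as array-wide log2 shifts (A: 0, B: +0.3,
  C: −0.3), applied to targets and internal controls alike, with non-cancer
  samples drawn from institutes in proportions (0.08, 0.57, 0.35); because
  the shift is array-wide, internal-control normalization removes it;
- internal controls at log2 (8.0, 7.5, 8.5) plus institute shift and
  per-sample noise (sd 0.1); negative controls linear
  Normal(20, 2) truncated at 0 — CV 0.10, safely below the QC cut so only
  outlier arrays fail QC;
- signals converted to the linear scale with additive scanner background
  drawn from the negative-control distribution; a `dropout_rate` = 0.005
  fraction of cells collapses to background level (below detection),
  modeling rare technical dropout of otherwise well-expressed serum
  miRNAs; flagged-probe counts are Binomial(n_probes, 0.002);
- ages Normal per class (cancer 56.8 ± 11.5, non-cancer 45.5 ± 10.8),
  clipped to [20, 90].

All randomness derives from one seed through named `SeedSequence` streams
(cohort / exosome table / PCR tables, and a fourth for the
discovery–validation split), so each sub-generator is reproducible in
isolation and pipeline reruns are byte-identical.

What the generator does **not** emulate: probe cross-hybridization and
sequence-dependent affinity, signal-dependent (heteroscedastic) noise and
intensity-dependent dropout, correlated miRNA co-regulation, or any real
miRBase content. Passing end-to-end tests therefore demonstrates that the
pipeline machinery recovers planted signal under its own statistical
assumptions — not that the published panels generalize to real serum data.

## Problem sizes and runtime

The default study conditions (600 samples × 233 probes, 10 pivots, 1023
enumerated subsets with n = 300 LOOCV folds each) run end-to-end in a few
seconds on one CPU thanks to the downdated LOOCV; oracle suites use 50–200
random instances with n ≤ 30. The acceptance script runs the full and null
pipelines plus all oracle comparisons in well under a minute.

## Known limitations

- The exhaustive search is exponential in the pivot count and deliberately
  capped at 20 pivots.
- "Other miRNAs were used to compensate" in the emulated workflow has no
  executable definition; the search pool is the validated pivots only, with
  a config hook to append further AUC-ranked candidates.
- Logistic CIs are Wald; profile-likelihood intervals are out of scope.
- No batch correction beyond internal-control normalization, and no
  quantile or global-median normalization.
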