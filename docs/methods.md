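# Methods

This note documents the statistical model behind `deliriscore`, the design
choices made where the procedure admitted more than one reasonable
implementation, and what the synthetic cohorts do and do not establish.

## The score-construction procedure

The pipeline reproduces a classical "points system" development workflow
for a binary outcome (delirium in older ED observation-unit patients):

1. **Univariate screening.** Each candidate is fitted alone in a logistic
   model of the outcome. We use maximum likelihood (statsmodels `Logit`,
   Newton, convergence tolerance 1e-10) and Wald inference: the reported
   95% CI is `exp(β ± 1.96·SE)` and the p-value is the Wald z-test. The
   selection threshold `p ≤ 0.200` is inclusive. Likelihood-ratio or
   profile intervals would be defensible alternatives; Wald is the common
   default and is used package-wide for consistency.
2. **Dichotomization.** Continuous candidates enter the score only through
   clinically anchored flags (age ≥ 75 y; SBP < 120 mmHg; Na < 135 mEq/L;
   Hb < 10 g/dL; `ge` means value ≥ cutoff, `lt` means value < cutoff, both
   evaluated exactly at the boundary). When a continuous variable and its
   flag both pass screening, only the flag is retained (the dedup map is
   explicit configuration, defaulting to the three pairs age/age≥75,
   SBP/SBP<120, Na/Na<135).
3. **Exhaustive search.** All component subsets of size 2–4 crossed with
   all integer weight vectors in {1,2,3}^k are enumerated — weight
   permutations across components are distinct definitions, which is
   exactly why 7 candidates yield Σ C(7,k)·3^k = 3969 definitions. Each is
   scored by the tie-aware Mann–Whitney AUC.
4. **External validation.** The maximizer is applied unchanged to an
   independent cohort.

## Exact AUC and tie handling

All discrimination measures use one convention: for each (case, non-case)
pair the case's higher score counts 1, a tie counts 1/2. We store the
*doubled* numerator `2·wins + ties` (an integer) together with `n₊·n₋`, so
AUCs from the same cohort are compared as integers. This matters because
integer scores on small cohorts produce many exact AUC ties among the 3,969
candidates; float comparison would make the argmax depend on summation
order. The tie-aware ROC polygon (one vertex per distinct score threshold,
positivity rule `S ≥ c`) has trapezoidal area identical to this AUC; the
suite checks the identity to 1e-12.

Tie-breaking among equal-AUC definitions is not dictated by the procedure
itself; we break ties by parsimony — fewer components, then smaller total
weight, then canonical enumeration order (subset size ascending, subsets in
lexicographic candidate order, weight vectors in odometer order) — making
the search output deterministic.

The search collapses patients onto their unique candidate-pattern (at most
2^m patterns for m binary candidates, with outcome-stratified pattern
counts) before scoring, so each definition is evaluated on ≤ 2^m weighted
rows; 3,969 definitions on n = 5,000 take well under a second. The general
`exact_auc` routine is O(n log n) sorting/counting and never loops over
pairs; an O(n²) all-pairs oracle exists only in the test suite.

## Separation

A binary predictor with a zero cell in its 2×2 outcome table has an
infinite ML odds ratio. Such rows are reported with the Haldane–Anscombe
correction (0.5 added to every cell, Wald inference on the corrected
table), flagged `separation_detected`, and remain eligible for selection —
screening tables in this setting routinely keep extreme-CI rows rather than
dropping them. Firth penalization would be a heavier alternative; the
corrected estimate is only used for reporting, never for score weights.

## Synthetic cohorts

Real patient-level data of this kind are shareable only on request, so the
generator is a first-class module, not a test fixture. Its defaults *are*
the study conditions the package targets:

| parameter | default | origin |
|---|---|---|
| training n / prevalence | 257 / 16.1% | study sample |
| testing n / prevalence | 107 / 34.6% | study sample |
| conditional ORs: dementia, hearing, psychotropics, age≥75 | 18.33, 8.07, 5.55, 9.22 | published univariate estimates |
| conditional ORs: infection, SBP<120, Na<135 | 2.23, 2.49, 2.54 | published univariate estimates |
| drug-subclass prevalences (antiepileptics, atypical AD, opioids, TCA) | 2.5%, 0.8%, 6.1%, 1.1% | published |
| dementia, hearing, age≥75, psychotropics-total, infection, SBP<120, Na<135 prevalence | 0.25, 0.20, 0.65, 0.30, 0.30, 0.15, 0.12 | **placeholders** (descriptive table not available) |

Testing-cohort shifts (age≥75 0.80, dementia 0.35, infection 0.40) echo the
reported qualitative differences between the samples; they are likewise
placeholders, chosen once.

Model: independent Bernoulli covariates (a Gaussian copula is available but
off by default — no dependence information is published); the psychotropics
composite is generated *structurally* as the OR of the four published
subclasses plus a residual "other psychotropics" class whose prevalence
solves `P(any) = 0.30`, so the `any_of` derivation rule holds on synthetic
data and subclass flags imply the composite. The outcome is Bernoulli with
`P = expit(α + Σβx)`.

**Non-collapsibility caveat.** The published effect sizes are univariate
(marginal) odds ratios, but the generator plants them as *conditional*
log-odds in one multivariable model. Marginal univariate estimates on
synthetic data therefore exceed or undershoot the planted values slightly
even with independent covariates; all recovery checks use the multivariable
refit. Consequently, passing tests show the pipeline recovers what was
planted — they do not show the synthetic cohorts match the real samples'
joint distribution, inter-covariate dependence, missingness patterns, or
the real-data AUCs (0.874/0.893) and per-point ORs (2.22/2.35), which are
reference values, not simulation targets. A property-level echo is tested
instead: on default cohorts the selected score's per-point OR exceeds 2 in
≥ 90% of seeds.

**Intercept calibration.** Prevalence is strictly increasing in α, so α is
found by Brent's method on [-40, 40] (xtol 1e-12). When every effect-bearing
covariate is binary (directly or through an `any_of` flag) and no copula is
requested, the expectation is computed exactly by enumerating all base
binary patterns (≤ 2^20); otherwise a fixed-seed Monte-Carlo average over
200,000 draws is used. Calibrated expected prevalence matches the target to
better than 1e-6 on the exact path.

**Reproducibility contract.** One `numpy.random.default_rng(seed)` stream
per cohort; covariates are drawn in spec order, then derived flags are
computed, then outcomes drawn. Identical (spec, seed, n) gives bitwise
identical cohorts, and a fixed pipeline seed reproduces every numeric
artifact byte-for-byte.

## Numerical and degenerate-input choices

- Missing data: complete-case per run; records missing the outcome or any
  candidate are dropped at ingest with a logged count. No imputation.
- ppv/npv with a zero denominator are reported as explicit `undefined`
  (JSON `null`), never 0.
- AUC with a single-class outcome, constant scores in the per-point fit,
  and a single-class no-dementia subgroup are hard errors, not NaNs.
- `threshold_or_flag` derivation uses *strictly greater than* the threshold
  (CRP = 5 mg/L does not flag suspected infection).
- Binary columns accept exactly 0/1/empty at ingest; anything else is a
  validation error naming the column and line.

## Problem sizes used in checks

The suite and the acceptance script use n = 200,000 cohorts for calibration
and parameter-recovery checks (Monte-Carlo prevalence error ≈ 0.08
percentage points, refit SEs small enough for 10% OR tolerances), n = 5,000
× 20 seeds for planted-score recovery, and n ≤ 50 × 200 instances for the
brute-force AUC equivalence. These sizes were chosen so each check's
sampling noise is an order of magnitude below its tolerance.

## Known limitations

- Covariate prevalences marked as placeholders above shift the synthetic
  cohorts' AUC and score distribution; replace them if descriptive data
  become available.
- The generator does not emulate missingness, measurement error, or
  covariate dependence by default.
- Only binary components are admissible in scores; graded (multi-level)
  point assignments per variable are out of scope.
- The search optimizes in-sample training AUC, exactly as the procedure
  prescribes; it inherits that procedure's overfitting risk, which is why
  external validation is part of the pipeline.
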