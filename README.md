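# deliriscore

Development and external validation of simple integer-point clinical risk
scores, built around the workflow used to construct a delirium risk
assessment tool for older (65+) patients admitted to an Emergency Department
Observation Unit: univariate logistic screening of candidate predictors in a
training cohort, an **exhaustive search over every integer-weighted
combination of screened variables** ranked by nonparametric ROC AUC, and
external validation of the winning score in an independent testing cohort.

The package is aimed at clinical epidemiologists and biostatisticians who
want this score-construction procedure as tested, reusable code. Because
patient-level ED data of this kind are typically not redistributable, it
ships a synthetic-cohort generator that emulates the two study samples, so
the entire pipeline runs end-to-end without access to raw data.

## The method

**Screening.** Each candidate predictor `x` is screened with an unadjusted
logistic model `logit P(Y=1) = α + βx`, reporting `OR = exp(β)`, its Wald
95% CI and p-value, and the tie-aware rank AUC of `x`. Candidates with
`p ≤ 0.200` are selected; continuous variables are dichotomized at clinical
cutoffs (age ≥ 75 y, SBP < 120 mmHg, Na < 135 mEq/L, Hb < 10 g/dL) and only
the binary form enters the score. Separation is handled with the
Haldane–Anscombe 0.5 correction plus a flag.

**Search.** A score assigns integer points `w_i ∈ {1,…,3}` to `k ∈ {2,…,4}`
selected binary components; a patient's score is `S = Σ w_i x_i`. Every
admissible definition is enumerated — `Σ_k C(n,k)·3^k`, which is **3,969**
for n = 7 candidates — and evaluated by the exact tie-aware Mann–Whitney
AUC, kept as a rational number (`2·wins + ties` over `2·n₊·n₋`) so the
maximum is found by integer comparison with no floating-point ties. Equal
AUCs break deterministically: fewer components, then smaller total weight,
then enumeration order.

**Validation.** The selected score is applied to the testing cohort:
tie-aware ROC and exact AUC, a sensitivity/specificity table over all
cutoffs (positive ⇔ `S ≥ cutoff`), the per-point odds ratio from
`logit P(Y=1) = α + β·S`, and the same fit in the dementia-free subgroup.

**Simulation.** Synthetic cohorts draw binary covariates as Bernoulli flags
(psychotropic drug subclasses are drawn separately and OR-ed into the
composite flag), and the outcome as Bernoulli with
`P = expit(α + Σ β_i x_i)`, where the planted `β` are published effect
sizes and `α` is calibrated by exact root-finding so the marginal delirium
prevalence hits the target (16.1% training, 34.6% testing).

## Worked example

```bash
cat > config.yaml <<'EOF'
seed: 7
cohorts:
  training: {spec: training_default, n: 2000}
  testing:  {spec: testing_default,  n: 800}
EOF
deliriscore --log-level WARNING run --config config.yaml --out-dir out/
```

prints

```
screened: age_ge75, dementia, hearing_impairment, suspected_infection, systolic_bp_lt120, sodium_lt135, psychotropics
tested 3969 scores; best {'age_ge75': 2, 'dementia': 3, 'hearing_impairment': 2, 'psychotropics': 2} training AUC 0.888
testing AUC 0.857
```

Seven candidates pass the `p ≤ 0.200` screen on this simulated training
cohort, so the search enumerates all 3,969 admissible scores. The winner is
a four-component score over age ≥ 75, dementia, hearing impairment and
psychotropic use — the same component set as the published tool, with
weights that can differ draw by draw — whose discrimination holds up in the
independent testing cohort (AUC 0.857). `out/` then contains the screening
table (`screening.csv`), the full search ranking (`search.json`), and per-
cohort validation reports (JSON + markdown + ROC points TSV), e.g.:

```
| cutoff | sensitivity | specificity | ppv | npv |
|---|---|---|---|---|
| >= 3 | 0.942 | 0.599 | 0.504 | 0.960 |
| >= 5 | 0.715 | 0.821 | 0.634 | 0.869 |
```

Each stage is also available separately (`deliriscore simulate / screen /
search / validate`) and as library functions (`deliriscore.search_best`,
`deliriscore.exact_auc`, …).

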