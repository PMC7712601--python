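# ctebayes

Bayesian subgroup discovery for conditional treatment effects on
right-censored survival data.

Patients are stratified exhaustively over nine dichotomized baseline
covariates (2^9 = 512 cells).  Within each cell, every treated/untreated
pair whose survival ordering is determinable under censoring contributes a
Bernoulli "win" observation for the treated arm; the win probability Y gets
a conjugate Beta posterior (uniform Beta(1,1) prior).  Cells are screened
with a Bayes factor against the no-effect point Y = 0.5 (Savage–Dickey
ratio, threshold 3) and ranked by their 95% equal-tailed credible bounds:
the *optimal* cell maximizes the lower bound above 0.5, the *worst* cell
minimizes the upper bound below 0.5.  The selected cell's net benefit is
compared against the pooled complement via P(Y* > Y_rest) with a 0.95 mass
criterion.  Supporting machinery: KNN covariate imputation, logistic
propensity fitting with greedy caliper matching on the logit score,
Kaplan–Meier curves, (pair-stratified) log-rank tests and O/E hazard
ratios, plus a synthetic cohort generator with planted, certified ground
truth for validation.

## Package layout

| module                 | contents                                                        |
|------------------------|-----------------------------------------------------------------|
| `ctebayes.cohort`      | data model, delimited I/O, KNN imputation, dichotomization, 512-cell stratification |
| `ctebayes.simulate`    | synthetic cohort generator (Weibull PH, logistic confounding, exponential censoring, masking) and Monte-Carlo truth certification |
| `ctebayes.propensity`  | logistic propensity fit (Newton), greedy 1:1 caliper matching, standardized mean differences |
| `ctebayes.survival`    | Kaplan–Meier with Greenwood variance, (stratified) log-rank, O/E hazard ratio |
| `ctebayes.bayes`       | win counting under censoring, conjugate updates, credible intervals, Bayes factors, optimal/worst selection |
| `ctebayes.report`      | pooled-complement net-benefit comparison and the end-to-end pipeline |

## Command line

```sh
ctebayes simulate --config cfg.json --out cohort.csv --truth-out truth.json
ctebayes match     --input cohort.csv --treatment chemo \
                   --out-pairs pairs.csv --out-balance balance.csv
ctebayes subgroups --input cohort.csv --treatment chemo --min-n 30 \
                   --out table.csv --verdict-out verdict.json
ctebayes report    --input cohort.csv --treatment chemo --out report.json
```

The cohort table is comma- or tab-delimited with header columns
`id, age, sex, size_cm, site, seer_stage, surgery, rt, chemo, histology,
time_months, event`; missing covariates are empty/NA.  Rows with missing
treatment indicators are dropped and counted in an exclusion report.

## Known methodological caveat

Win tallies pool *all* treated x untreated pairs in a cell, so the
comparable-pair count n overstates the effective sample size: the win
fraction is a U-statistic whose sampling spread scales with
1/sqrt(patients), while the Beta posterior narrows with 1/sqrt(pairs).
Large cells are therefore overconfident under the null.  This behavior is
inherent to the method being implemented; `n_incomparable` and the
`min_n` selection guard make the information loss and small-cell
exclusions visible but do not correct the pooling.  See
`tests/test_acceptance.py::test_criterion_7_null_calibration` for a
quantified demonstration.
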