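# Methods

## Background model

Per-gene recurrence is modeled as gamma-Poisson. The observed statistic
y_i is the number of distinct patients with at least one High/Moderate
impact mutation inside gene i's eligible coding territory (t_i bases);
capping each patient at one mutation per gene makes y_i robust to local
hypermutation and to duplicated variant calls. The regression

    y_i ~ NB(mu_i, phi),   log mu_i = log t_i + b0 + x_i . b

uses the NB2 parameterization (Var = mu + phi mu^2). Covariates x_i are
per-gene averages of genomic tracks over eligible bases, grouped into
families (replication timing, chromatin state, sequence context), each
family standardized and reduced to its leading principal components before
entering the regression. At full study scale the reduction keeps 50/200/50
components per family; the synthetic fixtures use 2/3/2 because their
covariomes have that many latent factors by construction.

Dispersion phi is estimated by maximum likelihood jointly with the
coefficients (statsmodels' NB2 likelihood, started from the Poisson
solution). When the estimate collapses below 1e-6, exceeds a cap of 1e4, or
the NB optimizer fails on a boundary case, the model is refit as a Poisson
GLM — the phi -> 0 limit of the same model — and phi is reported as exactly
0. A hard failure of the Poisson GLM raises a ConvergenceError carrying the
problem size and dispersion.

Significance is the right tail p_i = P(Y >= y_i) under the fitted
distribution with mean e_i and dispersion phi — no mid-p correction, so
y_i = 0 gives p_i = 1 exactly. Multiple testing uses Storey q-values: the
spline-smoother pi0 estimate over the grid lambda = 0.05..0.95 for the
recurrence stage, and pi0 fixed at 1 (lambda = 0, i.e. the Benjamini–
Hochberg step-up) for the association stage. Genes with zero eligible
territory or undefined covariates are excluded from fitting and testing.

### Calibration diagnostic and its known bias

The inflation factor lambda is the least-squares slope through the origin of
sorted observed -log10 p against -log10 uniform order-statistic quantiles
((i - 0.5)/m), computed over all tested genes without trimming; p = 0 is
clamped to the smallest positive float with a warning.

A property worth knowing: for discrete counts the right-tail p-value is
conservative (P(p <= t) <= t, with an atom at p = 1 for y = 0), so on a
*perfectly specified* null the slope-lambda sits below 1 whenever per-gene
expected counts are modest. Monte Carlo: a pure Poisson null gives
lambda ≈ 0.86 at e = 5, 0.89 at e = 10, 0.92 at e = 20, approaching 1 only
as counts grow continuous. At exome-realistic mutation density
(~10 High+Moderate mutations/Mb, per-gene e ≈ 5 over ~300 patients) a fully
calibrated screen therefore shows lambda ≈ 0.85–0.90, not 1.0; values near
or above 1 on real data indicate residual model misspecification offsetting
this conservatism. The test suite asserts the conservative band
[0.80, 1.05] on null simulations, alongside the empirical-FDR bound.

## Pathway test

A gene set I is tested by the intercept-only gamma-Poisson regression of
y_i on offset log e_i restricted to I; in the Poisson limit the intercept
is log(sum_I y / sum_I e). The p-value is one-sided (right) on the Wald
statistic of the intercept — recurrence is an enrichment question. The set
regression re-estimates its own dispersion when the set has >= 10 tested
genes and otherwise keeps the global estimate. An all-zero set returns
intercept -inf with p = 1. Redundancy pruning scans nominated sets in
increasing-p order (ties: larger intercept, then name) and drops a set
sharing strictly more than 40% of its universe-restricted genes with any
retained set; the denominator is the candidate's own gene count, and a
Jaccard denominator is available as an option. Screen-hit overlap is the
one-sided hypergeometric upper tail with step-up q-values across sets.

## Association and classifier

Stage-2 association is an unpenalized logistic fit per feature with age,
log2(TMB + 1), tumor type and study of origin as covariates; categorical
terms are reference-coded against their most frequent level. Complete or
quasi-complete separation is detected from diverging coefficients/standard
errors (|a1| > 15 or SE > 50) or an optimizer failure; such features are
reported with an infinite-CI sentinel rather than penalized or dropped,
since a plain-ML odds ratio is the estimand. TMB uses a +1 pseudocount
before log2 so zero-mutation patients stay defined. The TMB-high split is
strict: > 10 mutations/Mb, with the per-Mb conversion defaulting to a 38 Mb
territory (configurable; logged when defaulted).

CIRCLE is the same logistic machinery on the selected genes + pathways +
age + log2 TMB + tumor type (study of origin deliberately excluded: it is a
batch variable, not a transportable predictor). The benchmark baseline is a
single-feature logistic classifier on log2 panel-restricted TMB.

Monte Carlo cross-validation draws tumor-type-stratified 75/25 splits
(per-stratum train size round(0.75 n_s), globally corrected to within one
patient of round(0.75 N); tumor types with fewer than 8 included patients
are pooled into the modal stratum before splitting). Per iteration the
model is fit on the train fold and the ROC recorded on the test fold; a
split leaving either fold single-class is redrawn (bounded retries).
Aggregation: ROC curves (and their thresholds) are vertically averaged on a
fixed FPR grid of step 0.01; the operating cutoff is the averaged-curve
point closest to (0, 1) in Euclidean distance, ties resolved toward the
lowest (most sensitive) threshold; each patient's consensus call is the
majority vote over their test-fold appearances with exact ties going to
non-responder (the conservative call), and their consensus score the mean
test-fold probability. AUPRC is the trapezoid over the precision–recall
curve; Theta is the Hedge's-g standardized difference of consensus scores
between true responders and non-responders. The DeLong comparison uses the
midrank algorithm (verified against R pROC to 7 decimals); identical score
vectors return p = 1 by convention, and zero variance with unequal AUCs is
surfaced as an error. The whole report is a pure function of
(design, labels, strata, seed). With 100 iterations every patient reaches a
test fold in practice; shorter runs may opt out of the full-coverage
guarantee, in which case consensus quantities cover voted patients only.

Hedge's g uses the pooled sample-size-weighted SD, the small-sample
correction J = 1 - 3/(4 df - 1), and a normal-approximation CI with
Var(d) = (n1+n2)/(n1 n2) + d^2 / (2(n1+n2)).

## Survival

Kaplan–Meier with log(-log) 95% bands, the two-group log-rank test, and Cox
proportional hazards with Efron tie handling (lifelines throughout). For
ICB validation the Cox covariate set is tumor type; a monotone likelihood
is reported as a sentinel row rather than raised. Both the dichotomized
CIRCLE call and the continuous score can be tested.

## Synthetic cohorts

The generator emulates the generative assumptions above with known ground
truth. Defaults define the study-scale conditions:

* 300 patients over four tumor types at the mix of a dichotomized
  aggregated ICB cohort (74% melanoma, 15% NSCLC, 8% bladder, 3% head and
  neck); ~15% stable-disease labels that downstream stages exclude.
* 2,000 genes with lognormal CDS lengths (median ~1.35 kb); neutral rate
  1e-5 per base per patient, i.e. ~10 functional mutations/Mb — exome-scale
  mutation density.
* Covariates: three families of noisy linear mixtures of 2/3/2 latent
  factors; one factor per family carries a log-linear rate effect
  (0.4/0.3/0.2), giving ~0.5 SD of explainable log-rate variation.
* Counts per patient-gene are gamma-Poisson with NB2 dispersion 0.3 and a
  lognormal per-patient activity multiplier (sigma 0.75). The activity
  spread is pinned so that, under the default logistic TMB effect, generated
  responders carry ~1.4x the TMB of non-responders — the fold difference
  reported for real aggregated ICB cohorts.
* Five drivers (ten in the power studies) at a 5x rate excess, placed at
  gene-length quantiles 0.4–0.9: real driver genes are typical-length coding
  genes, not 150 bp fragments, and a driver on a minimal fragment would be
  undetectable by any method at this cohort size.
* Response: logistic on driver-mutation status (effects -1.5, +1.0, -0.8,
  +0.7, 0), centered log2 TMB (+0.4 per doubling), age (+0.2 per decade),
  intercept -0.8 (~35% responders). Survival: exponential event times with
  responder hazard ratio 0.5, exponential censoring.

All randomness flows through one SeedSequence with per-stage substreams, so
genome, counts, mutation rows, clinical and survival stages can be
regenerated independently and every product is a pure function of
(config, seed).

What the generator does *not* emulate: trinucleotide mutational signatures,
copy-number events, subclonal structure, inter-study batch effects beyond a
study label, coverage heterogeneity within genes, or correlated pathway
co-mutation. Passing tests therefore demonstrate statistical correctness of
the estimators under the model's own assumptions, not robustness to every
failure mode of real exome data.

### Power of driver recovery

Under the default conditions the weakest planted driver (neutral
expectation e ≈ 3, mutated-patient mean ≈ 13) misses a top-20 p-value rank
in roughly 5% of seeds from count fluctuation alone — an oracle that knows
the true covariates misses the same seeds. Consequently "9 or 10 of 10
drivers in the top 20" is routine (>= 90% of seeds; mean recovery ~9.5),
while "all 10 simultaneously" occurs in only ~50–70% of seeds. This is a
power bound of the cohort size and effect size, not an estimator defect.

## Problem sizes

The calibration study uses 100 null replicates, driver recovery 20 seeds,
and the benchmark 100 CV iterations (25 in the quick dominance checks) —
sizes at which every reported Monte Carlo quantity has a standard error
well inside the bands asserted on it, while the full suite and the
acceptance script each complete in about a minute on one CPU.

## Known limitations

* The NB tail probabilities condition on the fitted (e_i, phi); estimation
  uncertainty in the background is not propagated into p_i.
* Eligible-territory masks and covariate tracks are consumed as inputs; no
  coverage computation is performed.
* The association stage fits one feature at a time; correlated features
  (e.g. a gene and a pathway containing it) are tested marginally, as in
  the two-stage design itself.
* Stage-1 p-values are computed on the same cohort that stage 2 then tests
  for response association; the two-stage design controls this by
  conditioning nomination only on mutation counts, never on response.
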