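# circleicb

Two-stage discovery of somatic-mutation biomarkers of immune-checkpoint-blockade
(ICB) response, and the **CIRCLE** logistic classifier built from them.

Only a minority of patients respond durably to checkpoint blockade, and tumor
mutational burden (TMB) — the count of High + Moderate impact somatic
mutations — is an imperfect predictor. The idea implemented here is that
*which* genes are mutated carries signal beyond *how many* mutations a tumor
has: genes under positive selection harbor functional mutations that can make
a tumor more, or less, visible to the immune system. The package is aimed at
computational oncologists working with aggregated whole-exome ICB cohorts
(MAF-like mutation tables plus RECIST-annotated clinical tables).

## The method

**Stage 1 — recurrence nomination.** For gene *i* with observed recurrence
count *y<sub>i</sub>* (number of patients carrying ≥ 1 High/Moderate mutation
in its eligible coding territory of *t<sub>i</sub>* bases; each patient
contributes at most 1), a gamma-Poisson (negative binomial) background model

  *y<sub>i</sub>* ~ NB(*μ<sub>i</sub>*, φ),  log *μ<sub>i</sub>* =
  log *t<sub>i</sub>* + β₀ + **x**<sub>i</sub>·**β**

estimates the neutral expectation *e<sub>i</sub>* from genomic covariates
**x**<sub>i</sub> (replication timing, chromatin state, sequence context —
each family reduced by PCA). A gene is recurrently mutated when the
right-tail probability *p<sub>i</sub>* = P(*Y* ≥ *y<sub>i</sub>*) under the
fitted distribution is small; nomination uses Storey *q* < 0.1, with the
genomic inflation factor λ (slope of observed vs expected −log₁₀ *p*
quantiles) as the calibration diagnostic. Gene sets are tested through the
intercept-only regression *y<sub>i</sub>* ~ offset(log *e<sub>i</sub>*) over
the set, redundant sets (> 40 % shared genes with a more significant set) are
pruned, and overlap with an external CRISPR-screen hit list is scored by a
one-sided hypergeometric test.

**Stage 2 — response association and CIRCLE.** Each nominated feature becomes
a binary HasMutation indicator tested in

  Response ~ Logistic(α₀ + α₁ HasMutation + α₂ TumorType + α₃ Age +
  α₄ log₂TMB + α₅ StudyOfOrigin)

over patients with a dichotomized RECIST response (CR/PR = responder, PD =
non-responder, SD excluded). OR = e^α₁ with q < 0.2 (Storey, λ = 0) defines
the significant features, which — together with age, log₂ TMB and tumor
type — form the CIRCLE logistic classifier. CIRCLE is benchmarked against a
panel-TMB logistic baseline by 100 Monte Carlo cross-validation iterations
(tumor-type-stratified 75/25 splits): vertically averaged ROC curves, the
cutoff closest to (0, 1), majority-vote consensus calls, sensitivity/
specificity/F1, AUPRC, the standardized score difference Θ, a paired DeLong
AUC comparison, and Kaplan–Meier / log-rank / Cox survival stratification of
the consensus calls.

A synthetic-cohort generator (`circleicb.simulate`) reproduces the
statistical structure this analysis assumes — covariate-driven neutral
mutation counts, planted drivers with a multiplicative rate excess, logistic
response labels, censored survival — so the entire pipeline is testable with
known ground truth.

## Worked example

```python
from circleicb.simulate import SimConfig, simulate_cohort
from circleicb.pipeline import nominate_genes, benchmark_classifiers

sim = simulate_cohort(SimConfig(), seed=7)        # 300 patients, 2,000 genes
table, fit = nominate_genes(sim)                  # stage 1
nominated = table[table["nominated"]]
print(nominated[["y", "e", "p", "q"]].head())

out = benchmark_classifiers(sim, n_iter=100, seed=7)   # stage 2 + benchmark
print(out["circle"].mean_auc, out["tmb"].mean_auc, out["delong_p"])
```

Output:

```
dispersion phi = 0.024
nominated 5 genes at q < 0.1 (5 of 5 planted drivers)
        y       e    p       q
G1758  41  7.2011  0.0  0.0000
G1474  27  5.1945  0.0  0.0000
G0838  24  4.3864  0.0  0.0000
G0733  18  4.0276  0.0  0.0009
G0689  15  2.9874  0.0  0.0010

selected features: ['G1474', 'G0733']
CIRCLE    mean CV-AUC = 0.616 (sd 0.062)
panel TMB mean CV-AUC = 0.557 (sd 0.072)
consensus sensitivity 54.4%  specificity 63.4%  F1 0.46
DeLong p (CIRCLE vs panel TMB) = 0.012
```

All five planted drivers are recovered at *q* < 0.1 against a calibrated
background (observed counts *y* of 15–41 patients against neutral
expectations *e* of 3–7). Two drivers carry a response effect strong enough
to survive the stage-2 screen at this cohort size; combining them with age,
log₂ TMB and tumor type lifts the cross-validated AUC significantly above
the panel-TMB baseline (DeLong p = 0.012).

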