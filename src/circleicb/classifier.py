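"""CIRCLE: the Cancer Immunotherapy Response CLassifiEr, and its benchmark.

CIRCLE is a maximum-likelihood logistic regression on the stage-2-significant
genes, the screen-overlapping pathways, age, log2 TMB and tumor type (study
of origin is excluded from the classifier).  It is benchmarked against a
single-feature logistic classifier on panel-restricted TMB via Monte Carlo
cross-validation: 100 iterations of tumor-type-stratified 75/25 train/test
splits, vertically averaged ROC curves, an optimal cutoff (closest point to
(0,1)), per-patient majority-vote consensus classifications, confusion
metrics, AUPRC, the standardized score difference Θ, and a paired DeLong
comparison of AUCs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.utils.validation import check_is_fitted

from .cohort import DEFAULT_PSEUDOCOUNT, Cohort, compute_tmb, hedges_g
from .association import build_logistic_design

FPR_GRID = np.round(np.arange(0.0, 1.01, 0.01), 2)


@dataclass
class ConfusionMetrics:
    sensitivity: float
    specificity: float
    fpr: float
    fnr: float
    f1: float


@dataclass
class CvReport:
    """Everything a Monte Carlo cross-validation run produces."""

    aucs: np.ndarray
    mean_auc: float
    sd_auc: float
    averaged_roc: pd.DataFrame        # fpr grid, mean tpr, mean threshold
    optimal_cutoff: float
    consensus_labels: pd.Series       # bool per patient
    consensus_scores: pd.Series       # mean test-fold probability per patient
    metrics: ConfusionMetrics
    auprc: float
    theta: float
    per_iteration: list = field(repr=False, default_factory=list)


class CircleClassifier(BaseEstimator, ClassifierMixin):
    """Logistic-regression response classifier over a numeric design matrix.

    A thin scikit-learn estimator around an unpenalized (maximum likelihood)
    logistic fit; the design matrix is built by
    :func:`build_circle_design` (binary gene/pathway genotype + age +
    log2 TMB + tumor-type indicators) or by :func:`build_tmb_design` for the
    panel-TMB baseline.  Scores are predicted response probabilities.
    """

    def __init__(self, max_iter: int = 2000):
        self.max_iter = max_iter

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y).astype(int)
        # C=inf -> no regularization: plain maximum-likelihood logistic fit
        self._lr = LogisticRegression(C=np.inf, solver="lbfgs",
                                      max_iter=self.max_iter)
        self._lr.fit(X.to_numpy(dtype=float), y)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.classes_ = self._lr.classes_
        self.coef_ = self._lr.coef_
        self.intercept_ = self._lr.intercept_
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        return self._lr.decision_function(pd.DataFrame(X).to_numpy(dtype=float))

    def predict_proba(self, X):
        check_is_fitted(self, "coef_")
        return self._lr.predict_proba(pd.DataFrame(X).to_numpy(dtype=float))

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return self._lr.predict(pd.DataFrame(X).to_numpy(dtype=float))

    def score_patients(self, X) -> np.ndarray:
        """Probability of response, aligned with the rows of X."""
        return self.predict_proba(X)[:, 1]

    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "feature_names": list(self.feature_names_in_),
            "coefficients": self.coef_[0].tolist(),
            "intercept": float(self.intercept_[0]),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def build_circle_design(
    feature_matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    selected_features: list[str],
    log2_tmb: pd.Series | None = None,
) -> pd.DataFrame:
    """Design matrix for CIRCLE: selected genotype features + age +
    log2 TMB + tumor-type indicators.  Study of origin is deliberately
    excluded from the classifier."""
    clin = clinical.set_index("patient_id") if "patient_id" in clinical.columns else clinical
    blocks = [feature_matrix.loc[clin.index, selected_features].astype(float)]
    base = pd.DataFrame(index=clin.index)
    base["age"] = clin["age"].astype(float)
    base["log2_tmb"] = (clin["log2_tmb"].astype(float) if log2_tmb is None
                        else log2_tmb.loc[clin.index].astype(float))
    blocks.append(base)
    blocks.append(build_logistic_design(clin[["tumor_type"]], categorical=("tumor_type",)))
    return pd.concat(blocks, axis=1)


def build_tmb_design(
    cohort: Cohort, panel_genes: set[str], pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """Single-feature design for the panel-TMB baseline classifier."""
    if not (set(cohort.mutations["gene"]) & set(panel_genes)):
        raise ValueError("panel has no overlap with the cohort's mutated genes")
    counts = {
        pid: compute_tmb(grp, gene_subset=set(panel_genes))
        for pid, grp in cohort.mutations.groupby("patient_id")
    }
    panel_tmb = pd.Series(counts).reindex(cohort.patients["patient_id"], fill_value=0)
    return pd.DataFrame({"log2_panel_tmb": np.log2(panel_tmb + pseudocount)})


def fit_tmb_baseline(cohort: Cohort, panel_genes: set[str]) -> CircleClassifier:
    """Logistic classifier on panel TMB alone, fit on the included patients."""
    X = build_tmb_design(cohort, panel_genes).reset_index(drop=True)
    included = cohort.patients["response"].notna().to_numpy()
    y = cohort.patients.loc[included, "response"].astype(bool).to_numpy()
    return CircleClassifier().fit(X[included], y)


# ---------------------------------------------------------------------------
# Monte Carlo cross-validation
# ---------------------------------------------------------------------------

def _stratified_split(strata: np.ndarray, train_frac: float, rng) -> np.ndarray:
    """Boolean train mask keeping stratum proportions; per-stratum train size
    round(frac * n) with a global ±1-patient correction."""
    n = len(strata)
    target = int(round(train_frac * n))
    labels, inverse = np.unique(strata, return_inverse=True)
    sizes = []
    for s, lab in enumerate(labels):
        n_s = int((inverse == s).sum())
        if n_s < 2:
            raise ValueError(f"stratum {lab!r} has fewer than 2 patients; cannot split")
        k = int(round(train_frac * n_s))
        sizes.append(min(max(k, 1), n_s - 1))
    # global correction: nudge the largest strata until within one patient
    order = np.argsort([-(inverse == s).sum() for s in range(len(labels))])
    i = 0
    while abs(sum(sizes) - target) > 1 and i < 10 * len(labels):
        s = order[i % len(labels)]
        n_s = int((inverse == s).sum())
        if sum(sizes) > target and sizes[s] > 1:
            sizes[s] -= 1
        elif sum(sizes) < target and sizes[s] < n_s - 1:
            sizes[s] += 1
        i += 1
    mask = np.zeros(n, dtype=bool)
    for s in range(len(labels)):
        members = np.flatnonzero(inverse == s)
        chosen = rng.permutation(members)[: sizes[s]]
        mask[chosen] = True
    return mask


def monte_carlo_cv(
    X: pd.DataFrame,
    y,
    strata,
    n_iter: int = 100,
    train_frac: float = 0.75,
    seed: int = 0,
    estimator: CircleClassifier | None = None,
    require_full_coverage: bool = True,
) -> CvReport:
    """Monte Carlo cross-validation of a response classifier.

    Each iteration draws a tumor-type-stratified train/test split, fits the
    estimator on the train fold and records the test-fold ROC.  Aggregates:
    mean/sd AUC, the vertically averaged ROC with its optimal cutoff,
    majority-vote consensus classifications (ties go to non-responder),
    consensus scores (mean test-fold probability), confusion metrics, AUPRC
    and the standardized score difference Θ.  The whole report is a pure
    function of (X, y, strata, seed).
    """
    X = pd.DataFrame(X)
    y = np.asarray(y).astype(bool)
    strata = np.asarray(strata)
    if estimator is None:
        estimator = CircleClassifier()
    rng = np.random.default_rng(seed)

    per_iteration = []
    n = len(y)
    votes = [[] for _ in range(n)]
    score_sums = np.zeros(n)
    score_counts = np.zeros(n, dtype=int)

    for _ in range(n_iter):
        for _attempt in range(100):
            train = _stratified_split(strata, train_frac, rng)
            test = ~train
            if len(np.unique(y[train])) == 2 and len(np.unique(y[test])) == 2:
                break
        else:
            raise RuntimeError("could not draw a split with both classes in both folds")
        model = clone(estimator).fit(X[train], y[train])
        scores = model.predict_proba(X[test])[:, 1]
        fpr, tpr, thr = roc_curve(y[test], scores)
        auc = float(np.trapezoid(tpr, fpr))
        per_iteration.append({
            "auc": auc, "fpr": fpr, "tpr": tpr, "thresholds": thr,
            "test_index": np.flatnonzero(test), "scores": scores,
        })
        score_sums[test] += scores
        score_counts[test] += 1

    aucs = np.array([it["auc"] for it in per_iteration])
    averaged = average_roc_curves(
        [(it["fpr"], it["tpr"], it["thresholds"]) for it in per_iteration]
    )
    cutoff = optimal_cutoff(
        (averaged["fpr"].to_numpy(), averaged["tpr"].to_numpy(),
         averaged["threshold"].to_numpy())
    )

    for it in per_iteration:
        labels = it["scores"] > cutoff
        for idx, lab in zip(it["test_index"], labels):
            votes[idx].append(bool(lab))

    never_tested = [i for i in range(n) if not votes[i]]
    if never_tested:
        # vanishingly unlikely at n_iter=100; short runs may opt out and get
        # consensus over the patients that did reach a test fold
        if require_full_coverage:
            raise RuntimeError(
                f"{len(never_tested)} patients never appeared in a test fold"
            )
    voted = np.array([bool(v) for v in votes])
    consensus = consensus_classify(
        {i: votes[i] for i in range(n) if votes[i]}
    )
    consensus_labels = pd.Series(
        [consensus.get(i, False) for i in range(n)], index=X.index
    )[voted]
    with np.errstate(invalid="ignore"):
        consensus_scores = pd.Series(
            np.where(score_counts > 0, score_sums / np.maximum(score_counts, 1),
                     np.nan),
            index=X.index,
        )[voted]

    metrics, auprc, theta = classification_metrics(
        y[voted], consensus_labels.to_numpy(), consensus_scores.to_numpy()
    )
    return CvReport(
        aucs=aucs, mean_auc=float(aucs.mean()), sd_auc=float(aucs.std(ddof=1)),
        averaged_roc=averaged, optimal_cutoff=float(cutoff),
        consensus_labels=consensus_labels, consensus_scores=consensus_scores,
        metrics=metrics, auprc=auprc, theta=theta, per_iteration=per_iteration,
    )


def average_roc_curves(rocs: list) -> pd.DataFrame:
    """Vertically average ROC curves (and thresholds) over a fixed FPR grid."""
    if not rocs:
        raise ValueError("need at least one ROC curve")
    tprs, thrs = [], []
    for roc in rocs:
        fpr, tpr = np.asarray(roc[0], dtype=float), np.asarray(roc[1], dtype=float)
        tprs.append(np.interp(FPR_GRID, fpr, tpr))
        if len(roc) > 2:
            thr = np.asarray(roc[2], dtype=float)
            finite = np.isfinite(thr)
            thr = np.where(finite, thr, np.nanmax(np.where(finite, thr, np.nan)) + 1)
            thrs.append(np.interp(FPR_GRID, fpr, thr))
    out = pd.DataFrame({"fpr": FPR_GRID, "tpr": np.mean(tprs, axis=0)})
    out["threshold"] = np.mean(thrs, axis=0) if thrs else np.nan
    return out


def optimal_cutoff(roc) -> float:
    """Threshold of the ROC point closest (Euclidean) to (FPR, TPR) = (0, 1);
    ties resolved toward the lowest (most sensitive) threshold."""
    fpr, tpr, thr = (np.asarray(a, dtype=float) for a in roc)
    if fpr.size == 0:
        raise ValueError("empty ROC curve")
    dist = np.hypot(fpr, 1.0 - tpr)
    best = np.flatnonzero(np.isclose(dist, dist.min()))
    return float(thr[best].min())


def consensus_classify(votes: dict) -> dict:
    """Majority vote per patient; exact ties go to non-responder."""
    out = {}
    for patient, vs in votes.items():
        if not vs:
            raise ValueError(f"patient {patient!r} never appeared in a test fold")
        yes = sum(bool(v) for v in vs)
        out[patient] = yes * 2 > len(vs)
    return out


def classification_metrics(truth, labels, scores):
    """Confusion metrics + AUPRC + Θ from consensus labels and scores.

    Θ is the Hedge's-g standardized difference of mean scores between true
    responders and non-responders.
    """
    truth = np.asarray(truth).astype(bool)
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    if truth.all() or (~truth).all():
        raise ValueError("metrics undefined: truth contains a single class")

    tp = int((truth & labels).sum())
    fn = int((truth & ~labels).sum())
    fp = int((~truth & labels).sum())
    tn = int((~truth & ~labels).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    f1 = 2 * tp / (2 * tp + fp + fn)
    metrics = ConfusionMetrics(sensitivity=sens, specificity=spec,
                               fpr=1.0 - spec, fnr=1.0 - sens, f1=f1)

    precision, recall, _ = precision_recall_curve(truth, scores)
    auprc = float(np.trapezoid(precision[::-1], recall[::-1]))

    if np.allclose(scores[truth].var(ddof=1) + scores[~truth].var(ddof=1), 0.0):
        theta = 0.0 if np.isclose(scores[truth].mean(), scores[~truth].mean()) else np.inf
    else:
        theta = hedges_g(scores[truth], scores[~truth]).g
    return metrics, auprc, float(theta)


# ---------------------------------------------------------------------------
# DeLong paired AUC comparison
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")

def _delong_structural(scores: np.ndarray, truth: np.ndarray):
    """AUC and the DeLong structural components V10, V01 for one classifier."""
    pos, neg = scores[truth], scores[~truth]
    m, n = len(pos), len(neg)
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return auc, v10, v01


def delong_compare(scores_a, scores_b, truth) -> tuple[float, float, float]:
    """Paired DeLong test comparing the AUCs of two score vectors on the same
    patients.  Returns (auc_a, auc_b, two-sided p).  Identical score vectors
    return p = 1 by convention."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    truth = np.asarray(truth).astype(bool)
    auc_a, v10_a, v01_a = _delong_structural(scores_a, truth)
    auc_b, v10_b, v01_b = _delong_structural(scores_b, truth)

    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        if np.isclose(diff, 0.0):
            return float(auc_a), float(auc_b), 1.0
        raise FloatingPointError(
            "zero variance of the paired AUC difference with unequal AUCs"
        )
    z = diff / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(auc_a), float(auc_b), p
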