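"""Stage-2 biomarker association.

Each stage-1-nominated gene or pathway becomes a binary HasMutation feature
and is tested for association with dichotomized ICB response in a
multivariate logistic regression:

    Response ~ Logistic(a0 + a1 HasMutation + a2 TumorType + a3 Age
                        + a4 log2(TMB) + a5 StudyOfOrigin)

The odds ratio is e^a1 with its Wald 95% CI; OR > 1 means the mutation is
enriched in responders.  Multiple testing uses Storey q-values with pi0
fixed at 1 (lambda = 0) and a q < 0.2 nomination threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .background import storey_qvalues

#: |coefficient| or standard error beyond these marks (quasi-)complete
#: separation; the result is flagged with an infinite-CI sentinel.
SEPARATION_COEF = 15.0
SEPARATION_SE = 50.0

ASSOCIATION_FDR = 0.2


@dataclass
class AssociationResult:
    feature: str
    alpha1: float
    or_: float
    ci_low: float
    ci_high: float
    wald_p: float
    n_mutated: int
    separated: bool = False
    q: float = np.nan


def _categorical_dummies(series: pd.Series, prefix: str) -> pd.DataFrame:
    """Reference-coded indicators with the most frequent level as reference."""
    counts = series.value_counts()
    reference = counts.index[0]
    levels = [lv for lv in counts.index if lv != reference]
    return pd.DataFrame(
        {f"{prefix}[{lv}]": (series == lv).astype(float) for lv in levels},
        index=series.index,
    )


def build_logistic_design(
    covariates: pd.DataFrame,
    categorical: tuple[str, ...] = ("tumor_type", "study_id"),
) -> pd.DataFrame:
    """Numeric design block for the logistic covariates (no intercept)."""
    blocks = []
    for col in covariates.columns:
        if col in categorical:
            dummies = _categorical_dummies(covariates[col], col)
            if dummies.shape[1]:
                blocks.append(dummies)
        else:
            blocks.append(covariates[[col]].astype(float))
    return pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=covariates.index)


def fit_feature_association(
    response,
    has_mutation,
    covariates: pd.DataFrame | None = None,
    feature_name: str = "feature",
    ci: float = 0.95,
) -> AssociationResult:
    """Multivariate logistic fit of response on one binary mutation feature.

    Separation is detected from diverging coefficient/SE and reported as a
    flagged result with infinite CI rather than an exception.
    """
    response = np.asarray(response, dtype=float)
    has_mutation = np.asarray(has_mutation, dtype=float)
    if len(np.unique(has_mutation)) < 2:
        raise ValueError(f"feature {feature_name!r} is constant across patients")
    if response.sum() < 2 or (1 - response).sum() < 2:
        raise ValueError("need at least 2 patients in each response class")

    cols = [pd.Series(has_mutation, name="has_mutation")]
    if covariates is not None:
        design = build_logistic_design(covariates).reset_index(drop=True)
        cols.append(design)
    exog = sm.add_constant(pd.concat(cols, axis=1), has_constant="add")

    idx = list(exog.columns).index("has_mutation")
    alpha1, se = np.nan, np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("newton", "bfgs"):
            try:
                fit = sm.Logit(response, exog.to_numpy(dtype=float)).fit(
                    disp=0, maxiter=500, method=method)
                alpha1 = float(fit.params[idx])
                se = float(fit.bse[idx])
                break
            except Exception:  # singular Hessian under (quasi-)separation
                continue
    if not np.isfinite(alpha1):
        # sign of the divergence from the raw 2x2 direction
        p_mut = response[has_mutation == 1].mean()
        p_wt = response[has_mutation == 0].mean()
        alpha1 = np.inf if p_mut >= p_wt else -np.inf

    separated = (abs(alpha1) > SEPARATION_COEF) or (se > SEPARATION_SE) or not np.isfinite(se)
    z = stats.norm.ppf(0.5 + ci / 2.0)
    if separated:
        or_ = np.inf if alpha1 > 0 else 0.0
        ci_low, ci_high, wald_p = 0.0, np.inf, 1.0
    else:
        or_ = float(np.exp(alpha1))
        ci_low = float(np.exp(alpha1 - z * se))
        ci_high = float(np.exp(alpha1 + z * se))
        wald_p = float(2.0 * stats.norm.sf(abs(alpha1 / se)))

    return AssociationResult(
        feature=feature_name, alpha1=alpha1, or_=or_, ci_low=ci_low,
        ci_high=ci_high, wald_p=wald_p, n_mutated=int(has_mutation.sum()),
        separated=separated,
    )


def associate_features(
    feature_matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    fdr: float = ASSOCIATION_FDR,
    covariate_columns: tuple[str, ...] = ("age", "log2_tmb", "tumor_type", "study_id"),
) -> pd.DataFrame:
    """Per-feature logistic association over the included (CR/PR/PD) patients.

    ``clinical`` must carry a nullable-boolean ``response`` column plus the
    covariate columns; SD patients (response NA) are dropped before fitting.
    Returns a table with alpha1, OR, CI, Wald p, Storey q (lambda = 0) and a
    ``significant`` flag at ``q < fdr``.
    """
    clinical = clinical.set_index("patient_id") if "patient_id" in clinical.columns else clinical
    included = clinical[clinical["response"].notna()]
    X = feature_matrix.loc[included.index]
    response = included["response"].astype(bool).to_numpy()
    usable = [c for c in covariate_columns if c in included.columns]
    covs = included[usable].reset_index(drop=True) if usable else None

    results = []
    for feature in X.columns:
        results.append(
            fit_feature_association(
                response, X[feature].to_numpy(), covs, feature_name=feature
            )
        )
    table = pd.DataFrame(
        {
            "alpha1": [r.alpha1 for r in results],
            "or": [r.or_ for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "wald_p": [r.wald_p for r in results],
            "n_mutated": [r.n_mutated for r in results],
            "separated": [r.separated for r in results],
        },
        index=pd.Index([r.feature for r in results], name="feature"),
    )
    table["q"] = storey_qvalues(table["wald_p"].to_numpy(), pi0_lambda=0)
    table["significant"] = table["q"] < fdr
    return table.sort_values("wald_p", kind="mergesort")
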