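"""High-level runners that chain the two-stage analysis on a cohort.

These are thin orchestration helpers: stage-1 gene nomination (covariate PCA
→ gamma-Poisson background → recurrence table), stage-2 response association,
and the CIRCLE vs panel-TMB cross-validated benchmark.  They operate on a
:class:`~circleicb.simulate.SimulatedCohort` or on equivalently shaped inputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import associate_features
from .background import CovariatePCA, fit_background, recurrence_table
from .classifier import (
    CvReport,
    build_circle_design,
    build_tmb_design,
    delong_compare,
    monte_carlo_cv,
)
from .cohort import build_feature_matrix


def _pool_rare_strata(strata: np.ndarray, min_size: int = 8) -> np.ndarray:
    """Tumor types too small to split proportionally are pooled into the
    modal stratum so the stratified CV remains well defined."""
    strata = np.asarray(strata, dtype=object).copy()
    labels, counts = np.unique(strata, return_counts=True)
    modal = labels[np.argmax(counts)]
    for lab, n in zip(labels, counts):
        if n < min_size:
            strata[strata == lab] = modal
    return strata


def reduce_sim_covariates(sim, n_components=(2, 3, 2)) -> pd.DataFrame:
    """PCA-reduce a simulated covariome along its generating families."""
    families = {f: [c for c in sim.covariates.columns if c.startswith(f)]
                for f in ("timing", "chromatin", "context")}
    ncomp = dict(zip(families, n_components))
    return CovariatePCA(families, ncomp).fit(sim.covariates).transform(sim.covariates)


def nominate_genes(sim, fdr: float = 0.1, pi0_lambda="smoother"):
    """Stage 1 on a simulated cohort: returns (recurrence table, fit)."""
    pcs = reduce_sim_covariates(sim)
    fit = fit_background(sim.y.to_numpy(), sim.exposures, pcs)
    table = recurrence_table(fit, sim.y, pi0_lambda=pi0_lambda)
    table["nominated"] = table["q"] < fdr
    return table, fit


def benchmark_classifiers(
    sim,
    selected_features: list[str] | None = None,
    panel_genes: set[str] | None = None,
    n_iter: int = 100,
    seed: int = 0,
    association_fdr: float = 0.2,
) -> dict:
    """CIRCLE vs panel-TMB Monte Carlo CV benchmark on a simulated cohort.

    When ``selected_features`` is None the full two-stage selection runs:
    stage-1 nomination at q < 0.1, then stage-2 association at q < 0.2.
    ``panel_genes`` defaults to a 10%-of-exome panel that includes the
    planted drivers, mimicking a diagnostic panel enriched for cancer genes.
    """
    cohort = sim.cohort
    clin = cohort.patients.copy()
    clin["log2_tmb"] = np.log2(cohort.tmb.to_numpy() + 1.0)

    if selected_features is None:
        table, _ = nominate_genes(sim)
        nominated = sorted(table.index[table["nominated"]])
        fm = build_feature_matrix(cohort, nominated, sim.pathways)
        if nominated:
            assoc = associate_features(fm[nominated], clin, fdr=association_fdr)
            selected_features = list(assoc.index[assoc["significant"]])
        else:
            selected_features = []
    else:
        fm = build_feature_matrix(cohort, selected_features, sim.pathways)

    included = clin["response"].notna().to_numpy()
    clin_inc = clin[included].set_index("patient_id")
    y = clin_inc["response"].astype(bool).to_numpy()
    strata = _pool_rare_strata(clin_inc["tumor_type"].to_numpy())

    X_circle = build_circle_design(fm, clin_inc, selected_features)

    if panel_genes is None:
        all_genes = [g.gene_id for g in sim.genes]
        panel_genes = set(all_genes[::10]) | set(sim.driver_genes)
    X_tmb = build_tmb_design(cohort, panel_genes)
    X_tmb.index = cohort.patients["patient_id"]
    X_tmb = X_tmb.loc[clin_inc.index]

    full = n_iter >= 100
    circle = monte_carlo_cv(X_circle, y, strata, n_iter=n_iter, seed=seed,
                            require_full_coverage=full)
    tmb = monte_carlo_cv(X_tmb, y, strata, n_iter=n_iter, seed=seed,
                         require_full_coverage=full)

    common = circle.consensus_scores.index.intersection(tmb.consensus_scores.index)
    truth = clin_inc.loc[common, "response"].astype(bool).to_numpy()
    _, _, delong_p = delong_compare(
        circle.consensus_scores.loc[common].to_numpy(),
        tmb.consensus_scores.loc[common].to_numpy(), truth)

    return {
        "circle": circle,
        "tmb": tmb,
        "selected_features": selected_features,
        "delong_p": delong_p,
        "included_patients": clin_inc,
        "truth": y,
    }
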