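"""Gene-level positive-selection screen.

A gamma-Poisson (negative binomial) regression models the neutral expectation
of per-gene mutation counts: the count of patients carrying at least one
High/Moderate mutation in a gene's eligible coding territory is regressed on
genomic covariates (replication timing, chromatin state, sequence context —
each reduced to principal components) with the log of the eligible base count
as exposure.  A gene is recurrently mutated when its observed count lies far
in the right tail of its fitted count distribution.  q-values use the Storey
method and calibration is diagnosed with the genomic inflation factor λ.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from scipy.interpolate import UnivariateSpline
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
import statsmodels.api as sm
from statsmodels.discrete.discrete_model import NegativeBinomial

from .cohort import Cohort, FUNCTIONAL_IMPACTS

logger = logging.getLogger(__name__)

#: NB dispersion below this is indistinguishable from Poisson; the fit and the
#: tail probabilities fall back to the Poisson limit.
POISSON_DISPERSION_FLOOR = 1e-8


@dataclass
class GeneModel:
    """Per-gene hypothesis: coding intervals, eligible territory, covariates.

    Intervals are 0-based half-open ``(contig, start, end)``.  ``eligible``
    defaults to the full CDS; when a coverage mask restricts it,
    ``eligible_bases`` must equal the summed length of ``eligible``.
    """

    gene_id: str
    cds_intervals: list[tuple[str, int, int]]
    eligible: list[tuple[str, int, int]] = field(default=None)
    eligible_bases: int = None

    def __post_init__(self):
        if self.eligible is None:
            self.eligible = list(self.cds_intervals)
        if self.eligible_bases is None:
            self.eligible_bases = sum(e - s for _, s, e in self.eligible)


class ConvergenceError(RuntimeError):
    """The background regression failed to converge; carries diagnostics."""


# ---------------------------------------------------------------------------
# Covariate construction
# ---------------------------------------------------------------------------

def aggregate_covariates(
    tracks: dict[str, pd.DataFrame],
    genes: list[GeneModel],
) -> pd.DataFrame:
    """Average each interval track over every gene's eligible bases.

    ``tracks`` maps covariate name to a bedGraph-like frame with columns
    contig/start/end/score (0-based half-open).  The per-gene value is the
    base-weighted mean of the score over eligible bases; eligible bases not
    covered by the track are ignored in the mean.  Genes with zero eligible
    bases, or fully outside a track, are dropped with a warning.
    """
    trees: dict[str, dict[str, IntervalTree]] = {}
    for name, bed in tracks.items():
        per_contig: dict[str, IntervalTree] = {}
        for contig, grp in bed.groupby("contig"):
            per_contig[contig] = IntervalTree.from_tuples(
                (int(s), int(e), float(v))
                for s, e, v in zip(grp["start"], grp["end"], grp["score"])
                if e > s
            )
        trees[name] = per_contig

    rows, kept = [], []
    for gene in genes:
        if gene.eligible_bases <= 0:
            warnings.warn(f"gene {gene.gene_id} has no eligible bases; excluded")
            continue
        values = {}
        ok = True
        for name, per_contig in trees.items():
            weighted, covered = 0.0, 0
            for contig, start, end in gene.eligible:
                tree = per_contig.get(contig)
                if tree is None:
                    continue
                for iv in tree.overlap(start, end):
                    length = min(end, iv.end) - max(start, iv.begin)
                    weighted += iv.data * length
                    covered += length
            if covered == 0:
                warnings.warn(
                    f"gene {gene.gene_id} not covered by track {name!r}; excluded"
                )
                ok = False
                break
            values[name] = weighted / covered
        if ok:
            rows.append(values)
            kept.append(gene.gene_id)
    return pd.DataFrame(rows, index=pd.Index(kept, name="gene_id"))


class CovariatePCA(BaseEstimator, TransformerMixin):
    """Per-family standardize-then-PCA reduction of the covariate matrix.

    Covariates come in families (replication timing, chromatin states,
    sequence context); each family is centered, scaled to unit variance
    (constant columns dropped with a warning) and replaced by its top
    principal-component scores.  Families are concatenated in the order given.

    Parameters
    ----------
    families : dict[str, list[str]]
        Family name -> member column names.
    n_components : dict[str, int]
        Family name -> number of PCs to keep (the study-scale configuration
        keeps 50/200/50 for timing/chromatin/sequence; fixtures use fewer).
    """

    def __init__(self, families: dict[str, list[str]],
                 n_components: dict[str, int]):
        self.families = families
        self.n_components = n_components

    def fit(self, X: pd.DataFrame, y=None):
        self.columns_ = {}
        self.means_ = {}
        self.scales_ = {}
        self.pcas_ = {}
        for family, cols in self.families.items():
            sub = X[cols].to_numpy(dtype=float)
            std = sub.std(axis=0, ddof=1)
            keep = std > 0
            if not keep.all():
                dropped = [c for c, k in zip(cols, keep) if not k]
                warnings.warn(f"family {family!r}: constant columns dropped: {dropped}")
            cols_kept = [c for c, k in zip(cols, keep) if k]
            k = self.n_components[family]
            if k > min(len(X), len(cols_kept)):
                raise ValueError(
                    f"family {family!r}: {k} components exceed "
                    f"min(n_genes={len(X)}, n_columns={len(cols_kept)})"
                )
            sub = sub[:, keep]
            mean, scale = sub.mean(axis=0), sub.std(axis=0, ddof=1)
            pca = PCA(n_components=k, svd_solver="full", random_state=0)
            pca.fit((sub - mean) / scale)
            self.columns_[family] = cols_kept
            self.means_[family] = mean
            self.scales_[family] = scale
            self.pcas_[family] = pca
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        blocks = []
        for family in self.families:
            sub = X[self.columns_[family]].to_numpy(dtype=float)
            scaled = (sub - self.means_[family]) / self.scales_[family]
            scores = self.pcas_[family].transform(scaled)
            blocks.append(pd.DataFrame(
                scores,
                index=X.index,
                columns=[f"{family}_pc{i + 1}" for i in range(scores.shape[1])],
            ))
        return pd.concat(blocks, axis=1)


# ---------------------------------------------------------------------------
# Observed counts
# ---------------------------------------------------------------------------

def count_gene_mutations(cohort: Cohort, genes: list[GeneModel]) -> pd.Series:
    """Observed recurrence count y_i per gene.

    y_i is the number of *distinct patients* carrying >= 1 High/Moderate
    mutation inside gene i's eligible territory — each patient contributes at
    most one mutation per gene.  Mutations at ineligible bases are not
    counted.  Input positions are 1-based; intervals 0-based half-open.
    """
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        for contig, start, end in gene.eligible:
            if end > start:
                trees.setdefault(contig, IntervalTree())[start:end] = gene.gene_id

    carriers: dict[str, set] = {g.gene_id: set() for g in genes}
    functional = cohort.mutations[cohort.mutations["impact"].isin(FUNCTIONAL_IMPACTS)]
    for patient, contig, pos in zip(
        functional["patient_id"], functional["chrom"], functional["pos"]
    ):
        tree = trees.get(contig)
        if tree is None:
            continue
        for iv in tree.at(int(pos) - 1):
            carriers[iv.data].add(patient)

    return pd.Series({g.gene_id: len(carriers[g.gene_id]) for g in genes},
                     name="y").astype(int)


# ---------------------------------------------------------------------------
# Gamma-Poisson background regression
# ---------------------------------------------------------------------------

class GammaPoissonBackground(BaseEstimator):
    """Negative-binomial (gamma-Poisson) regression of mutation counts on
    covariates with a log-exposure offset.

    The model is ``y_i ~ NB(mu_i, phi)`` with
    ``log mu_i = log t_i + beta0 + x_i . beta`` where ``t_i`` is the gene's
    eligible base count.  The dispersion ``phi`` (NB2 parameterization,
    ``Var = mu + phi mu^2``) is estimated by maximum likelihood jointly with
    the regression; when the estimate collapses to zero the model is refit as
    a Poisson GLM and ``dispersion_`` is exactly 0.

    Attributes (after ``fit``)
    --------------------------
    intercept_ : float
    coef_ : ndarray of covariate effects
    dispersion_ : float, NB2 phi (0 in the Poisson limit)
    expected_ : pandas.Series of fitted means e_i on the training genes
    converged_ : bool
    """

    def __init__(self, dispersion_cap: float = 1e4, maxiter: int = 200):
        self.dispersion_cap = dispersion_cap
        self.maxiter = maxiter

    def fit(self, X, y, exposure):
        X = pd.DataFrame(X)
        if len(X) < 2:
            raise ValueError("background fit needs at least 2 genes")
        y = np.asarray(y, dtype=float)
        exposure = np.asarray(exposure, dtype=float)
        if not np.all(np.isfinite(np.log(exposure))):
            raise ValueError("exposure (eligible bases) must be positive and finite")

        exog = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")

        poisson = sm.GLM(y, exog, family=sm.families.Poisson(),
                         exposure=exposure).fit(maxiter=self.maxiter)

        params, bse, alpha, converged = self._fit_nb(y, exog, exposure, poisson)
        # dispersion at (or heading to) the Poisson boundary, or an NB
        # optimizer failure: the Poisson GLM is the model's own limit
        if alpha <= 1e-6 or alpha != alpha or not converged:
            params, bse, alpha, converged = (np.asarray(poisson.params),
                                             np.asarray(poisson.bse), 0.0,
                                             poisson.converged)

        if not converged:
            raise ConvergenceError(
                "background regression did not converge "
                f"(n={len(y)}, p={exog.shape[1]}, dispersion={alpha:.3g})"
            )

        self.intercept_ = float(params[0])
        self.coef_ = np.asarray(params[1:], dtype=float)
        self.bse_ = np.asarray(bse, dtype=float)  # intercept first
        self.dispersion_ = float(alpha)
        self.n_features_in_ = X.shape[1]
        mu = exposure * np.exp(exog @ params)
        self.expected_ = pd.Series(mu, index=X.index, name="e")
        self.converged_ = True
        return self

    def _fit_nb(self, y, exog, exposure, poisson):
        """ML negative-binomial fit started from the Poisson solution."""
        start = np.r_[np.asarray(poisson.params), 0.1]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = NegativeBinomial(y, exog, loglike_method="nb2",
                                         exposure=exposure)
                res = model.fit(start_params=start, method="bfgs",
                                maxiter=self.maxiter, disp=0)
            alpha = float(res.params[-1])
            if alpha > self.dispersion_cap:
                return (np.asarray(poisson.params), np.asarray(poisson.bse),
                        0.0, poisson.converged)
            return (np.asarray(res.params[:-1]), np.asarray(res.bse[:-1]),
                    max(alpha, 0.0), bool(res.mle_retvals.get("converged", True)))
        except Exception:  # singular Hessian etc. -> Poisson fallback
            return (np.asarray(poisson.params), np.asarray(poisson.bse),
                    0.0, poisson.converged)

    def predict(self, X, exposure):
        X = pd.DataFrame(X)
        exog = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
        params = np.r_[self.intercept_, self.coef_]
        return pd.Series(np.asarray(exposure, dtype=float) * np.exp(exog @ params),
                         index=X.index)

    def tail_pvalues(self, y, expected=None) -> np.ndarray:
        """Right-tail p_i = P(Y >= y_i) under the fitted count distribution."""
        mu = np.asarray(self.expected_ if expected is None else expected, dtype=float)
        return nb_tail_pvalues(np.asarray(y), mu, self.dispersion_)


def nb_tail_pvalues(y, mu, dispersion: float) -> np.ndarray:
    """P(Y >= y) for a gamma-Poisson with mean mu and NB2 dispersion.

    ``dispersion = 0`` gives the Poisson limit.  y = 0 returns exactly 1.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if dispersion <= POISSON_DISPERSION_FLOOR:
        return stats.poisson.sf(y - 1, mu)
    size = 1.0 / dispersion
    prob = size / (size + mu)
    return stats.nbinom.sf(y - 1, size, prob)


def fit_background(y, genes: list[GeneModel] | np.ndarray, pcs) -> GammaPoissonBackground:
    """Fit the gamma-Poisson background for a gene list.

    ``genes`` provides the exposures (eligible base counts) either as
    GeneModel objects or directly as an array; ``pcs`` is the reduced
    covariate matrix aligned to ``y``.
    """
    if len(genes) and isinstance(genes[0], GeneModel):
        exposure = np.array([g.eligible_bases for g in genes], dtype=float)
    else:
        exposure = np.asarray(genes, dtype=float)
    return GammaPoissonBackground().fit(pcs, y, exposure=exposure)


def gene_recurrence_pvalues(fit: GammaPoissonBackground, y) -> pd.DataFrame:
    """Recurrence table: observed y_i, expected e_i, right-tail p."""
    y = pd.Series(y)
    p = fit.tail_pvalues(y.to_numpy())
    return pd.DataFrame({
        "y": y.to_numpy(),
        "e": fit.expected_.to_numpy(),
        "p": p,
    }, index=y.index)


# ---------------------------------------------------------------------------
# Multiple testing and calibration diagnostics
# ---------------------------------------------------------------------------

def storey_qvalues(p, pi0_lambda="smoother") -> np.ndarray:
    """Storey q-values.

    ``pi0_lambda="smoother"`` estimates the null proportion pi0 by the
    spline-smoother method over the grid 0.05..0.95.  ``pi0_lambda=0`` fixes
    pi0 = 1, reducing to the Benjamini–Hochberg step-up adjustment — the
    convention used for the stage-2 association tests.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size

    if pi0_lambda == "smoother":
        pi0 = _pi0_smoother(p)
    else:
        lam = float(pi0_lambda)
        pi0 = 1.0 if lam == 0.0 else min(1.0, max(
            np.mean(p > lam) / (1.0 - lam), 1.0 / m))

    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def _pi0_smoother(p: np.ndarray) -> float:
    grid = np.arange(0.05, 0.96, 0.05)
    pi0_raw = np.array([np.mean(p > lam) / (1.0 - lam) for lam in grid])
    try:
        spline = UnivariateSpline(grid, pi0_raw, k=3)
        pi0 = float(spline(grid[-1]))
    except Exception:
        pi0 = float(pi0_raw[-1])
    return min(max(pi0, 1.0 / p.size), 1.0)


def inflation_factor(p) -> float:
    """Genomic inflation factor λ: least-squares slope through the origin of
    sorted observed -log10 p against -log10 uniform order-statistic quantiles.

    λ ≈ 1 indicates calibrated null p-values; λ > 1 inflation.
    """
    p = np.asarray(p, dtype=float)
    if p.size < 10:
        raise ValueError("inflation factor needs at least 10 p-values")
    if np.any(p <= 0):
        tiny = np.finfo(float).tiny
        warnings.warn("p-values of 0 clamped to the smallest positive float")
        p = np.maximum(p, tiny)
    m = p.size
    observed = -np.log10(np.sort(p))  # decreasing: smallest p first
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    return float(np.sum(observed * expected) / np.sum(expected * expected))


def recurrence_table(
    fit: GammaPoissonBackground, y, pi0_lambda="smoother"
) -> pd.DataFrame:
    """Full stage-1 table: y, e, p, Storey q (sorted by p ascending)."""
    table = gene_recurrence_pvalues(fit, y)
    table["q"] = storey_qvalues(table["p"].to_numpy(), pi0_lambda=pi0_lambda)
    return table.sort_values("p", kind="mergesort")
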