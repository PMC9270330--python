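"""Pathway-level recurrence: gene-set offset-intercept test, redundancy
pruning, and hypergeometric overlap with a functional-screen hit list.

Given the gene-level background fit (observed y_i, expected e_i), a gene set
I is tested by the intercept-only gamma-Poisson regression
``y_i ~ offset(log e_i)`` restricted to I: the fitted intercept is the
pathway-level log rate excess and its one-sided (right) Wald p-value the
significance.  In the Poisson limit the intercept has the closed form
``log(sum y / sum e)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.discrete.discrete_model import NegativeBinomial

from .background import POISSON_DISPERSION_FLOOR, storey_qvalues

#: Below this many genes the pathway regression keeps the global dispersion
#: rather than re-estimating it from the set itself.
MIN_GENES_FOR_DISPERSION = 10


@dataclass
class PathwayDef:
    name: str
    genes: set[str]


@dataclass
class PathwayResult:
    name: str
    intercept: float
    se: float
    p: float
    n_genes_tested: int
    q: float = np.nan


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> gene..."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            out[parts[0]] = {g for g in parts[2:] if g}
    return out


def pathway_effect_test(
    y: pd.Series,
    e: pd.Series,
    pathway: PathwayDef,
    global_dispersion: float = 0.0,
) -> PathwayResult | None:
    """Intercept-only gamma-Poisson test of a gene set against the background.

    Dispersion is re-estimated from the set itself when it has at least
    ``MIN_GENES_FOR_DISPERSION`` tested genes, else the global estimate is
    kept.  Returns None (with a warning) when no pathway gene was tested.
    """
    members = sorted(pathway.genes & set(y.index))
    if not members:
        warnings.warn(f"pathway {pathway.name!r} has no tested genes; skipped")
        return None
    ys = y.loc[members].to_numpy(dtype=float)
    es = e.loc[members].to_numpy(dtype=float)

    if ys.sum() == 0:
        # no mutation in the whole set: excess unbounded below, not enriched
        return PathwayResult(pathway.name, -np.inf, np.inf, 1.0, len(members))

    offset = np.log(es)
    exog = np.ones((len(ys), 1))

    alpha = float(global_dispersion)
    if len(members) >= MIN_GENES_FOR_DISPERSION:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = NegativeBinomial(ys, exog, loglike_method="nb2",
                                       offset=offset).fit(disp=0, method="bfgs")
            est = float(res.params[-1])
            if np.isfinite(est) and 0 <= est < 1e4:
                alpha = est
        except Exception:
            pass

    if alpha <= POISSON_DISPERSION_FLOOR:
        family = sm.families.Poisson()
    else:
        family = sm.families.NegativeBinomial(alpha=alpha)
    glm = sm.GLM(ys, exog, family=family, offset=offset).fit()
    intercept = float(glm.params[0])
    se = float(glm.bse[0])
    p = float(stats.norm.sf(intercept / se))  # one-sided: enrichment only
    return PathwayResult(pathway.name, intercept, se, p, len(members))


def test_pathways(
    y: pd.Series,
    e: pd.Series,
    pathways: list[PathwayDef] | dict[str, set[str]],
    global_dispersion: float = 0.0,
    pi0_lambda="smoother",
) -> pd.DataFrame:
    """Run the offset-intercept test over a pathway collection; adds Storey q."""
    if isinstance(pathways, dict):
        pathways = [PathwayDef(n, set(g)) for n, g in pathways.items()]
    results = []
    for pw in pathways:
        res = pathway_effect_test(y, e, pw, global_dispersion=global_dispersion)
        if res is not None:
            results.append(res)
    table = pd.DataFrame(
        {
            "intercept": [r.intercept for r in results],
            "se": [r.se for r in results],
            "p": [r.p for r in results],
            "n_genes_tested": [r.n_genes_tested for r in results],
        },
        index=pd.Index([r.name for r in results], name="pathway"),
    )
    if len(table):
        table["q"] = storey_qvalues(table["p"].to_numpy(), pi0_lambda=pi0_lambda)
    return table.sort_values("p", kind="mergesort")


def prune_redundant_pathways(
    results: pd.DataFrame,
    definitions: dict[str, set[str]],
    max_shared: float = 0.40,
    universe: set[str] | None = None,
) -> list[str]:
    """Greedy redundancy pruning of nominated pathways.

    Pathways are scanned in increasing-p order (ties: larger intercept, then
    name); a pathway is dropped when it shares strictly more than
    ``max_shared`` of its (universe-restricted) genes with any already
    retained, more significant pathway.  Exactly 40% shared is retained.
    """
    order = results.sort_values(
        ["p", "intercept"], ascending=[True, False], kind="mergesort"
    )
    order = order.loc[order.index.sort_values()].sort_values(
        ["p", "intercept"], ascending=[True, False], kind="mergesort"
    )
    retained: list[str] = []
    for name in order.index:
        genes = set(definitions[name])
        if universe is not None:
            genes &= universe
        if not genes:
            continue
        redundant = any(
            len(genes & (set(definitions[kept]) & universe if universe is not None
                         else set(definitions[kept]))) / len(genes) > max_shared
            for kept in retained
        )
        if not redundant:
            retained.append(name)
    return retained


def screen_overlap_test(
    pathway_genes: set[str], hits: set[str], universe: set[str]
) -> tuple[int, float]:
    """One-sided hypergeometric enrichment of screen hits in a pathway.

    Returns the overlap size k and P(X >= k) when drawing |pathway| genes
    from a universe containing |hits| hits.
    """
    if not universe:
        raise ValueError("empty gene universe")
    pw = pathway_genes & universe
    hit = hits & universe
    k = len(pw & hit)
    return k, float(stats.hypergeom.sf(k - 1, len(universe), len(hit), len(pw)))


def screen_overlap_table(
    pathways: dict[str, set[str]], hits: set[str], universe: set[str]
) -> pd.DataFrame:
    """Overlap test across pathways with BH-style (pi0 = 1) q-values."""
    rows = {}
    for name, genes in pathways.items():
        k, p = screen_overlap_test(set(genes), hits, universe)
        rows[name] = {"k": k, "p": p}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "pathway"
    if len(table):
        table["q"] = storey_qvalues(table["p"].to_numpy(), pi0_lambda=0)
    return table.sort_values("p", kind="mergesort")
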