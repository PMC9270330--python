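"""Cohort data model: readers, RECIST dichotomization, TMB accounting,
age imputation, effect sizes and the patient × feature mutation matrix.

A cohort joins a MAF-like somatic mutation table (one row per variant call,
annotated with a SnpEff impact class) to a clinical table (one row per
patient).  Tumor mutational burden (TMB) is the count of High + Moderate
impact mutations per patient — the union of classes that capture
non-synonymous coding variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

IMPACT_CLASSES = ("High", "Moderate", "Low", "Modifier")
#: Impact classes that count toward TMB and toward gene/pathway features.
FUNCTIONAL_IMPACTS = frozenset({"High", "Moderate"})

RECIST_CATEGORIES = ("CR", "PR", "SD", "PD")

#: Default exome territory used to convert a mutation count to mutations/Mb.
#: Configurable; a typical captured exome is close to this size.
DEFAULT_TERRITORY_MB = 38.0

#: Pseudocount added before log2 of a count that may be zero.
DEFAULT_PSEUDOCOUNT = 1.0

MUTATION_COLUMNS = ["patient_id", "gene", "chrom", "pos", "impact", "variant_class"]
CLINICAL_COLUMNS = ["patient_id", "age", "tumor_type", "study_id", "recist"]

#: Melanoma subtype labels collapsed to a single category at parse time.
_MELANOMA_ALIASES = {"melanoma", "cutaneous melanoma", "uveal melanoma",
                     "acral melanoma", "mucosal melanoma", "skin melanoma"}


class CohortFormatError(ValueError):
    """An input table is missing required columns or violates referential
    integrity (e.g. a mutation row naming a patient absent from the clinical
    table)."""


@dataclass
class EffectSize:
    """Hedge's g standardized mean difference with its 95% CI."""

    g: float
    ci_low: float
    ci_high: float
    n1: int
    n2: int


@dataclass
class Cohort:
    """Joined clinical + mutation records with per-patient TMB.

    Attributes
    ----------
    patients : pandas.DataFrame
        One row per patient: patient_id, age, tumor_type, study_id, recist,
        response (nullable boolean), os_time, os_event.
    mutations : pandas.DataFrame
        One row per variant call: patient_id, gene, chrom, pos (1-based),
        impact, variant_class, optionally protein_pos.
    tmb : pandas.Series
        High+Moderate mutation count indexed by patient_id.
    """

    patients: pd.DataFrame
    mutations: pd.DataFrame
    tmb: pd.Series = field(default=None)
    territory_mb: float = DEFAULT_TERRITORY_MB

    def __post_init__(self):
        if self.tmb is None:
            counts = _tmb_counts(self.mutations)
            self.tmb = counts.reindex(self.patients["patient_id"], fill_value=0)
            self.tmb.index = self.patients["patient_id"]

    @property
    def tmb_per_mb(self) -> pd.Series:
        return self.tmb / self.territory_mb

    @property
    def included(self) -> pd.DataFrame:
        """Patients with a defined dichotomized response (CR/PR/PD)."""
        return self.patients[self.patients["response"].notna()]

    def log2_tmb(self, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.Series:
        return np.log2(self.tmb + pseudocount)


def dichotomize_response(recist: str) -> bool | None:
    """Map a RECIST category to the responder dichotomy.

    Complete and partial responders (CR, PR) are responders; progressive
    disease (PD) is non-response; stable disease (SD) is undefined and those
    patients are excluded from association and classification.
    """
    if recist in ("CR", "PR"):
        return True
    if recist == "PD":
        return False
    if recist == "SD":
        return None
    raise ValueError(f"unknown RECIST category: {recist!r}")


def _tmb_counts(mutations: pd.DataFrame) -> pd.Series:
    functional = mutations[mutations["impact"].isin(FUNCTIONAL_IMPACTS)]
    return functional.groupby("patient_id").size()


def _normalize_tumor_type(value: str) -> str:
    if str(value).strip().lower() in _MELANOMA_ALIASES:
        return "melanoma"
    return value


def parse_cohort(
    mutation_table,
    clinical_table,
    column_map: dict[str, str] | None = None,
    territory_mb: float = DEFAULT_TERRITORY_MB,
) -> Cohort:
    """Read and join mutation + clinical TSVs into a :class:`Cohort`.

    Parameters
    ----------
    mutation_table, clinical_table
        Paths to tab-separated files with a header row, or DataFrames.
        Required mutation columns: patient_id, gene, chrom, pos, impact,
        variant_class.  Required clinical columns: patient_id, age,
        tumor_type, study_id, recist.  Extra columns are preserved.
    column_map
        Optional {file column -> canonical column} renaming.
    """
    muts = _read_table(mutation_table, column_map)
    clin = _read_table(clinical_table, column_map)

    for col in MUTATION_COLUMNS:
        if col not in muts.columns:
            raise CohortFormatError(f"mutation table missing required column {col!r}")
    for col in CLINICAL_COLUMNS:
        if col not in clin.columns:
            raise CohortFormatError(f"clinical table missing required column {col!r}")

    bad_impact = set(muts["impact"]) - set(IMPACT_CLASSES)
    if bad_impact:
        raise CohortFormatError(f"unknown impact classes: {sorted(bad_impact)}")
    if len(muts) and (muts["pos"] < 1).any():
        raise CohortFormatError("mutation positions must be 1-based (>= 1)")

    orphans = sorted(set(muts["patient_id"]) - set(clin["patient_id"]))
    if orphans:
        raise CohortFormatError(
            f"mutation rows reference patients absent from the clinical table: {orphans}"
        )

    clin = clin.copy()
    clin["tumor_type"] = clin["tumor_type"].map(_normalize_tumor_type)
    clin["response"] = pd.array(
        [dichotomize_response(r) for r in clin["recist"]], dtype="boolean"
    )
    for col, default in (("os_time", np.nan), ("os_event", np.nan)):
        if col not in clin.columns:
            clin[col] = default

    dup = muts.duplicated(subset=["patient_id", "chrom", "pos"])
    if dup.any():
        logger.info("mutation table holds %d rows duplicating a (patient, site); "
                    "rows are counted as given", int(dup.sum()))

    return Cohort(patients=clin.reset_index(drop=True),
                  mutations=muts.reset_index(drop=True),
                  territory_mb=territory_mb)


def _read_table(table, column_map=None) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.read_csv(table, sep="\t", dtype={"patient_id": str})
    if column_map:
        df = df.rename(columns=column_map)
    return df


def compute_tmb(
    mutations: pd.DataFrame,
    gene_subset: set[str] | None = None,
    territory_mb: float | None = None,
):
    """Count High+Moderate mutations, optionally restricted to a gene panel.

    Returns the count, or ``(count, count / territory_mb)`` when
    ``territory_mb`` is given (used for the strict >10 mutations/Mb TMB-high
    split: exactly 10.0 is TMB-low).
    """
    if territory_mb is not None and territory_mb <= 0:
        raise ValueError("territory_mb must be positive")
    functional = mutations[mutations["impact"].isin(FUNCTIONAL_IMPACTS)]
    if gene_subset is not None:
        functional = functional[functional["gene"].isin(gene_subset)]
    count = int(len(functional))
    if territory_mb is None:
        return count
    return count, count / territory_mb


def is_tmb_high(tmb_per_mb: float, threshold: float = 10.0) -> bool:
    """Strict '>10 mutations/Mb' split; the boundary value is TMB-low."""
    return tmb_per_mb > threshold


def impute_missing_age(patients: pd.DataFrame) -> pd.DataFrame:
    """Replace missing ages with the mean age of patients that have one."""
    ages = patients["age"]
    observed = ages.dropna()
    if observed.empty:
        raise ValueError("cannot impute age: no patient has an observed age")
    out = patients.copy()
    out["age"] = ages.fillna(float(observed.mean()))
    return out


def hedges_g(sample_a, sample_b, ci: float = 0.95) -> EffectSize:
    """Hedge's g: difference of means over the pooled, sample-size-weighted
    standard deviation, with the small-sample bias correction
    J = 1 - 3/(4(n1+n2-2)-1) and a normal-approximation CI.

    Callers comparing mutation counts apply log2 (with a pseudocount for
    zeros) before calling.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 values")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    if pooled_var <= 0:
        raise ValueError("pooled variance is zero; effect size undefined")
    d = (a.mean() - b.mean()) / np.sqrt(pooled_var)
    correction = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = d * correction
    var_d = (n1 + n2) / (n1 * n2) + d * d / (2.0 * (n1 + n2))
    se_g = correction * np.sqrt(var_d)
    z = stats.norm.ppf(0.5 + ci / 2.0)
    return EffectSize(g=float(g), ci_low=float(g - z * se_g),
                      ci_high=float(g + z * se_g), n1=n1, n2=n2)


def build_feature_matrix(
    cohort: Cohort,
    genes: list[str],
    pathways: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Binary patients × features matrix of somatic genotype.

    A gene feature is 1 when the patient carries a High or Moderate impact
    mutation anywhere in the gene; a pathway feature is the logical OR of its
    member-gene indicators.
    """
    pathways = pathways or {}
    functional = cohort.mutations[cohort.mutations["impact"].isin(FUNCTIONAL_IMPACTS)]
    mutated = functional.groupby("gene")["patient_id"].agg(set)

    index = pd.Index(cohort.patients["patient_id"], name="patient_id")
    out = pd.DataFrame(0, index=index, columns=list(genes) + list(pathways), dtype=int)
    for gene in genes:
        carriers = mutated.get(gene, set())
        out.loc[out.index.isin(carriers), gene] = 1
    for name, members in pathways.items():
        carriers = set().union(*(mutated.get(g, set()) for g in members)) if members else set()
        out.loc[out.index.isin(carriers), name] = 1
    return out
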