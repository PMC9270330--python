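"""Synthetic ICB cohorts with the statistical structure the analysis assumes.

The generator emulates, with known ground truth, the data the pipeline
consumes: a miniature exome of genes with covariate-driven neutral mutation
rates (gamma-Poisson per patient-gene counts with a log-linear covariate
effect and an exposure proportional to gene length), planted driver genes
with a multiplicative rate excess, RECIST response labels drawn from a
logistic model on driver-mutation status, log2 TMB, age and tumor type, and
response-linked exponentially censored survival times.

Every stage is a pure function of (config, seed); per-stage substreams are
spawned from one SeedSequence so stages can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .background import GeneModel
from .cohort import Cohort

TUMOR_TYPES = ("melanoma", "NSCLC", "bladder", "head_and_neck")

#: Tumor-type mix of the dichotomized study cohort (202/41/22/7 of 272).
DEFAULT_TUMOR_MIX = (202 / 272, 41 / 272, 22 / 272, 7 / 272)


@dataclass
class SimConfig:
    """Generative parameters for a synthetic cohort.

    Defaults are sized to the study conditions: ~300 patients across four
    tumor types dominated by melanoma, ~2,000 genes, a handful of driver
    genes at a multiplicative rate excess, a ~35% responder rate, and a
    ~15% stable-disease fraction that is excluded downstream.
    """

    n_patients: int = 300
    n_genes: int = 2000
    # lognormal CDS length: median ~1.35 kb, heavy right tail
    gene_length_mu: float = 7.2
    gene_length_sigma: float = 0.6
    # covariate families: latent factors per family -> observed columns
    n_covariates: dict = field(default_factory=lambda: {
        "timing": 6, "chromatin": 10, "context": 6})
    n_latents: dict = field(default_factory=lambda: {
        "timing": 2, "chromatin": 3, "context": 2})
    # effect of each family's first latent factor on log mutation rate
    covariate_effects: dict = field(default_factory=lambda: {
        "timing": 0.4, "chromatin": 0.3, "context": 0.2})
    covariate_noise: float = 0.3
    # neutral rate per eligible base per patient (~30 counted muts/patient
    # over a 3 Mb miniature exome, i.e. exome-scale mutation density)
    background_rate_per_base: float = 1e-5
    dispersion: float = 0.3
    # patient-level activity multiplier (lognormal sigma) -> TMB spread;
    # with the default TMB->response effect this yields responders carrying
    # ~1.4x the TMB of non-responders, the fold difference seen in real
    # aggregated ICB cohorts
    patient_activity_sigma: float = 0.75
    # driver genes: {index or name: rate multiplier}; default five at 5x
    n_drivers: int = 5
    driver_multiplier: float = 5.0
    # impact mix among counted (functional) mutations, plus passenger noise
    p_high: float = 0.2
    low_modifier_ratio: float = 0.6
    # response model: logit(P(resp)) = a0 + sum a1_d HasMut_d
    #   + a_tmb (log2 TMB - center) + a_age (age - 60)/10 + tumor offsets
    response_intercept: float = -0.8
    driver_response_effects: tuple = (-1.5, 1.0, -0.8, 0.7, 0.0)
    response_tmb_effect: float = 0.4
    response_age_effect: float = 0.2
    tumor_type_mix: tuple = DEFAULT_TUMOR_MIX
    tumor_type_offsets: tuple = (0.0, 0.0, 0.0, 0.0)
    sd_fraction: float = 47 / 319
    n_studies: int = 6
    age_mean: float = 62.0
    age_sd: float = 12.0
    # pathways: gene sets sampled from the universe; a few contain drivers
    n_pathways: int = 40
    pathway_size: int = 15
    # survival: exponential event times, responders at a reduced hazard
    baseline_hazard: float = 1 / 400.0
    responder_hazard_ratio: float = 0.5
    censoring_hazard: float = 1 / 800.0

    def __post_init__(self):
        if self.n_patients <= 0 or self.n_genes < 0:
            raise ValueError("n_patients must be positive and n_genes nonnegative")
        if abs(sum(self.tumor_type_mix) - 1.0) > 1e-9:
            raise ValueError("tumor_type_mix must sum to 1")
        if self.background_rate_per_base <= 0 or self.dispersion < 0:
            raise ValueError("rates must be positive, dispersion nonnegative")


@dataclass
class SimulatedCohort:
    """A generated cohort with its ground truth attached."""

    cohort: Cohort
    genes: list                      # GeneModel per gene
    covariates: pd.DataFrame         # genes x observed covariate columns
    counts: np.ndarray               # patients x genes functional-mutation counts
    driver_genes: list[str]
    driver_status: pd.DataFrame      # patients x drivers binary ground truth
    pathways: dict[str, set[str]]
    true_log_rate: np.ndarray        # per-gene log relative neutral rate
    survival: pd.DataFrame           # patient_id, time, event

    @property
    def y(self) -> pd.Series:
        """Observed per-gene recurrence counts (patients with >=1 mutation)."""
        return pd.Series((self.counts > 0).sum(axis=0),
                         index=[g.gene_id for g in self.genes], name="y")

    @property
    def exposures(self) -> np.ndarray:
        return np.array([g.eligible_bases for g in self.genes], dtype=float)


def _stream(seed: int, k: int):
    """k-th independent substream of the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(6)[k])


def generate_genome(config: SimConfig, seed: int):
    """Gene models, observed covariates, and the true per-gene log rate.

    Observed covariate columns are noisy linear mixtures of a few latent
    factors per family; only each family's first latent factor carries a
    configured effect on the log neutral rate, so PCA-reduced covariates can
    recover the signal.
    """
    rng = _stream(seed, 0)
    lengths = np.maximum(
        rng.lognormal(config.gene_length_mu, config.gene_length_sigma,
                      config.n_genes).astype(int), 150)
    genes, start = [], 0
    for i, length in enumerate(lengths):
        genes.append(GeneModel(
            gene_id=f"G{i:04d}",
            cds_intervals=[("chr1", start, start + int(length))],
        ))
        start += int(length) + 100

    latents, blocks = {}, []
    for family, n_cols in config.n_covariates.items():
        k = config.n_latents[family]
        z = rng.standard_normal((config.n_genes, k))
        loadings = rng.standard_normal((k, n_cols))
        obs = z @ loadings + config.covariate_noise * rng.standard_normal(
            (config.n_genes, n_cols))
        latents[family] = z
        blocks.append(pd.DataFrame(
            obs, columns=[f"{family}_{j}" for j in range(n_cols)]))
    covariates = pd.concat(blocks, axis=1)
    covariates.index = pd.Index([g.gene_id for g in genes], name="gene_id")

    log_rate = np.zeros(config.n_genes)
    for family, effect in config.covariate_effects.items():
        log_rate += effect * latents[family][:, 0]
    return genes, covariates, log_rate


def generate_counts(genes, log_rate, config: SimConfig, seed: int) -> np.ndarray:
    """Patients × genes functional (High/Moderate) mutation counts.

    Counts are gamma-Poisson: mean = eligible_bases * background_rate *
    exp(covariate effect) * driver multiplier * patient activity, with NB2
    dispersion ``config.dispersion`` (0 gives the Poisson limit).
    """
    rng = _stream(seed, 1)
    t = np.array([g.eligible_bases for g in genes], dtype=float)
    rate = config.background_rate_per_base * np.exp(log_rate - log_rate.mean())
    mult = np.ones(len(genes))
    mult[_driver_indices(config, genes)] = config.driver_multiplier
    activity = rng.lognormal(-config.patient_activity_sigma ** 2 / 2,
                             config.patient_activity_sigma, config.n_patients)
    mu = activity[:, None] * (t * rate * mult)[None, :]
    if config.dispersion > 0:
        lam = rng.gamma(1.0 / config.dispersion, config.dispersion * mu)
        return rng.poisson(lam)
    return rng.poisson(mu)


def _driver_indices(config: SimConfig, genes) -> np.ndarray:
    """Deterministic driver placement on representative-length genes.

    Real driver genes are typical protein-coding genes, not length outliers
    (KRAS ~0.6 kb, TP53 ~1.2 kb, BRAF ~2.3 kb), so drivers sit at evenly
    spaced quantiles of the gene-length distribution between 0.4 and 0.9.
    """
    if config.n_drivers == 0:
        return np.array([], dtype=int)
    lengths = np.array([g.eligible_bases for g in genes])
    order = np.argsort(lengths, kind="mergesort")
    qs = np.linspace(0.4, 0.9, config.n_drivers)
    return np.sort(order[(qs * (len(genes) - 1)).astype(int)])


def counts_to_mutations(genes, counts: np.ndarray, patient_ids,
                        config: SimConfig, seed: int) -> pd.DataFrame:
    """Expand the count matrix into MAF-like mutation rows.

    Functional counts become High/Moderate rows at uniform positions inside
    the gene; passenger Low/Modifier rows are added at a configured ratio.
    """
    rng = _stream(seed, 2)
    rows = []
    for p_idx, pid in enumerate(patient_ids):
        gene_idx = np.flatnonzero(counts[p_idx])
        for gi in gene_idx:
            gene = genes[gi]
            contig, start, end = gene.cds_intervals[0]
            c = int(counts[p_idx, gi])
            positions = rng.integers(start, end, size=c) + 1  # 1-based
            for pos in positions:
                high = rng.random() < config.p_high
                rows.append((pid, gene.gene_id, contig, int(pos),
                             "High" if high else "Moderate",
                             "stop_gained" if high else "missense_variant"))
        n_noise = rng.poisson(config.low_modifier_ratio * counts[p_idx].sum())
        for _ in range(n_noise):
            gi = rng.integers(len(genes))
            contig, start, end = genes[gi].cds_intervals[0]
            rows.append((pid, genes[gi].gene_id, contig,
                         int(rng.integers(start, end)) + 1,
                         "Low" if rng.random() < 0.5 else "Modifier",
                         "synonymous_variant"))
    return pd.DataFrame(rows, columns=["patient_id", "gene", "chrom", "pos",
                                       "impact", "variant_class"])


def generate_clinical(genes, counts: np.ndarray, config: SimConfig,
                      seed: int) -> pd.DataFrame:
    """Clinical table with response drawn from the configured logistic model."""
    rng = _stream(seed, 3)
    n = config.n_patients
    pids = [f"P{i:04d}" for i in range(n)]
    tumor = rng.choice(TUMOR_TYPES, size=n, p=config.tumor_type_mix)
    study = rng.integers(config.n_studies, size=n)
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 20, 95)

    driver_idx = _driver_indices(config, genes)
    has_driver = (counts[:, driver_idx] > 0).astype(float) if len(driver_idx) else \
        np.zeros((n, 0))
    tmb = counts.sum(axis=1)  # functional mutations only
    log2_tmb = np.log2(tmb + 1.0)

    logit = np.full(n, config.response_intercept)
    effects = np.asarray(config.driver_response_effects[: len(driver_idx)])
    logit += has_driver[:, : len(effects)] @ effects
    logit += config.response_tmb_effect * (log2_tmb - np.median(log2_tmb))
    logit += config.response_age_effect * (age - 60.0) / 10.0
    offsets = dict(zip(TUMOR_TYPES, config.tumor_type_offsets))
    logit += np.array([offsets[t] for t in tumor])

    responder = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
    recist = np.where(responder,
                      np.where(rng.random(n) < 14 / 94, "CR", "PR"), "PD")
    sd_mask = rng.random(n) < config.sd_fraction
    recist = np.where(sd_mask, "SD", recist)

    return pd.DataFrame({
        "patient_id": pids,
        "age": age,
        "tumor_type": tumor,
        "study_id": [f"study_{s}" for s in study],
        "recist": recist,
        "true_responder": responder,
    })


def generate_survival(clinical: pd.DataFrame, config: SimConfig,
                      seed: int) -> pd.DataFrame:
    """Exponential overall-survival times; responders at a reduced hazard,
    independent exponential right censoring."""
    rng = _stream(seed, 4)
    n = len(clinical)
    hr = np.where(clinical["true_responder"], config.responder_hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / (config.baseline_hazard * hr))
    if config.censoring_hazard > 0:
        censor_time = rng.exponential(1.0 / config.censoring_hazard, size=n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    return pd.DataFrame({
        "patient_id": clinical["patient_id"],
        "time": np.maximum(time, 1e-6),
        "event": event_time <= censor_time,
    })


def generate_pathways(genes, config: SimConfig, seed: int) -> dict[str, set[str]]:
    """Random gene sets; the first few are seeded with one driver each."""
    rng = _stream(seed, 5)
    names = [g.gene_id for g in genes]
    driver_idx = _driver_indices(config, genes)
    out = {}
    for k in range(config.n_pathways):
        members = set(rng.choice(names, size=min(config.pathway_size, len(names)),
                                 replace=False))
        if k < len(driver_idx):
            members.add(names[driver_idx[k]])
        out[f"PW{k:03d}"] = members
    return out


def simulate_cohort(config: SimConfig | None = None, seed: int = 0,
                    with_mutation_rows: bool = True) -> SimulatedCohort:
    """Generate a full synthetic cohort: genome, mutations, clinical,
    pathways and survival, with ground truth attached.

    ``with_mutation_rows=False`` skips expanding counts into MAF-like rows
    (the count matrix is enough for calibration studies and much faster).
    """
    config = config or SimConfig()
    genes, covariates, log_rate = generate_genome(config, seed)
    counts = generate_counts(genes, log_rate, config, seed)
    clinical = generate_clinical(genes, counts, config, seed)
    survival_df = generate_survival(clinical, config, seed)

    clin = clinical.drop(columns=["true_responder"]).copy()
    clin = clin.merge(survival_df.rename(columns={"time": "os_time",
                                                  "event": "os_event"}),
                      on="patient_id")
    if with_mutation_rows:
        mutations = counts_to_mutations(genes, counts, clin["patient_id"],
                                        config, seed)
    else:
        mutations = pd.DataFrame(columns=["patient_id", "gene", "chrom", "pos",
                                          "impact", "variant_class"])

    from .cohort import parse_cohort  # late import avoids a cycle at module load
    cohort = parse_cohort(mutations, clin)
    if not with_mutation_rows:
        # functional counts come from the matrix when rows were skipped
        tmb = pd.Series(counts.sum(axis=1), index=cohort.patients["patient_id"])
        cohort.tmb = tmb

    driver_idx = _driver_indices(config, genes)
    driver_names = [genes[i].gene_id for i in driver_idx]
    driver_status = pd.DataFrame(
        (counts[:, driver_idx] > 0).astype(int),
        index=cohort.patients["patient_id"], columns=driver_names,
    )
    return SimulatedCohort(
        cohort=cohort,
        genes=genes,
        covariates=covariates,
        counts=counts,
        driver_genes=driver_names,
        driver_status=driver_status,
        pathways=generate_pathways(genes, config, seed),
        true_log_rate=log_rate,
        survival=survival_df,
    )


def null_config(**overrides) -> SimConfig:
    """Study-scale configuration with no drivers and no response signal."""
    base = SimConfig(n_drivers=0, driver_response_effects=(),
                     response_tmb_effect=0.0, response_age_effect=0.0)
    return replace(base, **overrides) if overrides else base
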