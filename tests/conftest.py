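import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")

from circleicb.background import CovariatePCA
from circleicb.simulate import SimConfig, simulate_cohort


@pytest.fixture
def tiny_tables():
    """Two patients, three mutations — the smallest joinable cohort."""
    mutations = pd.DataFrame({
        "patient_id": ["P1", "P1", "P2"],
        "gene": ["TP53", "KRAS", "TP53"],
        "chrom": ["chr17", "chr12", "chr17"],
        "pos": [7578406, 25398284, 7577120],
        "impact": ["High", "Moderate", "Low"],
        "variant_class": ["stop_gained", "missense_variant", "synonymous_variant"],
    })
    clinical = pd.DataFrame({
        "patient_id": ["P1", "P2"],
        "age": [64.0, np.nan],
        "tumor_type": ["melanoma", "NSCLC"],
        "study_id": ["study_A", "study_B"],
        "recist": ["PR", "SD"],
    })
    return mutations, clinical


def make_pcs(sim, k=(2, 3, 2)):
    """Reduce a simulated covariome with the family structure it was built with."""
    fams = {f: [c for c in sim.covariates.columns if c.startswith(f)]
            for f in ("timing", "chromatin", "context")}
    ncomp = dict(zip(fams, k))
    return CovariatePCA(fams, ncomp).fit(sim.covariates).transform(sim.covariates)


@pytest.fixture(scope="session")
def sim_small():
    """Mid-size synthetic cohort with full mutation rows, shared across tests."""
    return simulate_cohort(SimConfig(n_genes=500, n_patients=300), seed=3)


@pytest.fixture(scope="session")
def sim_small_pcs(sim_small):
    return make_pcs(sim_small)
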