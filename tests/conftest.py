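import numpy as np
import pandas as pd
import pytest

from paleoselect import simulate as sim
from paleoselect import structure
from paleoselect.cohort_io import CohortGenotypes


@pytest.fixture(scope="session")
def small_sim():
    """Structured two-population dated cohort, 140 samples, 60 variants."""
    cfg = sim.SimulationConfig(
        n_pops=2, n_samples=120, n_modern=20, n_variants=60, n_chrom=2,
        fst=0.05, seed=11,
    )
    return sim.synth_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    return small_sim.cohort


@pytest.fixture(scope="session")
def small_grm(small_cohort):
    return structure.compute_grm(small_cohort)


@pytest.fixture(scope="session")
def small_clusters(small_cohort, small_grm):
    pcs = structure.top_pcs(small_grm, 10)
    return structure.cluster_ancestry_date(
        pcs, small_cohort.dates_bp, list(small_cohort.samples["sample_id"]),
        target=30, max_gap=500.0,
    )


@pytest.fixture()
def tiny_cohort():
    """Hand-sized 4-sample, 3-variant cohort with one missing dosage."""
    G = np.array([
        [0.0, 2.0, 1.0],
        [1.0, 1.0, 0.0],
        [2.0, 0.0, np.nan],
        [1.0, 2.0, 2.0],
    ])
    variants = pd.DataFrame({
        "chrom": ["1", "1", "2"],
        "pos": [100, 200, 50],
        "ref": ["A", "C", "G"],
        "alt": ["G", "T", "A"],
        "ancestral_is_ref": [True, True, False],
        "maf": [0.5, 0.375, 0.5],
    })
    samples = pd.DataFrame({
        "sample_id": ["a", "b", "c", "d"],
        "date_bp": [5800.0, 2900.0, 0.0, 1000.0],
        "region": ["x", "x", "y", "y"],
        "is_modern": [False, False, True, False],
    })
    return CohortGenotypes(G, variants, samples)
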