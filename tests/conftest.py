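import numpy as np
import pandas as pd
import pytest

from laspa import (
    GenotypeMatrix,
    SimulationConfig,
    simulate_cohort,
)

FIXTURE_SEED = 20240817


@pytest.fixture(scope="session")
def fixture_cohort():
    """Small admixed test cohort: 200 subjects × 2,000 SNVs over 2 chromosomes."""
    cfg = SimulationConfig(
        n_subjects=200,
        n_chromosomes=2,
        snvs_per_chromosome=1000,
        region_size=500,
        missing_rate=0.01,
        seed=FIXTURE_SEED,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def fixture_config():
    return SimulationConfig(
        n_subjects=200,
        n_chromosomes=2,
        snvs_per_chromosome=1000,
        region_size=500,
        missing_rate=0.01,
        seed=FIXTURE_SEED,
    )


def make_genotypes(dosages, chrom=None, pos=None):
    """GenotypeMatrix from a raw dosage array with auto metadata."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    meta = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["chr1"] * m,
            "pos": pos if pos is not None else np.arange(1, m + 1) * 100,
            "snv_id": [f"s{i}" for i in range(m)],
        }
    )
    ids = np.array([f"sub{i}" for i in range(n)], dtype=object)
    return GenotypeMatrix(dosages, meta, ids)
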