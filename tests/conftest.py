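import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from longtraj import GenotypeDataset, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def null_cohort():
    """A no-selection cohort reused by several calibration tests."""
    cfg = SimulationConfig(
        n_birth_cohort=6000,
        n_snps=300,
        seed=7,
        sample_sizes=(381, 392, 333),
    )
    return simulate_cohort(cfg)


@pytest.fixture
def tiny_dataset():
    """Hand-built 4-individual x 3-SNP dataset with one missing genotype."""
    dosages = np.array(
        [
            [0.0, 1.0, 2.0],
            [1.0, np.nan, 2.0],
            [2.0, 0.0, 1.0],
            [1.0, 1.0, 0.0],
        ]
    )
    snp_meta = pd.DataFrame(
        {
            "snp": ["rsA", "rsB", "rsC"],
            "chrom": [1, 1, 2],
            "pos": [100, 200, 300],
            "effect_allele": ["A", "C", "G"],
            "other_allele": ["G", "T", "A"],
        }
    )
    ind_meta = pd.DataFrame(
        {
            "id": ["i1", "i2", "i3", "i4"],
            "sex": ["F", "M", "F", "M"],
            "age": [30.0, 45.0, 70.0, 101.0],
            "group": ["G1", "G1", "G2", "G3"],
            "center": ["N", "N", "C", "S"],
        }
    )
    return GenotypeDataset(dosages, snp_meta, ind_meta)
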