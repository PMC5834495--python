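import numpy as np
import pandas as pd
import pytest

from bnbmla.bn_core import DiscreteDataset
from bnbmla.cohort_data import SNP_LEVELS, SNP_NAMES, default_dictionary, from_dataframe
from bnbmla.synthetic_cohort import gxe_config, null_config, simulate_cohort


def make_cohort_frame(n: int, seed: int = 0) -> pd.DataFrame:
    """Small hand-rolled valid cohort frame (independent of the simulator)."""
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {
            "id": [f"P{i}" for i in range(n)],
            "age": rng.uniform(18, 70, n).round(1),
            "sex": rng.choice(["male", "female"], n),
            "population": rng.choice(["BUD", "MAN"], n),
            **{snp: rng.choice(SNP_LEVELS[snp], n) for snp in SNP_NAMES},
            "rle_count": rng.integers(0, 6, n),
            "dep": rng.integers(0, 2, n),
            "bsi_dep": rng.uniform(0, 4, n).round(2),
            "bsi_anx": rng.uniform(0, 4, n).round(2),
        }
    )
    return frame


@pytest.fixture
def small_cohort():
    return from_dataframe(make_cohort_frame(60, seed=1))


@pytest.fixture(scope="session")
def gxe_cohort():
    """One seeded interaction-only cohort at the study's scale."""
    return simulate_cohort(gxe_config(n_subjects=1700, seed=0)).cohort


@pytest.fixture(scope="session")
def null_cohort():
    """One seeded cohort with every effect coefficient zero."""
    return simulate_cohort(null_config(n_subjects=1700, seed=0)).cohort


@pytest.fixture(scope="session")
def oracle_dataset():
    """3-variable dataset where X copies the target T and Z is noise."""
    rng = np.random.default_rng(42)
    n = 100
    t = rng.integers(0, 2, n)
    z = rng.integers(0, 2, n)
    return DiscreteDataset(["T", "X", "Z"], [2, 2, 2], np.column_stack([t, t.copy(), z]))
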