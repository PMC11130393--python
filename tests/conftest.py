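import numpy as np
import pandas as pd
import pytest

from tmtprofiler import CohortSpec, simulate_cohort, preprocess_cohort
from tmtprofiler.preprocess import ProteinMatrix


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(
        n_sets=3, channels_per_set=10, n_proteins=150, common_core_fraction=0.4,
        n_subtypes=2, signature_size=6, signature_effect=1.5, noise_sd=0.3, seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return simulate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    psms, sheet, _ = small_cohort
    matrix, report = preprocess_cohort(psms, sheet)
    return matrix, report


def make_matrix(ratios: pd.DataFrame, psm_counts: pd.DataFrame | None = None,
                set_id: str = "set01") -> ProteinMatrix:
    """Build a single-set ProteinMatrix directly from a ratio frame."""
    if psm_counts is None:
        psm_counts = pd.DataFrame({set_id: np.ones(len(ratios), dtype=int)},
                                  index=ratios.index)
    sample_sets = pd.Series(set_id, index=ratios.columns)
    return ProteinMatrix(ratios=ratios, psm_counts=psm_counts, sample_sets=sample_sets)
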