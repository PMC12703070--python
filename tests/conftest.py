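import numpy as np
import pytest

from neurotyp import filter_cohort
from neurotyp.simulate import SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A quick mid-size cohort: 24 subjects, 10 signals, 240 volumes."""
    return SyntheticCohortConfig(
        n_subjects=24,
        n_components=10,
        n_volumes=240,
        segment_lengths=(80, 78, 82),
        n_outlier_subjects=0,
        seed=2,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    cohort, personality, covariates, truth = generate_cohort(small_config)
    return cohort, personality, covariates, truth


@pytest.fixture(scope="session")
def small_filtered(small_cohort):
    cohort, personality, covariates, truth = small_cohort
    return filter_cohort(cohort), personality, covariates, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
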