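import numpy as np
import pytest

from rehabprog import GeneratorConfig, generate_cohort
from rehabprog.interface_io import cohort_arrays


@pytest.fixture(scope="session")
def tiny_config():
    """Small cohort for fast structural tests."""
    return GeneratorConfig(n_subjects=6, n_exercises=2, frames_per_trial=40,
                           clinical_dim=3, seed=11)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    samples, profiles = generate_cohort(tiny_config)
    return samples, profiles


@pytest.fixture(scope="session")
def tiny_arrays(tiny_cohort):
    samples, _ = tiny_cohort
    return cohort_arrays(samples)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
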