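import numpy as np
import pytest

from cctpipe import CohortConfig, synthesize_subject, sample_truths


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """A two-subject cohort at study noise levels (cheap to synthesize)."""
    return CohortConfig(n_control=1, n_vasospasm=1, seed=42)


@pytest.fixture(scope="session")
def noiseless_config() -> CohortConfig:
    return CohortConfig(n_control=1, n_vasospasm=1, noise_sd=0.0, seed=42)


@pytest.fixture(scope="session")
def noiseless_subject(noiseless_config):
    truth = sample_truths(noiseless_config)[0]
    return synthesize_subject(truth, noiseless_config, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
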