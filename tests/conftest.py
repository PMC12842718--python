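import numpy as np
import pytest

from hms.synthetic import GenConfig, build_dataset


@pytest.fixture(scope="session")
def small_config():
    """A small but fully populated cohort used across module tests."""
    return GenConfig(n_eyes=300, seed=123)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return build_dataset(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
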