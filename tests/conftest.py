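import numpy as np
import pytest

from memtc import ModelParams, settle_to_attractor


@pytest.fixture(scope="session")
def default_params():
    return ModelParams()


@pytest.fixture(scope="session")
def swd_trajectory(default_params):
    """Settled spike-and-wave discharge (single model, k7 = 2, k0 = 0)."""
    return settle_to_attractor(default_params.replace(k7=2.0))


@pytest.fixture(scope="session")
def tonic_trajectory(default_params):
    """Settled tonic oscillation (single model, k7 = 4.5, k0 = 0)."""
    return settle_to_attractor(default_params.replace(k7=4.5))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
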