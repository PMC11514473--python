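import numpy as np
import pytest

from foldbind import GroundTruth, NoiseModel


@pytest.fixture(scope="session")
def truth():
    """Wild-type study conditions."""
    return GroundTruth()


@pytest.fixture
def quiet_noise():
    return NoiseModel(sigma=0.01, seed=7)


@pytest.fixture
def no_noise():
    return NoiseModel(sigma=0.0, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
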