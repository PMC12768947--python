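import numpy as np
import pytest

from pahsers.references import NoiseConfig, default_reference_library
from pahsers.spectra import WavenumberGrid


@pytest.fixture(scope="session")
def grid():
    return WavenumberGrid()


@pytest.fixture(scope="session")
def library(grid):
    return default_reference_library(grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def silent_cfg():
    """Measurement model with noise, shifts and background all off."""
    return NoiseConfig(noise_sd=0.0, max_shift=0, background_scale=0.0, seed=0)


@pytest.fixture()
def quiet_cfg():
    """Background present but no stochastic components."""
    return NoiseConfig(noise_sd=0.0, max_shift=0, background_scale=0.05, seed=0)
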