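import numpy as np
import pytest

from teoim import GridSpec, NoiseConfig, SceneConfig


@pytest.fixture
def square_grid():
    """Odd-sized square grid: the center coincides with a pixel center."""
    return GridSpec(33, 33, 0.25)


@pytest.fixture
def sim_grid():
    return GridSpec(64, 64, 0.2)


@pytest.fixture
def scene():
    return SceneConfig()


@pytest.fixture
def quiet_noise():
    """Low-noise configuration for tests that still exercise the noise path."""
    return NoiseConfig(read_noise_sigma=0.002, n_frames=100, replicate_drift_sigma=0.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
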