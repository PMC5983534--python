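import numpy as np
import pytest

from gazeclean import (
    FixationChunk,
    GazeTrace,
    NoiseConfig,
    PipelineConfig,
    ScreenGeometry,
    gen_layout,
)


@pytest.fixture
def geom():
    return ScreenGeometry()


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def ng50():
    return gen_layout("ng", spacing=50)


@pytest.fixture
def calibration_layout():
    return gen_layout("calibration")


def make_trace(xy, fs=30.0, valid=None):
    xy = np.asarray(xy, dtype=float)
    t = np.arange(len(xy)) / fs
    return GazeTrace(t, xy, valid, fs)


def static_chunk(target, sigma, n, seed):
    """A fixation chunk of Gaussian-dispersed samples around one target."""
    rng = np.random.default_rng(seed)
    xy = np.asarray(target, float) + rng.normal(0.0, sigma, (n, 2))
    return FixationChunk(xy, 0, n - 1, t=np.arange(n) / 30.0)


@pytest.fixture
def noise_free():
    return NoiseConfig(sigma=0.0, outlier_prob=0.0, seed=0)
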