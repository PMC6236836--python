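import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phantomtex import AcquisitionParams, NoiseModel, PhantomConfig, ROIMask
from phantomtex.texture_features import QuantizedROI

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_params():
    """Small-matrix acquisition for fast simulation tests."""
    return AcquisitionParams(matrix=(64, 48), n_slices=3)


@pytest.fixture
def default_phantom():
    return PhantomConfig()


@pytest.fixture
def quiet_noise():
    return NoiseModel(sigma_base=0.0, rng_seed=0)


def random_roi(rng, max_side=16, G=6):
    """Random quantized ROI with a random (mostly-covering) mask."""
    rows = int(rng.integers(4, max_side + 1))
    cols = int(rng.integers(4, max_side + 1))
    levels = rng.integers(0, G, size=(rows, cols)).astype(np.int32)
    mask = rng.random((rows, cols)) < 0.8
    mask[1:-1, 1:-1] |= rng.random((rows - 2, cols - 2)) < 0.5
    mask[1:3, 1:3] = True  # guarantee interior pixels and adjacent pairs
    return QuantizedROI(levels=levels, G=G, mask=ROIMask(mask))
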