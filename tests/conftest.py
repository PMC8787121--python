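import numpy as np
import pytest

from mmiqa import FixtureSpec, MMIQAParams, generate_pool_fixture
from mmiqa.saliency import SaliencyParams

# Test-scale metric parameters: the synthetic fixtures are 144x192, so the
# saliency stage runs at width 64 (3x downscale, comfortably below the 8-px
# JPEG block grid). Every test that depends on parameter values pins them
# through this object.
TEST_SALIENCY = SaliencyParams(working_width=64)
TEST_PARAMS = MMIQAParams(saliency=TEST_SALIENCY)


def pool_fixture(seed: int, height: int = 144, width: int = 192):
    """Standard small pool-scene fixture used across the suite."""
    return generate_pool_fixture(FixtureSpec(
        seed=seed, height=height, width=width, tile_period=16,
        ripple_amplitude=1.5, noise_sd=2.0,
    ))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def params():
    return TEST_PARAMS
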