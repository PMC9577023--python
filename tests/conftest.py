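import numpy as np
import pytest

from fbmdrop import FBMParams, build_grid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid10():
    return build_grid(10)


@pytest.fixture
def fast_params():
    """Small FBM parameter set for quick Monte-Carlo checks."""
    return FBMParams(hurst=0.9, sigma=1.0, t_max=8.0, dt=1.0)
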