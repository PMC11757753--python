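import numpy as np
import pytest

from turingrmt import DiffusionSpec, KGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def diff():
    """The default diffusion protocol: D1 = 1, D2 = 10, others immobile."""
    return DiffusionSpec(1.0, 10.0)


@pytest.fixture
def coarse_grid():
    """Wavenumber grid coarse enough for fast Monte-Carlo tests."""
    return KGrid(step=0.05)
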