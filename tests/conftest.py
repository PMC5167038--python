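import numpy as np
import pytest

from mastsecr import TrapArray, build_mask


@pytest.fixture
def rng():
    return np.random.default_rng(20160)


@pytest.fixture(scope="session")
def grid8():
    """The study design's 8x8 trap grid at 10-m spacing."""
    return TrapArray.grid(8, 8, 10.0)


@pytest.fixture(scope="session")
def mask8(grid8):
    """Analysis mask for the 8x8 grid: 100-m buffer, 10-m spacing."""
    return build_mask(grid8, buffer=100.0, spacing=10.0)


@pytest.fixture(scope="session")
def mask8_coarse(grid8):
    """Coarser mask used where many fits are needed."""
    return build_mask(grid8, buffer=100.0, spacing=25.0)
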