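import numpy as np
import pytest

from retodr.io import RunConfig, VesselMask


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def bar_mask():
    """Horizontal bar, 5 px wide, 100 px long."""
    m = np.zeros((60, 120), bool)
    m[20:25, 10:110] = True
    return VesselMask(m)


@pytest.fixture
def plus_mask():
    """Two 5-px-wide bars crossing at the center."""
    m = np.zeros((81, 81), bool)
    m[38:43, 5:76] = True
    m[5:76, 38:43] = True
    return VesselMask(m)


@pytest.fixture
def y_mask():
    """Three 5-px-wide arms meeting at one point."""
    m = np.zeros((81, 81), bool)
    m[40:76, 38:43] = True
    for i in range(35):
        r = 40 - i
        for c in range(38 - i - 2, 38 - i + 3):
            if 0 <= c < 81:
                m[r, c] = True
        for c in range(42 + i - 2, 42 + i + 3):
            if 0 <= c < 81:
                m[r, c] = True
    return VesselMask(m)


def make_bar_mask(width, length=100, shape=(60, 120), top=20, left=10):
    m = np.zeros(shape, bool)
    m[top:top + width, left:left + length] = True
    return VesselMask(m)
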