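import numpy as np
import pytest

from gdikit.ctmc import IMParams


@pytest.fixture
def symmetric_im() -> IMParams:
    """The symmetric high-gene-flow configuration used throughout:
    tau = theta = 0.01 for all populations, M = 10 in both directions."""
    return IMParams(0.01, 0.01, 0.01, 10.0, 10.0, theta_AB=0.01)


@pytest.fixture
def asymmetric_im() -> IMParams:
    """An asymmetric configuration with distinct eigenvalues (spectral path)."""
    return IMParams(0.01, 0.02, 0.008, 5.0, 3.0, theta_AB=0.015)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
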