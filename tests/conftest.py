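import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from cstquant import get_preset
from cstquant.calibration import BleedThroughParams


@pytest.fixture(scope="session")
def untreated():
    return get_preset("CST-untreated")


@pytest.fixture(scope="session")
def small_untreated():
    """Untreated preset on a 128 px field — fast, same physics."""
    return get_preset("CST-untreated").with_(field_size=128)


@pytest.fixture(scope="session")
def small_noiseless():
    return get_preset("CST-untreated").with_(field_size=128, noise_scale=0.0)


@pytest.fixture(scope="session")
def typical_bleed():
    return BleedThroughParams(A=0.1, B=0.25)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
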