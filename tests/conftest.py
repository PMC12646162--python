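import numpy as np
import pytest

from trichomech import synthio
from trichomech.beam import TrichomeGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def standard_geometry():
    """A typical type VI stalk: 100 μm long, tapering 10 → 5 μm radius."""
    return TrichomeGeometry(L=100.0, R1=5.0, R2=10.0)


@pytest.fixture
def noiseless_scenario():
    return synthio.RuptureScenario(k_true=0.1, F_r_true=6.0, loading_rate=1.0,
                                   noise_sd=0.0, seed=7)
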