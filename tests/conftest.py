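import numpy as np
import pytest

from swvquant.io import Voltammogram


@pytest.fixture
def ramp_sweep():
    """Current equal to the potential over 0–2 V (piecewise-linear exact)."""
    pot = np.linspace(0.0, 2.0, 201)
    return Voltammogram(potentials=pot, currents=pot.copy(), sample_id="ramp")


@pytest.fixture
def flat_sweep():
    """Constant 3 µA over the full sweep."""
    pot = np.linspace(-2.4, 2.5, 491)
    return Voltammogram(potentials=pot, currents=np.full(pot.size, 3.0),
                        sample_id="flat")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
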