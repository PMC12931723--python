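import numpy as np
import pytest

from gutpkpd import presets
from gutpkpd.dosing import Regimen


@pytest.fixture
def rng():
    return np.random.default_rng(20240615)


@pytest.fixture
def cro_regimen():
    return presets.default_regimen("CRO", 5)


@pytest.fixture
def single_infusion():
    """One 1-hour infusion of 1000 mg."""
    return Regimen("X", 1000.0, interval_h=24.0, n_days=1, infusion_h=1.0)
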