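import numpy as np
import pytest

from rhizophb.flow_calibration import GatingConfig
from rhizophb.synthetic_data import default_instrument_curve


@pytest.fixture
def curve():
    return default_instrument_curve()


@pytest.fixture
def gate():
    return GatingConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
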