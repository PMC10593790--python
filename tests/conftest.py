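import numpy as np
import pytest

from bgpipe import synthdata as sd


@pytest.fixture
def base_cfg():
    """Small, fast simulation config shared across tests."""
    return sd.SimConfig(seed=0, duration_s=120.0,
                        bout_schedule=sd.default_bout_schedule(120.0))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
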