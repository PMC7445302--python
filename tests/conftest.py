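import numpy as np
import pytest

from rosette.topology import RosetteTopology


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def chain_topology():
    return RosetteTopology(f_c=1, f_r=0, n_per_arm=99)


@pytest.fixture
def ring_topology():
    return RosetteTopology(f_c=0, f_r=1, n_per_arm=100)
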