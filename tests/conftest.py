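import numpy as np
import pytest

from abmkf import viral, wsg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def wsg_params():
    return wsg.WSGParams(world_width=21, world_height=21, init_wolves=20, init_sheep=40)


@pytest.fixture
def viral_params():
    return viral.ViralParams(width=15, height=15)


@pytest.fixture
def hotspot_micro(viral_params):
    """Mid-epidemic viral state grown from a single seed: clustered infection."""
    rng = np.random.default_rng(777)
    micro = viral.init_viral(viral_params, 1, rng)
    for _ in range(20):
        micro = viral.step_viral(micro, viral_params, rng)
    return micro
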