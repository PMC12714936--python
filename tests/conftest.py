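import numpy as np
import pytest

from abrnirs import stimuli as st
from abrnirs import synthetic as sy


@pytest.fixture(scope="session")
def warble_protocol():
    return st.build_warble_protocol()


@pytest.fixture(scope="session")
def small_click_protocol():
    """10 clicks per intensity at the standard rate, with a lead-in and
    inter-block gaps so pre-block baselines exist."""
    return st.build_click_protocol(
        81.9, 10, [50.0, 70.0, 90.0], start=1.0, inter_block_gap=1.0
    )


@pytest.fixture(scope="session")
def abr_recording(small_click_protocol):
    truth = sy.AbrTruth(seed=7)
    return sy.simulate_abr(small_click_protocol, truth, n_channels=2), truth


@pytest.fixture(scope="session")
def fnirs_pair(warble_protocol):
    truth = sy.HemoTruth(seed=11)
    raw, chromo = sy.simulate_fnirs(warble_protocol, truth)
    return raw, chromo, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
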