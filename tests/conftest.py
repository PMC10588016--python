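import numpy as np
import pytest

from morsecg import MorseParams, design_filterbank


@pytest.fixture(scope="session")
def default_params():
    return MorseParams(gamma=3.0, p2=60.0)


@pytest.fixture(scope="session")
def small_bank(default_params):
    """Filterbank for 64-sample signals at 128 Hz (fast oracle comparisons)."""
    return design_filterbank(64, 128.0, default_params, voices_per_octave=12)


@pytest.fixture(scope="session")
def paper_bank(default_params):
    """The reference configuration: 500 samples, 128 Hz, P^2=60, 12 voices."""
    return design_filterbank(500, 128.0, default_params, voices_per_octave=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
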