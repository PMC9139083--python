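import numpy as np
import pytest

from chromacal.simulate import DeviceModel, measure_chart, synth_chart


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def chart55():
    return synth_chart(55, seed=7)


@pytest.fixture
def identity_pairs(chart55):
    """Pairs where the device reproduces the reference exactly."""
    dev = DeviceModel.identity(noise_sd=0.0)
    return measure_chart(dev, chart55)
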