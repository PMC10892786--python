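import numpy as np
import pytest

from somnoboost import Hypnogram, Recording, simulate_subject
from somnoboost.preprocess import Epoch


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_subject():
    """One seeded synthetic subject: 80 epochs, easy preset."""
    return simulate_subject(80, preset="easy", seed=5, rec_id="S00")


@pytest.fixture
def sine_epoch():
    """Unit-amplitude 10 Hz sine, 30 s at 100 Hz."""
    t = np.arange(3000) / 100.0
    return Epoch(np.sin(2 * np.pi * 10 * t), rate=100.0, index=0, recording_id="sine")


@pytest.fixture
def noise_epoch(rng):
    return Epoch(rng.standard_normal(3000), rate=100.0, index=0, recording_id="noise")


@pytest.fixture
def flat_recording():
    return Recording(np.zeros(6000) + 3.0, rate=100.0, id="flat")


def make_recording(samples, rate=100.0, **kw):
    return Recording(np.asarray(samples, float), rate=rate, **kw)
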