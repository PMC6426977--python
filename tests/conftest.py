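import numpy as np
import pytest

from dstab import Recording, StateInterval, make_two_state_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """4 channels x 1000 samples of band-limited noise at 1 kHz."""
    t = np.arange(1000) / 1000.0
    data = np.vstack(
        [
            np.sin(2 * np.pi * (10 + 5 * c) * t) + 0.1 * rng.normal(size=t.size)
            for c in range(4)
        ]
    )
    return Recording(data, fs=1000.0)


@pytest.fixture
def labeled_interval():
    """Interval whose trimmed extent is exactly [30, 130] s."""
    return StateInterval("awake", 0.0, 160.0, trim_s=30.0)


@pytest.fixture(scope="session")
def two_state():
    """One default synthetic two-state recording, shared across tests."""
    return make_two_state_recording(seed=7)
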