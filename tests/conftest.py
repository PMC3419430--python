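import numpy as np
import pytest

from cardioemd import Signal, white_noise_reference


@pytest.fixture(scope="session")
def wn_reference():
    """White-noise band shared by every test that classifies IMFs."""
    return white_noise_reference(n_samples=2048, n_realizations=100, seed=11)


@pytest.fixture()
def sine_signal():
    t = np.arange(0, 10, 1 / 250)
    return Signal(np.sin(2 * np.pi * 1.0 * t), 250.0, "sine")


@pytest.fixture()
def two_tone_signal():
    t = np.arange(0, 5, 1 / 1000)
    return (
        Signal(np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 1 * t), 1000.0),
        np.sin(2 * np.pi * 10 * t),
        np.sin(2 * np.pi * 1 * t),
    )
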