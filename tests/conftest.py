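import numpy as np
import pytest

from soundtexture import AudioSignal, design_cochlear_filterbank


@pytest.fixture(scope="session")
def default_bank():
    return design_cochlear_filterbank()


@pytest.fixture(scope="session")
def white_noise_1s():
    rng = np.random.default_rng(0)
    return AudioSignal(rng.standard_normal(48_000) * 0.1, 48_000)


@pytest.fixture(scope="session")
def white_noise_5s():
    rng = np.random.default_rng(1)
    return AudioSignal(rng.standard_normal(240_000) * 0.1, 48_000)


def am_noise(duration=2.0, rate=48_000, am_rate=4.0, depth=1.0, seed=42,
             rms=0.1):
    """Sinusoidally amplitude-modulated Gaussian noise."""
    rng = np.random.default_rng(seed)
    n = int(duration * rate)
    t = np.arange(n) / rate
    x = (1.0 + depth * np.sin(2 * np.pi * am_rate * t)) * rng.standard_normal(n)
    x *= rms / np.sqrt(np.mean(x**2))
    return AudioSignal(x, rate)
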