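import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def periodic_envelope(n: int = 1200, fs: float = 20.0, cycle_s: float = 2.0,
                      noise: float = 0.0, seed: int = 0) -> np.ndarray:
    """Noise-free (or lightly noisy) quasi-periodic envelope for prediction tests."""
    t = np.arange(n) / fs
    x = np.sin(2 * np.pi * t / cycle_s) + 0.5 * np.sin(4 * np.pi * t / cycle_s + 0.7)
    if noise > 0:
        x = x + noise * np.random.default_rng(seed).standard_normal(n)
    return x
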