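import numpy as np
import pytest

import ecgkit as ek


@pytest.fixture(scope="session")
def small_five_class():
    """100 noisy synthetic beats, 20 per class."""
    return ek.make_beat_dataset({c: 20 for c in "NSVFQ"}, noise_sd=0.05, seed=7)


@pytest.fixture(scope="session")
def clean_five_class():
    """Noise-free beats for separability checks."""
    return ek.make_beat_dataset({c: 10 for c in "NSVFQ"}, noise_sd=0.0, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def numeric_grad(f, x, eps=1e-6):
    """Central-difference gradient of scalar f at array x."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp = x.copy(); xp[i] += eps
        xm = x.copy(); xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
    return g
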