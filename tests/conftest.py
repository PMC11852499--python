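import numpy as np
import pytest

from gdtil import EEGEpochs, SyntheticConfig, generate_mi_epochs


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_epochs():
    """24 trials, 2 classes, 4 channels, 64 samples at 128 Hz."""
    cfg = SyntheticConfig(n_classes=2, trials_per_class=12, n_channels=4,
                          duration_s=0.5, fs=128.0, snr=1.0, seed=3)
    return generate_mi_epochs(cfg)


def numerical_gradient(f, x, eps=1e-6):
    """Central finite differences of scalar f with respect to array x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
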