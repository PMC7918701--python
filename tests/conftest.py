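import numpy as np
import pytest

from ssvepdecode import EpochSet, SimConfig, simulate_subject


def make_epochs(data, fs=250.0, freqs=None, labels=None, t0=0.0):
    """Wrap a raw 4-way array in an EpochSet with consistent metadata."""
    data = np.asarray(data, dtype=float)
    nf, _, nc, _ = data.shape
    if freqs is None:
        freqs = 8.0 + 0.2 * np.arange(nf)
    if labels is None:
        labels = tuple(f"CH{c + 1}" for c in range(nc))
    return EpochSet(data=data, fs=fs, channel_labels=labels, stim_freqs=freqs, t0=t0)


@pytest.fixture(scope="session")
def noiseless_subject():
    """Small noise-free recording: every trial equals its class source."""
    return simulate_subject(SimConfig(snr_db=np.inf))


@pytest.fixture(scope="session")
def noisy_subject():
    """One subject at the default study conditions (pink + alpha, -10 dB)."""
    return simulate_subject(SimConfig(mixing_seed=7, noise_seed=8))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
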