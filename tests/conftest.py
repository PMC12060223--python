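import numpy as np
import pytest

from icohnet.preprocess import EpochSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_epochs(data: np.ndarray, fs: float = 256.0, tmin: float = -2.0, ch_names=None) -> EpochSet:
    if ch_names is None:
        ch_names = [f"CH{i + 1}" for i in range(data.shape[1])]
    return EpochSet(data=data, fs=fs, ch_names=ch_names, tmin=tmin)


@pytest.fixture
def noise_epochs(rng):
    """42 trials x 4 channels of white noise over the full -2..+5 s epoch."""
    data = rng.standard_normal((42, 4, 1792))
    return make_epochs(data)


def narrowband(rng, n_trials: int, n_samp: int, fs: float, band) -> np.ndarray:
    """Analytic narrow-band noise (trials, samples), unit real RMS — test helper."""
    freqs = np.fft.fftfreq(n_samp, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs < band[1])
    spec = np.zeros((n_trials, n_samp), dtype=complex)
    k = int(mask.sum())
    spec[:, mask] = rng.standard_normal((n_trials, k)) + 1j * rng.standard_normal((n_trials, k))
    z = np.fft.ifft(spec, axis=-1)
    return z / np.sqrt(np.mean(z.real**2, axis=-1, keepdims=True))
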