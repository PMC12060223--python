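"""Cross-spectra, complex coherency and its imaginary part (iCOH).

Per analysis window, each trial is Fourier-transformed over the full 1-s
segment with a Hann taper (single segment, 1 Hz resolution) and the
cross-spectral matrix averages outer products over trials:

    S_ij(f) = (1/N) sum_n X_i^(n)(f) conj(X_j^(n)(f))

Coherency is the auto-spectrum-normalized cross-spectrum,
C_ij(f) = S_ij(f) / sqrt(S_ii(f) S_jj(f)), and iCOH is Im{C_ij(f)} averaged
over the frequency bins of a band.  Because a zero-lag (volume-conducted)
common source contributes a purely real coherency, iCOH is insensitive to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default sensorimotor bands (name, low Hz, high Hz); bins taken half-open
#: [low, high) so adjacent bands do not share the 13 Hz bin.
DEFAULT_BANDS: tuple[tuple[str, float, float], ...] = (
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 30.0),
)

#: Recorded in serialized output metadata: the coherency normalization used.
NORMALIZATION = "C_ij(f) = S_ij(f) / sqrt(S_ii(f) * S_jj(f))"


@dataclass
class SpectralEstimate:
    """Trial spectra ``X`` (trials, channels, freqs) and cross-spectra ``S``."""

    X: np.ndarray
    S: np.ndarray
    freqs: np.ndarray
    n_trials: int


@dataclass
class CoherenceStack:
    """Complex coherency per frequency plus band-averaged iCOH matrices."""

    coherency: np.ndarray  # (channels, channels, freqs)
    freqs: np.ndarray
    window: str = ""  # 'pre' or 'post'
    icoh: dict[str, np.ndarray] = field(default_factory=dict)  # band name -> (ch, ch)
    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS
    normalization: str = NORMALIZATION


def cross_spectra(window_trials: np.ndarray, fs: float) -> SpectralEstimate:
    """Hann-tapered single-segment spectra per trial, averaged cross-spectra.

    ``window_trials`` is (trials, channels, samples); at least two trials are
    required — coherence is undefined from a single realization.
    """
    x = np.asarray(window_trials, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected (trials, channels, samples)")
    n_trials, _, n_samp = x.shape
    if n_trials < 2:
        raise ValueError("cross-spectra require at least 2 trials")
    taper = np.hanning(n_samp)
    X = np.fft.rfft(x * taper, axis=-1)
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / fs)
    # S: (ch, ch, freq); einsum over trials implements the trial average.
    S = np.einsum("tif,tjf->ijf", X, X.conj()) / n_trials
    return SpectralEstimate(X=X, S=S, freqs=freqs, n_trials=n_trials)


def coherency(est: SpectralEstimate, window: str = "") -> CoherenceStack:
    """Normalize cross-spectra to complex coherency, |C_ij(f)| <= 1."""
    S = est.S
    auto = np.real(np.einsum("iif->if", S))  # (ch, freq)
    bad = np.argwhere(auto <= 0)
    if bad.size:
        ch, fi = bad[0]
        raise ValueError(
            f"auto-spectrum non-positive at channel {ch}, {est.freqs[fi]:g} Hz"
        )
    denom = np.sqrt(auto[:, None, :] * auto[None, :, :])
    return CoherenceStack(coherency=S / denom, freqs=est.freqs, window=window)


def icoh_band(stack: CoherenceStack, band: tuple[float, float]) -> np.ndarray:
    """Band-average of Im{C_ij(f)} over bins in [low, high); antisymmetric."""
    low, high = band
    mask = (stack.freqs >= low) & (stack.freqs < high)
    if not mask.any():
        raise ValueError(f"no frequency bins in band [{low}, {high}) Hz")
    m = np.imag(stack.coherency[:, :, mask]).mean(axis=-1)
    np.fill_diagonal(m, 0.0)
    return m


def window_icoh(
    window_trials: np.ndarray,
    fs: float,
    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS,
    window: str = "",
) -> CoherenceStack:
    """Convenience: trials of one analysis window -> coherency + per-band iCOH."""
    stack = coherency(cross_spectra(window_trials, fs), window=window)
    stack.bands = tuple(bands)
    stack.icoh = {name: icoh_band(stack, (lo, hi)) for name, lo, hi in bands}
    return stack
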