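"""Synthetic EEG cohorts with planted connectivity, ERD, and outcome structure.

The generator emulates the study protocol the analysis expects: 64 channels at
256 Hz, 42 grasp trials per subject, epochs spanning -2..+5 s around the task
cue, a stroke and a control group.  Ground truth is planted explicitly:

- **edges**: each planted edge is one latent narrow-band oscillator projected
  to channel i directly and to channel j with a phase delay phi, on top of
  independent per-channel background noise.  A nonzero phi yields nonzero
  expected iCOH in the stated band/window; phi = 0 (pure instantaneous
  mixing) yields iCOH indistinguishable from zero — the property iCOH exists
  to enforce.
- **volume conduction**: an optional common broadband source mixed
  instantaneously into all channels (default on), to exercise iCOH's
  insensitivity to zero-lag mixing.
- **ERD**: a sustained narrow-band oscillator whose post-window amplitude is
  rescaled against the measured background so that post-window band power is
  ~ratio x pre-window band power on the stated channel.
- **outcome**: UL-FMA = intercept + sum(coef x true feature value) + Gaussian
  noise, clipped to [0, 66].

All randomness flows from one seeded generator hierarchy
(``numpy.random.SeedSequence(seed)`` with per-subject spawn keys); identical
seed + spec gives a bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import EpochSet, PRE_WINDOW, POST_WINDOW, load_channel_names
from .stats import band_power

_WINDOWS = {"pre": PRE_WINDOW, "post": POST_WINDOW}


@dataclass(frozen=True)
class PlantedEdge:
    """Phase-lagged coupling between two channels in one band and window."""

    ch_i: str
    ch_j: str
    band: str
    phase_lag: float  # radians; 0 = instantaneous mixing (no expected iCOH)
    strength: float  # 0..1, scales the shared-oscillator amplitude
    window: str = "post"  # 'pre' | 'post' | 'both'
    group: str | None = None  # restrict to one group; None = both

    @property
    def name(self) -> str:
        return f"EDGE({self.ch_i},{self.ch_j},{self.band})"


@dataclass(frozen=True)
class ERDEffect:
    """Target post/pre band-power ratio on one channel (ratio < 1 is ERD)."""

    channel: str
    band: str
    ratio: float
    group: str | None = None

    @property
    def name(self) -> str:
        return f"ERD({self.channel})"


@dataclass(frozen=True)
class OutcomeModel:
    """UL-FMA as a linear function of planted feature truth plus noise."""

    intercept: float = 45.0
    coefficients: dict[str, float] = field(default_factory=dict)  # feature name -> coef
    noise_sd: float = 5.0


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort; defaults follow the protocol."""

    n_subjects_per_group: int = 12
    n_channels: int = 64
    fs: float = 256.0
    n_trials: int = 42
    epoch_window: tuple[float, float] = (-2.0, 5.0)
    seed: int = 0
    band_specs: tuple[tuple[str, float, float], ...] = (("alpha", 8.0, 13.0), ("beta", 13.0, 30.0))
    planted_edges: tuple[PlantedEdge, ...] = ()
    erd_effects: tuple[ERDEffect, ...] = ()
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    background_sd: float = 1.0  # uV, white background noise
    pink_sd: float = 0.3  # uV, additional 1/f-shaped component
    edge_amplitude: float = 2.0  # uV at strength 1
    erd_snr: float = 4.0  # planted oscillator pre-window power / background power
    volume_conduction: float = 0.5  # common zero-lag source amplitude; 0 = off
    subject_sd: float = 0.2  # between-subject log-normal spread of effect sizes
    groups: tuple[str, ...] = ("stroke", "control")
    #: 'protocol': stroke affected hands alternate right/left, controls perform
    #: with the non-dominant (left) hand; 'all_right': every subject right —
    #: hemispheric flipping becomes the identity, so planted effects stay on
    #: their nominal channels (useful for channel-anchored recovery studies).
    hand_policy: str = "protocol"

    def __post_init__(self) -> None:
        for name, lo, hi in self.band_specs:
            if not 0 < lo < hi < self.fs / 2:
                raise ValueError(f"band {name!r}: require 0 < {lo} < {hi} < fs/2 = {self.fs / 2}")
        bands = {b[0] for b in self.band_specs}
        for e in self.planted_edges:
            if not 0 <= e.strength <= 1:
                raise ValueError(f"edge {e.name}: coupling strength must be in [0, 1]")
            if e.band not in bands:
                raise ValueError(f"edge {e.name}: unknown band {e.band!r}")
            if e.window not in {"pre", "post", "both"}:
                raise ValueError(f"edge {e.name}: window must be pre/post/both")
        if self.hand_policy not in {"protocol", "all_right"}:
            raise ValueError("hand_policy must be 'protocol' or 'all_right'")
        for eff in self.erd_effects:
            if eff.ratio <= 0:
                raise ValueError(f"ERD effect on {eff.channel}: power ratio must be > 0")
            if eff.band not in bands:
                raise ValueError(f"ERD effect on {eff.channel}: unknown band {eff.band!r}")

    @property
    def channel_names(self) -> list[str]:
        if self.n_channels == 64:
            return load_channel_names()
        return [f"CH{i + 1}" for i in range(self.n_channels)]

    @property
    def band_edges(self) -> dict[str, tuple[float, float]]:
        return {name: (lo, hi) for name, lo, hi in self.band_specs}

    @property
    def n_subjects(self) -> int:
        return self.n_subjects_per_group * len(self.groups)


@dataclass
class SubjectRecord:
    """One synthetic subject: clinical covariates plus epoched EEG."""

    subject_id: str
    group: str
    hand: str  # affected hand (stroke) / performing hand (control)
    ul_fma: float
    epochs: EpochSet

    def __post_init__(self) -> None:
        if not 0 <= self.ul_fma <= 66:
            raise ValueError("ul_fma must lie in [0, 66]")


# ---------------------------------------------------------------------------
# deterministic per-subject parameters (shared by generate_cohort and
# planted_truth so truth can be computed without synthesizing signals)


def _subject_meta(spec: CohortSpec, idx: int) -> tuple[str, str, str]:
    group = spec.groups[idx // spec.n_subjects_per_group]
    within = idx % spec.n_subjects_per_group
    sid = f"{group[:2]}{within + 1:02d}"
    if spec.hand_policy == "all_right":
        hand = "right"
    elif group == "stroke":
        hand = "right" if within % 2 == 0 else "left"
    else:
        hand = "left"  # controls perform with the non-dominant hand
    return sid, group, hand


def _subject_effects(spec: CohortSpec, idx: int) -> tuple[dict[PlantedEdge, float], dict[ERDEffect, float]]:
    """Per-subject realized edge strengths and ERD ratios (log-normal spread)."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(idx, 1)))
    _, group, _ = _subject_meta(spec, idx)
    edge_s: dict[PlantedEdge, float] = {}
    for e in spec.planted_edges:
        mult = float(np.exp(rng.normal(0.0, spec.subject_sd)))
        active = e.group is None or e.group == group
        edge_s[e] = float(np.clip(e.strength * mult, 0.0, 1.0)) if active else 0.0
    erd_r: dict[ERDEffect, float] = {}
    for eff in spec.erd_effects:
        mult = float(np.exp(rng.normal(0.0, spec.subject_sd)))
        active = eff.group is None or eff.group == group
        if active:
            erd_r[eff] = float(max(1.0 + (eff.ratio - 1.0) * mult, 0.05))
        else:
            erd_r[eff] = 1.0
    return edge_s, erd_r


def _truth_features(edge_s: dict[PlantedEdge, float], erd_r: dict[ERDEffect, float]) -> dict[str, float]:
    feats: dict[str, float] = {}
    for e, s in edge_s.items():
        feats[e.name] = s
    for eff, r in erd_r.items():
        feats[eff.name] = (r - 1.0) * 100.0  # ERD percent, negative for suppression
    return feats


def _outcome(spec: CohortSpec, idx: int, feats: dict[str, float]) -> float:
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(idx, 2)))
    m = spec.outcome_model
    y = m.intercept
    for name, coef in m.coefficients.items():
        if name not in feats:
            raise KeyError(f"outcome coefficient refers to unknown feature {name!r}")
        y += coef * feats[name]
    if m.noise_sd > 0:
        y += rng.normal(0.0, m.noise_sd)
    return float(np.clip(y, 0.0, 66.0))


def planted_truth(spec: CohortSpec) -> pd.DataFrame:
    """Noise-free per-subject feature values and outcomes, for recovery tests.

    Long table (subject, group, feature, value); rows also include the
    ``ul_fma`` the outcome model produced.  Empty when nothing is planted.
    """
    rows = []
    for idx in range(spec.n_subjects):
        sid, group, _ = _subject_meta(spec, idx)
        feats = _truth_features(*_subject_effects(spec, idx))
        for name, value in feats.items():
            rows.append({"subject": sid, "group": group, "feature": name, "value": value})
        if feats:
            rows.append(
                {"subject": sid, "group": group, "feature": "ul_fma", "value": _outcome(spec, idx, feats)}
            )
    return pd.DataFrame(rows, columns=["subject", "group", "feature", "value"])


# ---------------------------------------------------------------------------
# signal synthesis


def _narrowband_analytic(rng: np.random.Generator, shape: tuple[int, ...], n_samp: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS analytic narrow-band noise, shape (..., n_samp), complex."""
    freqs = np.fft.fftfreq(n_samp, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs < band[1])
    if not mask.any():
        raise ValueError(f"band {band} has no Fourier support at n={n_samp}, fs={fs}")
    spec = np.zeros(shape + (n_samp,), dtype=complex)
    k = int(mask.sum())
    spec[..., mask] = rng.standard_normal(shape + (k,)) + 1j * rng.standard_normal(shape + (k,))
    z = np.fft.ifft(spec, axis=-1)
    rms = np.sqrt(np.mean(np.abs(z.real) ** 2, axis=-1, keepdims=True))
    return z / np.maximum(rms, 1e-30)


def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    return (times >= window[0]) & (times < window[1])


def _gate(times: np.ndarray, which: str) -> np.ndarray:
    if which == "both":
        return np.ones_like(times)
    return _window_mask(times, _WINDOWS[which]).astype(float)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], n_samp: int) -> np.ndarray:
    """1/f-shaped Gaussian noise with unit standard deviation."""
    white = rng.standard_normal(shape + (n_samp,))
    F = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samp)
    scale = 1.0 / np.sqrt(np.maximum(f, f[1]))
    pink = np.fft.irfft(F * scale, n=n_samp, axis=-1)
    return pink / pink.std()


def _synthesize_subject(spec: CohortSpec, idx: int, edge_s, erd_r) -> EpochSet:
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(idx, 0)))
    ch_names = spec.channel_names
    ch_index = {c: i for i, c in enumerate(ch_names)}
    n_samp = int(round((spec.epoch_window[1] - spec.epoch_window[0]) * spec.fs))
    times = spec.epoch_window[0] + np.arange(n_samp) / spec.fs
    shape = (spec.n_trials, spec.n_channels)

    data = spec.background_sd * rng.standard_normal(shape + (n_samp,))
    if spec.pink_sd > 0:
        data += spec.pink_sd * _pink_noise(rng, shape, n_samp)
    if spec.volume_conduction > 0:
        common = rng.standard_normal((spec.n_trials, n_samp))
        gains = rng.uniform(0.5, 1.5, size=spec.n_channels)
        data += spec.volume_conduction * gains[None, :, None] * common[:, None, :]

    band_edges = spec.band_edges
    for e, s in edge_s.items():
        if s <= 0:
            continue
        z = _narrowband_analytic(rng, (spec.n_trials,), n_samp, spec.fs, band_edges[e.band])
        env = _gate(times, e.window)
        amp = spec.edge_amplitude * s
        data[:, ch_index[e.ch_i], :] += amp * (z * env).real
        data[:, ch_index[e.ch_j], :] += amp * (z * np.exp(-1j * e.phase_lag) * env).real

    for eff, r in erd_r.items():
        band = band_edges[eff.band]
        ci = ch_index[eff.channel]
        z = _narrowband_analytic(rng, (spec.n_trials,), n_samp, spec.fs, band)
        osc = z.real
        pre_sl = _window_mask(times, PRE_WINDOW)
        post_sl = _window_mask(times, POST_WINDOW)
        bg_pre = float(band_power(data[:, [ci], :][:, :, pre_sl], spec.fs, band)[0])
        bg_post = float(band_power(data[:, [ci], :][:, :, post_sl], spec.fs, band)[0])
        u_pre = float(band_power(osc[:, None, pre_sl], spec.fs, band)[0])
        u_post = float(band_power(osc[:, None, post_sl], spec.fs, band)[0])
        a_pre = np.sqrt(spec.erd_snr * bg_pre / u_pre)
        target_post = r * (bg_pre + a_pre**2 * u_pre) - bg_post
        a_post = np.sqrt(max(target_post, 0.0) / u_post)
        # amplitude envelope: baseline level up to the cue, post level from
        # 0.25 s on, linear ramp across the movement-preparation gap
        env = np.full(n_samp, a_pre)
        ramp = (times >= 0.0) & (times < POST_WINDOW[0])
        env[times >= POST_WINDOW[0]] = a_post
        env[ramp] = a_pre + (a_post - a_pre) * (times[ramp] / POST_WINDOW[0])
        data[:, ci, :] += env * osc

    return EpochSet(
        data=data.astype(np.float32), fs=spec.fs, ch_names=ch_names, tmin=spec.epoch_window[0]
    )


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Synthesize every subject of the cohort (deterministic in spec.seed)."""
    records = []
    for idx in range(spec.n_subjects):
        sid, group, hand = _subject_meta(spec, idx)
        edge_s, erd_r = _subject_effects(spec, idx)
        feats = _truth_features(edge_s, erd_r)
        ul_fma = _outcome(spec, idx, feats)
        epochs = _synthesize_subject(spec, idx, edge_s, erd_r)
        records.append(
            SubjectRecord(subject_id=sid, group=group, hand=hand, ul_fma=ul_fma, epochs=epochs)
        )
    return records
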