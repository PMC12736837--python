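"""Synthetic SSVEP generator.

Trials are frequency-phase coded periodic responses: channel ``k`` of a
class-``c`` trial carries

    g_k * sum_{m=1..M} d^{m-1} * sin(2*pi*m*f_c*(t - latency) + m*phi_c)

for ``t >= latency`` (zero before; the visual system needs ~0.14 s to start
responding), embedded in pink+white background noise scaled to a requested
SNR. Harmonics at or above Nyquist are dropped. Channel gains follow a
posterior gradient so occipital channels dominate, mirroring where real
SSVEPs are strongest.

Default stimulus plans reproduce the two public benchmark codings: 40
frequencies 8.0-15.8 Hz in 0.2 Hz steps with phases advancing by 0.5*pi, and
the standard 12-target plan (9.25-14.75 Hz) with 0.5*pi phase steps per
frequency column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError
from .signal_io import (
    DATASET_II_CHANNELS,
    LAYOUT_I,
    LAYOUT_II,
    RawRecording,
    TrialSample,
    load_montage_64,
)

WHITE = "white"
PINK = "pink"
MIXED = "mixed"

#: stimulus onset within a trial, seconds, per layout convention
LAYOUT_STIM_ONSET_S = {LAYOUT_I: 0.5, LAYOUT_II: 0.15}


def dataset_i_plan() -> tuple[np.ndarray, np.ndarray]:
    """40-target frequency/phase coding: 8.0-15.8 Hz step 0.2, phases k*0.5*pi."""
    freqs = 8.0 + 0.2 * np.arange(40)
    phases = (0.5 * np.pi * np.arange(40)) % (2 * np.pi)
    return freqs, phases


def dataset_ii_plan() -> tuple[np.ndarray, np.ndarray]:
    """Standard 12-target plan: 9.25-14.75 Hz, phases 0, 0.5*pi, pi, 1.5*pi."""
    freqs = np.array(
        [9.25, 11.25, 13.25, 9.75, 11.75, 13.75, 10.25, 12.25, 14.25, 10.75, 12.75, 14.75]
    )
    phases = np.array([0.0, 0.0, 0.0, 0.5, 0.5, 0.5, 1.0, 1.0, 1.0, 1.5, 1.5, 1.5]) * np.pi
    return freqs, phases


def posterior_channel_gains(n_channels: int) -> np.ndarray:
    """Gain profile increasing toward occipital electrodes (last channels)."""
    return np.linspace(0.4, 1.0, n_channels)


@dataclass
class SynthConfig:
    """Stimulus plan plus signal/noise model for one synthetic dataset."""

    frequencies: np.ndarray
    phases: np.ndarray
    n_harmonics: int = 3
    harmonic_decay: float = 0.5
    channel_gains: np.ndarray = field(default_factory=lambda: posterior_channel_gains(9))
    snr_db: float = 0.0
    noise: str = MIXED
    fs: float = 250.0
    latency_s: float = 0.14
    seed: int = 0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.phases = np.asarray(self.phases, dtype=float)
        self.channel_gains = np.asarray(self.channel_gains, dtype=float)
        if self.frequencies.shape != self.phases.shape:
            raise ValueError("frequencies and phases must pair one-to-one")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if np.any(self.channel_gains < 0):
            raise ValueError("channel gains must be nonnegative")
        if self.noise not in (WHITE, PINK, MIXED):
            raise ValueError(f"unknown noise kind {self.noise!r}")

    @property
    def n_classes(self) -> int:
        return len(self.frequencies)

    @property
    def n_channels(self) -> int:
        return len(self.channel_gains)


def default_config(layout: str = LAYOUT_I, **kwargs) -> SynthConfig:
    """A SynthConfig mirroring one of the two benchmark protocols."""
    if layout == LAYOUT_I:
        freqs, phases = dataset_i_plan()
        base = dict(frequencies=freqs, phases=phases, fs=250.0,
                    channel_gains=posterior_channel_gains(9))
    elif layout == LAYOUT_II:
        freqs, phases = dataset_ii_plan()
        base = dict(frequencies=freqs, phases=phases, fs=256.0,
                    channel_gains=posterior_channel_gains(8))
    else:
        raise ValueError(f"unknown layout {layout!r}")
    base.update(kwargs)
    return SynthConfig(**base)


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def pink_noise(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """1/f-power noise via spectral shaping, unit variance per row."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** -0.5  # amplitude ~ f^-1/2 so power ~ 1/f
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def make_noise(rng: np.random.Generator, shape: tuple[int, ...], kind: str = MIXED) -> np.ndarray:
    """Background noise of unit-scale power; ``mixed`` is pink+white at 3:1 power."""
    if kind == WHITE:
        return rng.standard_normal(shape)
    if kind == PINK:
        return pink_noise(rng, shape)
    if kind == MIXED:
        p = pink_noise(rng, shape)
        w = rng.standard_normal(shape)
        return np.sqrt(0.75) * p + np.sqrt(0.25) * w
    raise ValueError(f"unknown noise kind {kind!r}")


def snr_scale(clean: np.ndarray, noise: np.ndarray, snr_db: float) -> np.ndarray:
    """Return ``clean + c * noise`` with c set so the realized SNR equals snr_db.

    SNR is mean-square power of ``clean`` over mean-square power of the scaled
    noise, in dB. ``snr_db = inf`` returns ``clean`` unchanged.
    """
    clean = np.asarray(clean, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if clean.shape != noise.shape:
        raise ValueError(f"shape mismatch: {clean.shape} vs {noise.shape}")
    if np.isinf(snr_db) and snr_db > 0:
        return clean.copy()
    p_clean = np.mean(clean**2)
    p_noise = np.mean(noise**2)
    if p_clean == 0:
        raise DegenerateInputError("all-zero clean signal with finite SNR requested")
    if p_noise == 0:
        raise DegenerateInputError("all-zero noise with finite SNR requested")
    c = np.sqrt(p_clean / (p_noise * 10.0 ** (snr_db / 10.0)))
    return clean + c * noise


# ---------------------------------------------------------------------------
# trials and recordings
# ---------------------------------------------------------------------------

def clean_trial(cfg: SynthConfig, class_idx: int, T: int, latency_s: float | None = None) -> np.ndarray:
    """Noise-free ``[C, T]`` response for one class (zero before latency)."""
    if not 0 <= class_idx < cfg.n_classes:
        raise IndexError(f"class {class_idx} out of range [0, {cfg.n_classes})")
    lat = cfg.latency_s if latency_s is None else latency_s
    f = cfg.frequencies[class_idx]
    phi = cfg.phases[class_idx]
    t = np.arange(T) / cfg.fs
    active = t >= lat
    wave = np.zeros(T)
    for m in range(1, cfg.n_harmonics + 1):
        if m * f >= cfg.fs / 2:
            break  # harmonic above Nyquist: dropped
        wave += cfg.harmonic_decay ** (m - 1) * np.sin(
            2 * np.pi * m * f * (t - lat) + m * phi
        )
    wave *= active
    return cfg.channel_gains[:, None] * wave[None, :]


def synth_trial(
    cfg: SynthConfig,
    class_idx: int,
    T: int,
    rng: np.random.Generator | None = None,
    latency_s: float | None = None,
    subject_id: str = "synthetic",
    block_id: int = 0,
) -> TrialSample:
    """One noisy ``[C, T]`` trial; reproducible from ``cfg.seed`` when no rng is given."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    clean = clean_trial(cfg, class_idx, T, latency_s)
    noise = make_noise(rng, clean.shape, cfg.noise)
    if np.all(cfg.channel_gains == 0):
        sig = noise  # pure background; SNR undefined
    else:
        sig = snr_scale(clean, noise, cfg.snr_db)
    return TrialSample(sig, class_idx, subject_id, block_id)


def synth_recording(
    cfg: SynthConfig,
    layout: str,
    n_blocks: int,
    trial_len_s: float,
    subject_id: str = "synthetic",
) -> RawRecording:
    """A full 4-D recording in the requested benchmark layout.

    Each (target, block) cell embeds a ``synth_trial`` whose response starts at
    the layout's stimulus onset (0.5 s or 0.15 s) plus ``cfg.latency_s``.
    """
    if layout not in LAYOUT_STIM_ONSET_S:
        raise ValueError(f"unknown layout {layout!r}")
    onset = LAYOUT_STIM_ONSET_S[layout]
    T = round(trial_len_s * cfg.fs)
    C, n_cls = cfg.n_channels, cfg.n_classes
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(n_cls * n_blocks)
    trials = np.empty((n_cls, n_blocks, C, T))
    for c in range(n_cls):
        for b in range(n_blocks):
            rng = np.random.default_rng(children[c * n_blocks + b])
            trials[c, b] = synth_trial(
                cfg, c, T, rng=rng, latency_s=onset + cfg.latency_s,
                subject_id=subject_id, block_id=b,
            ).signal
    if layout == LAYOUT_I:
        data = trials.transpose(2, 3, 0, 1)  # [C, T, targets, blocks]
    else:
        data = trials.transpose(0, 2, 3, 1)  # [targets, C, T, blocks]
    if layout == LAYOUT_I and C == 64:
        names = load_montage_64()
    elif layout == LAYOUT_II and C == 8:
        names = list(DATASET_II_CHANNELS)
    else:
        names = [f"ch{i}" for i in range(C)]
    return RawRecording(data, layout, cfg.fs, names, subject_id)
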