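"""Canonical-correlation baselines: plain CCA and filter-bank CCA (FBCCA).

CCA scores an EEG window ``X [C x T]`` against a bank of sinusoidal reference
templates ``Y_c [2H x T]`` (sine/cosine pairs at the first ``H`` harmonics of
class ``c``'s stimulation frequency); the decoded class maximizes the first
canonical correlation. FBCCA decomposes the window into ``n`` sub-bands
(here Butterworth band-passes ``[8n, 88]`` Hz, zero phase), computes the
correlation ``rho_n`` per sub-band, and combines them as

    score(c) = sum_n w(n) * rho_n(c)^2,      w(n) = n^-a + b

with the canonical weighting ``a = 1.25, b = 0.25``. Scores are invariant to
overall amplitude scaling of the trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.signal

from .signal_io import TrialSample


@dataclass
class ReferenceBank:
    """Per-class sinusoidal templates: list of ``[2H_c x T]`` row matrices."""

    templates: list[np.ndarray]
    fs: float
    n_harmonics: int
    frequencies: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_classes(self) -> int:
        return len(self.templates)


@dataclass
class FBConfig:
    """Filter-bank layout and sub-band weighting."""

    n_subbands: int = 5
    low_edges: tuple[float, ...] = (8.0, 16.0, 24.0, 32.0, 40.0)
    high_edge: float = 88.0
    weight_a: float = 1.25
    weight_b: float = 0.25
    filter_order: int = 4

    def __post_init__(self) -> None:
        if self.n_subbands < 1 or len(self.low_edges) < self.n_subbands:
            raise ValueError("need a low edge per sub-band")
        if any(lo >= self.high_edge for lo in self.low_edges[: self.n_subbands]):
            raise ValueError("every sub-band low edge must lie below the high edge")

    def weights(self) -> np.ndarray:
        n = np.arange(1, self.n_subbands + 1, dtype=float)
        return n**-self.weight_a + self.weight_b


def make_reference_bank(
    frequencies,
    phases=None,
    fs: float = 250.0,
    n_samples: int = 1000,
    n_harmonics: int = 5,
) -> ReferenceBank:
    """Sine/cosine harmonic templates; harmonic ``m`` advances the phase as
    ``m * phi`` (phase-locked harmonics). Harmonics at or above Nyquist are
    dropped; rows are centered and unit-normalized."""
    frequencies = np.asarray(frequencies, dtype=float)
    if phases is None:
        phases = np.zeros_like(frequencies)
    phases = np.asarray(phases, dtype=float)
    t = np.arange(n_samples) / fs
    templates = []
    for f, phi in zip(frequencies, phases):
        rows = []
        for m in range(1, n_harmonics + 1):
            if m * f >= fs / 2:
                break
            arg = 2 * np.pi * m * f * t + m * phi
            rows.append(np.sin(arg))
            rows.append(np.cos(arg))
        y = np.asarray(rows)
        y = y - y.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(y, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        templates.append(y / norms)
    return ReferenceBank(templates, fs, n_harmonics, frequencies)


def cca_corr(X: np.ndarray, Y: np.ndarray) -> float:
    """First canonical correlation between the row spaces of ``X`` and ``Y``.

    Rows are centered internally; computed via thin QR of the centered data
    matrices followed by an SVD of the cross product (numerically stable).
    Rank-deficient inputs are handled by dropping the deficient directions,
    with a warning; an all-zero side yields correlation 0.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"time axes differ: {X.shape[1]} vs {Y.shape[1]}")
    qs = []
    for M in (X, Y):
        A = (M - M.mean(axis=1, keepdims=True)).T  # [T, rows]
        q, r = np.linalg.qr(A)
        diag = np.abs(np.diag(r))
        tol = max(A.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
        keep = diag > tol
        if not np.all(keep):
            warnings.warn(
                "rank-deficient input to cca_corr; deficient directions dropped",
                RuntimeWarning,
                stacklevel=2,
            )
        if not np.any(keep):
            return 0.0
        qs.append(q[:, keep])
    s = np.linalg.svd(qs[0].T @ qs[1], compute_uv=False)
    return float(min(max(s[0], 0.0), 1.0))


def subband_filter(
    signal: np.ndarray, fs: float, low: float, high: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass used for the filter-bank decomposition."""
    high = min(high, 0.99 * fs / 2)
    sos = scipy.signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return scipy.signal.sosfiltfilt(sos, signal, axis=-1)


def fbcca_scores(trial: TrialSample | np.ndarray, bank: ReferenceBank, fb: FBConfig | None = None) -> np.ndarray:
    """Weighted sum of squared sub-band canonical correlations, per class."""
    fb = fb or FBConfig()
    sig = trial.signal if isinstance(trial, TrialSample) else np.asarray(trial, dtype=float)
    w = fb.weights()
    scores = np.zeros(bank.n_classes)
    for n in range(fb.n_subbands):
        filtered = subband_filter(sig, bank.fs, fb.low_edges[n], fb.high_edge, fb.filter_order)
        for c, y in enumerate(bank.templates):
            rho = cca_corr(filtered, y)
            scores[c] += w[n] * rho**2
    return scores


def fbcca_classify(trial: TrialSample | np.ndarray, bank: ReferenceBank, fb: FBConfig | None = None) -> int:
    """Argmax of the FBCCA score vector; ties break toward the lowest index."""
    return int(np.argmax(fbcca_scores(trial, bank, fb)))


def cca_classify(trial: TrialSample | np.ndarray, bank: ReferenceBank) -> int:
    """Plain CCA decoding (single band, no filter bank)."""
    sig = trial.signal if isinstance(trial, TrialSample) else np.asarray(trial, dtype=float)
    scores = [cca_corr(sig, y) for y in bank.templates]
    return int(np.argmax(scores))
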