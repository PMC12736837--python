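"""Readers and writers for multi-channel SSVEP EEG recordings and epochs.

Two public benchmark tensor layouts are supported natively:

* ``datasetI``  — per-subject array ``[channels, samples, targets, blocks]``,
  64 electrodes in an extended 10-20 montage, 250 Hz.
* ``datasetII`` — per-subject array ``[targets, channels, samples, blocks]``,
  8 occipital/parietal electrodes, 256 Hz.

Recordings travel on disk as MAT (v5) files; processed epochs use a small
HDF5 container (``/signals [n, C, T]``, ``/labels``, ``/subjects``,
``/blocks``; root attributes ``fs`` and ``layout``). All signal data is
held as 64-bit floats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import h5py
import numpy as np
import scipy.io

from .errors import LayoutError, ShapeError

LAYOUT_I = "datasetI"
LAYOUT_II = "datasetII"

#: axis roles per layout: (channel axis, sample axis, target axis, block axis)
LAYOUT_AXES = {
    LAYOUT_I: (0, 1, 2, 3),
    LAYOUT_II: (1, 2, 0, 3),
}

DATASET_I_FS = 250.0
DATASET_II_FS = 256.0

#: the 8 occipital/parietal electrodes of the 12-target dataset
DATASET_II_CHANNELS = ("PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2")


def load_montage_64() -> list[str]:
    """Return the bundled 64-electrode extended 10-20 channel order."""
    text = resources.files("ssvephybrid.data").joinpath("montage_64.txt").read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


@dataclass
class RawRecording:
    """A subject's full 4-D EEG tensor plus acquisition metadata.

    Parameters
    ----------
    data : ndarray
        4-D float array in the declared ``layout``.
    layout : str
        ``"datasetI"`` (``[C, S, targets, blocks]``) or ``"datasetII"``
        (``[targets, C, S, blocks]``).
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        Electrode labels, ordered along the channel axis.
    subject_id : str
    """

    data: np.ndarray
    layout: str
    fs: float
    channel_names: list[str] = field(default_factory=list)
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.layout not in LAYOUT_AXES:
            raise LayoutError(f"unknown layout {self.layout!r}")
        if self.data.ndim != 4:
            raise LayoutError(
                f"layout {self.layout} expects a 4-D array, got {self.data.ndim} axes "
                f"of shape {self.data.shape}"
            )
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_names) != self.n_channels:
            raise LayoutError(
                f"{self.n_channels} channels in data but {len(self.channel_names)} names"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")

    # -- axis accessors ----------------------------------------------------
    @property
    def channel_axis(self) -> int:
        return LAYOUT_AXES[self.layout][0]

    @property
    def sample_axis(self) -> int:
        return LAYOUT_AXES[self.layout][1]

    @property
    def target_axis(self) -> int:
        return LAYOUT_AXES[self.layout][2]

    @property
    def block_axis(self) -> int:
        return LAYOUT_AXES[self.layout][3]

    @property
    def n_channels(self) -> int:
        return self.data.shape[self.channel_axis]

    @property
    def n_samples(self) -> int:
        return self.data.shape[self.sample_axis]

    @property
    def n_targets(self) -> int:
        return self.data.shape[self.target_axis]

    @property
    def n_blocks(self) -> int:
        return self.data.shape[self.block_axis]


@dataclass
class TrialSample:
    """One ``[C, T]`` epoch with its class label and provenance."""

    signal: np.ndarray
    label: int
    subject_id: str = "unknown"
    block_id: int = 0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ShapeError(f"trial signal must be [C, T], got shape {self.signal.shape}")
        c, t = self.signal.shape
        if c < 1 or t < 1:
            raise ShapeError(f"trial signal must be non-empty, got shape {self.signal.shape}")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("trial contains non-finite values")
        if self.label < 0:
            raise ValueError(f"label must be a nonnegative class index, got {self.label}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


# ---------------------------------------------------------------------------
# MAT recordings
# ---------------------------------------------------------------------------

def _pick_4d_variable(contents: dict, var_name: str | None) -> np.ndarray:
    if var_name is not None:
        if var_name not in contents:
            raise LayoutError(f"variable {var_name!r} not found in MAT file")
        arr = np.asarray(contents[var_name])
        if arr.ndim != 4:
            raise LayoutError(f"variable {var_name!r} has {arr.ndim} axes, expected 4")
        return arr
    candidates = {
        k: np.asarray(v)
        for k, v in contents.items()
        if not k.startswith("__") and np.asarray(v).ndim == 4
    }
    if len(candidates) != 1:
        raise LayoutError(
            f"expected exactly one 4-D variable in MAT file, found {sorted(candidates)}"
        )
    return next(iter(candidates.values()))


def read_dataset_i(
    path,
    var_name: str | None = None,
    channel_names: Sequence[str] | None = None,
    subject_id: str = "unknown",
) -> RawRecording:
    """Read a 40-target benchmark recording: ``[64, S, targets, blocks]`` at 250 Hz.

    The MAT variable name is not standardized; by default the unique 4-D array
    in the file is used. Channel names default to the bundled 64-electrode
    extended 10-20 montage.
    """
    arr = _pick_4d_variable(scipy.io.loadmat(path), var_name)
    if arr.shape[0] != 64:
        raise LayoutError(
            f"dataset-I layout expects 64 channels on axis 0, found shape {arr.shape}"
        )
    names = list(channel_names) if channel_names is not None else load_montage_64()
    return RawRecording(arr, LAYOUT_I, DATASET_I_FS, names, subject_id)


def read_dataset_ii(
    path,
    var_name: str | None = None,
    channel_names: Sequence[str] | None = None,
    subject_id: str = "unknown",
) -> RawRecording:
    """Read a 12-target recording: ``[targets, 8, S, blocks]`` at 256 Hz."""
    arr = _pick_4d_variable(scipy.io.loadmat(path), var_name)
    if arr.shape[1] != 8:
        raise LayoutError(
            f"dataset-II layout expects 8 channels on axis 1, found shape {arr.shape}"
        )
    names = list(channel_names) if channel_names is not None else list(DATASET_II_CHANNELS)
    return RawRecording(arr, LAYOUT_II, DATASET_II_FS, names, subject_id)


def write_recording(rec: RawRecording, path, var_name: str = "data") -> None:
    """Write a recording's tensor as a MAT v5 file (values stored bit-exactly)."""
    scipy.io.savemat(path, {var_name: rec.data})


def read_recording(path, layout: str, **kwargs) -> RawRecording:
    """Dispatch to the layout-specific reader."""
    if layout == LAYOUT_I:
        return read_dataset_i(path, **kwargs)
    if layout == LAYOUT_II:
        return read_dataset_ii(path, **kwargs)
    raise LayoutError(f"unknown layout {layout!r}")


# ---------------------------------------------------------------------------
# HDF5 epoch container
# ---------------------------------------------------------------------------

def write_epochs(samples: list[TrialSample], path, fs: float = 0.0, layout: str = "") -> None:
    """Write a homogeneous list of epochs to the HDF5 container.

    All samples must share ``[C, T]``; labels, subject ids and block ids are
    preserved. An empty list writes an empty container.
    """
    if samples:
        c, t = samples[0].signal.shape
        for s in samples:
            if s.signal.shape != (c, t):
                raise ShapeError(
                    f"heterogeneous epoch shapes: {s.signal.shape} vs {(c, t)}"
                )
        signals = np.stack([s.signal for s in samples])
    else:
        signals = np.zeros((0, 0, 0))
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=signals)
        f.create_dataset("labels", data=np.array([s.label for s in samples], dtype=np.int64))
        f.create_dataset(
            "subjects",
            data=np.array([s.subject_id for s in samples], dtype=h5py.string_dtype()),
        )
        f.create_dataset("blocks", data=np.array([s.block_id for s in samples], dtype=np.int64))
        f.attrs["fs"] = float(fs)
        f.attrs["layout"] = layout


def read_epochs(path) -> tuple[list[TrialSample], float, str]:
    """Read the HDF5 epoch container back to ``(samples, fs, layout)``."""
    with h5py.File(path, "r") as f:
        signals = f["signals"][...]
        labels = f["labels"][...]
        subjects = [s.decode() if isinstance(s, bytes) else str(s) for s in f["subjects"][...]]
        blocks = f["blocks"][...]
        fs = float(f.attrs["fs"])
        layout = str(f.attrs["layout"])
    samples = [
        TrialSample(signals[i], int(labels[i]), subjects[i], int(blocks[i]))
        for i in range(len(labels))
    ]
    return samples, fs, layout
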