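"""Spatiotemporal CNN classification head.

Layer plan for an input plane of ``C`` electrode rows by ``L`` time columns:

* spatial block — ``C x 1`` convolution with ``C`` filters (+ batch norm,
  ELU), collapsing the electrode axis to learn inter-channel synchronicity;
* temporal block 1 — ``1 x 4`` convolution, ``2C`` filters, batch norm, ELU,
  ``1 x 2`` max pool;
* temporal block 2 — ``1 x 2`` convolution, ``2C`` filters, batch norm, ELU,
  ``1 x 2`` max pool;
* classification head — flatten, then fully connected 512 -> 128 -> N with
  ReLU between; the softmax lives in the cross-entropy loss.

Convolutions are "valid" (no padding), stride 1; pools are non-overlapping.
With those conventions the flattened width follows the closed form
``2C * floor((floor((L - 3) / 2) - 1) / 2)`` and is checked at build time.

In hybrid mode the input is the ``[C, Nh]`` RBM feature map; the CNN-only
ablation consumes the raw ``[C, T]`` window directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ArchitectureError, ShapeError


@dataclass
class CNNConfig:
    """Geometry of the classifier; defaults follow the reference layer table."""

    n_channels: int
    feature_len: int
    n_classes: int
    temporal_kernels: tuple[int, int] = (4, 2)
    pool: int = 2
    fc_dims: tuple[int, int] = (512, 128)

    def __post_init__(self) -> None:
        if min(self.n_channels, self.feature_len, self.n_classes) < 1:
            raise ValueError("all dimensions must be positive")


def conv_pool_length(length: int, kernels: tuple[int, ...], pool: int) -> int:
    """Time-axis length after the valid-conv + pool cascade; raises if impossible."""
    for k in kernels:
        length = length - k + 1
        if length < 1:
            raise ArchitectureError(f"kernel {k} does not fit in length {length + k - 1}")
        length //= pool
        if length < 1:
            raise ArchitectureError(f"pool {pool} empties the feature map")
    return length


def flatten_length(cfg: CNNConfig) -> int:
    """Width of the flattened tensor entering the first FC layer."""
    return 2 * cfg.n_channels * conv_pool_length(cfg.feature_len, cfg.temporal_kernels, cfg.pool)


def min_feature_len(kernels: tuple[int, ...] = (4, 2), pool: int = 2) -> int:
    """Smallest input length the conv/pool cascade admits."""
    length = 1
    while True:
        try:
            conv_pool_length(length, kernels, pool)
            return length
        except ArchitectureError:
            length += 1


def build_model(cfg: CNNConfig, seed: int = 0) -> nn.Sequential:
    """Construct the network with seeded (hence reproducible) initialization."""
    try:
        flat = flatten_length(cfg)
    except ArchitectureError as exc:
        raise ArchitectureError(
            f"feature_len={cfg.feature_len} too short for kernels "
            f"{cfg.temporal_kernels} and pool {cfg.pool}; minimum admissible length "
            f"is {min_feature_len(cfg.temporal_kernels, cfg.pool)}"
        ) from exc
    rng = np.random.default_rng(seed)
    c = cfg.n_channels
    k1, k2 = cfg.temporal_kernels
    d1, d2 = cfg.fc_dims
    return nn.Sequential(
        [
            nn.ChannelConv(c, c, rng),
            nn.BatchNorm(c),
            nn.ELU(),
            nn.TemporalConv(c, 2 * c, k1, rng),
            nn.BatchNorm(2 * c),
            nn.ELU(),
            nn.MaxPool(cfg.pool),
            nn.TemporalConv(2 * c, 2 * c, k2, rng),
            nn.BatchNorm(2 * c),
            nn.ELU(),
            nn.MaxPool(cfg.pool),
            nn.Flatten(),
            nn.Linear(flat, d1, rng),
            nn.ReLU(),
            nn.Linear(d1, d2, rng),
            nn.ReLU(),
            nn.Linear(d2, cfg.n_classes, rng),
        ]
    )


def build_fc_head(cfg: CNNConfig, seed: int = 0) -> nn.Sequential:
    """Fully connected head only (flatten -> 512 -> 128 -> N), no convolutions.

    Used by the feature-extractor-only ablation, which classifies the flattened
    RBM feature map with a plain feed-forward network.
    """
    rng = np.random.default_rng(seed)
    d1, d2 = cfg.fc_dims
    flat = cfg.n_channels * cfg.feature_len
    return nn.Sequential(
        [
            nn.Flatten(),
            nn.Linear(flat, d1, rng),
            nn.ReLU(),
            nn.Linear(d1, d2, rng),
            nn.ReLU(),
            nn.Linear(d2, cfg.n_classes, rng),
        ]
    )


def _as_batch(features: np.ndarray) -> np.ndarray:
    features = np.asarray(features, dtype=float)
    if features.ndim == 2:
        features = features[None]
    if features.ndim != 3:
        raise ShapeError(f"expected [C, L] or [N, C, L], got shape {features.shape}")
    return features


def forward(model: nn.Sequential, features: np.ndarray) -> np.ndarray:
    """Eval-mode logits for one ``[C, L]`` input (or a ``[N, C, L]`` batch)."""
    x = _as_batch(features)
    logits = model.forward(x, train=False)
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite logits")
    return logits[0] if np.asarray(features).ndim == 2 else logits


def class_probabilities(model: nn.Sequential, features: np.ndarray) -> np.ndarray:
    return nn.softmax(forward(model, features))


def predict(model: nn.Sequential, features: np.ndarray):
    """Argmax class index; exact ties break toward the lowest index."""
    logits = forward(model, features)
    return int(np.argmax(logits)) if logits.ndim == 1 else np.argmax(logits, axis=1)
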