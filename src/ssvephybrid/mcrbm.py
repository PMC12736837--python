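"""Multi-channel Gaussian-Bernoulli restricted Boltzmann machine.

One RBM per EEG channel, with the weight matrix ``W [Nv x Nh]`` and biases
``a [Nv]`` (visible), ``b [Nh]`` (hidden) shared across all ``Nc`` channels.
Visible units are real-valued with unit conditional variance; hidden units are
binary. The energy of a joint configuration ``(v, h)`` with ``v [Nc x Nv]``
and ``h [Nc x Nh]`` is

    E(v, h) = sum_{k,i} v_ki^2 / 2  -  sum_{k,i,j} v_ki w_ij h_kj
              - sum_{k,j} b_j h_kj  -  sum_{k,i} a_i v_ki

which factorizes over channels, so the conditionals are per-channel:
``P(h_kj = 1 | v) = sigmoid(sum_i w_ij v_ki + b_j)`` and
``v_ki | h ~ Normal(sum_j w_ij h_kj + a_i, 1)``.

Training is contrastive divergence: the gradient statistics are averaged over
the channel axis (factor 1/Nc) and the mini-batch. Because the model assumes
unit-scale Gaussian visibles, inputs are standardized per channel before
entering the RBM.

For verification, the module carries exact oracles usable at small ``Nh``:
the log-likelihood (closed-form Gaussian integral + enumeration over the
2^Nh hidden configurations), its parameter gradient, and the exact hidden
marginals of the Boltzmann distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.special

from .errors import ShapeError
from .signal_io import TrialSample


def sigmoid(x: np.ndarray) -> np.ndarray:
    return scipy.special.expit(x)


def standardize_channels(x: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Per-channel (last-axis) zero-mean unit-variance scaling."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    return (x - mu) / (sd + eps)


@dataclass
class MCRBMParams:
    """Shared weights and biases: ``W [Nv x Nh]``, ``a [Nv]``, ``b [Nh]``."""

    W: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        nv, nh = self.W.shape
        if self.a.shape != (nv,) or self.b.shape != (nh,):
            raise ShapeError(
                f"bias shapes {self.a.shape}, {self.b.shape} inconsistent with W {self.W.shape}"
            )
        for arr in (self.W, self.a, self.b):
            if not np.all(np.isfinite(arr)):
                raise ValueError("parameters contain non-finite values")

    @property
    def nv(self) -> int:
        return self.W.shape[0]

    @property
    def nh(self) -> int:
        return self.W.shape[1]

    @classmethod
    def init(cls, nv: int, nh: int, scale: float = 0.01, seed: int = 0) -> "MCRBMParams":
        rng = np.random.default_rng(seed)
        return cls(scale * rng.standard_normal((nv, nh)), np.zeros(nv), np.zeros(nh))

    def copy(self) -> "MCRBMParams":
        return MCRBMParams(self.W.copy(), self.a.copy(), self.b.copy())


@dataclass
class CDConfig:
    """Contrastive-divergence training schedule.

    ``k_steps=1`` with mean-field visible reconstruction is the default; set
    ``sample_visible=True`` to draw the Gaussian visible conditional at each
    step (needed when the negative chain must actually sample the model, e.g.
    long-chain gradient estimation).
    """

    learning_rate: float = 1e-3
    k_steps: int = 1
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0
    init_scale: float = 0.01
    sample_visible: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning rate must be nonnegative")
        if self.k_steps < 1:
            raise ValueError("k_steps must be >= 1")


# ---------------------------------------------------------------------------
# energy and conditionals
# ---------------------------------------------------------------------------

def _check_state(params: MCRBMParams, v: np.ndarray, h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    v = np.atleast_2d(np.asarray(v, dtype=float))
    h = np.atleast_2d(np.asarray(h, dtype=float))
    if v.shape[1] != params.nv or h.shape[1] != params.nh or v.shape[0] != h.shape[0]:
        raise ShapeError(
            f"state shapes v{v.shape}, h{h.shape} inconsistent with "
            f"W [{params.nv} x {params.nh}]"
        )
    return v, h


def energy(params: MCRBMParams, v: np.ndarray, h: np.ndarray) -> float:
    """Joint energy of ``(v, h)``; additive over the channel axis."""
    v, h = _check_state(params, v, h)
    quad = 0.5 * np.sum(v**2)
    inter = np.sum((v @ params.W) * h)
    return float(quad - inter - np.sum(h @ params.b) - np.sum(v @ params.a))


def hidden_conditional(params: MCRBMParams, v: np.ndarray) -> np.ndarray:
    """``P(h_kj = 1 | v)`` per channel: sigmoid(v W + b)."""
    v = np.atleast_2d(np.asarray(v, dtype=float))
    return sigmoid(v @ params.W + params.b)


def visible_conditional_mean(params: MCRBMParams, h: np.ndarray) -> np.ndarray:
    """Mean of the unit-variance Gaussian visible conditional: h W^T + a."""
    h = np.atleast_2d(np.asarray(h, dtype=float))
    return h @ params.W.T + params.a


def sample_hidden(params: MCRBMParams, v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    p = hidden_conditional(params, v)
    return (rng.random(p.shape) < p).astype(float)


def sample_visible(params: MCRBMParams, h: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    mu = visible_conditional_mean(params, h)
    return mu + rng.standard_normal(mu.shape)


# ---------------------------------------------------------------------------
# contrastive divergence
# ---------------------------------------------------------------------------

def _moments(v: np.ndarray, ph: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sufficient statistics averaged over batch and channel axes."""
    n = v.shape[0] * v.shape[1]
    dw = np.einsum("bki,bkj->ij", v, ph) / n
    da = v.mean(axis=(0, 1))
    db = ph.mean(axis=(0, 1))
    return dw, da, db


def cd_update(
    params: MCRBMParams,
    batch: np.ndarray,
    cfg: CDConfig,
    rng: np.random.Generator,
) -> tuple[MCRBMParams, dict]:
    """One CD-k parameter update on a ``[B, Nc, Nv]`` batch.

    Positive statistics use the data with hidden probabilities; the negative
    chain samples the hidden units and reconstructs visibles as the conditional
    mean (or a Gaussian draw when ``cfg.sample_visible``). Negative statistics
    use the final visibles with hidden probabilities. Statistics carry the
    1/Nc channel average and the batch average.
    """
    batch = np.asarray(batch, dtype=float)
    if batch.ndim == 2:
        batch = batch[None]
    if batch.ndim != 3 or batch.shape[0] == 0:
        raise ValueError(f"batch must be nonempty [B, Nc, Nv], got shape {batch.shape}")
    if batch.shape[2] != params.nv:
        raise ShapeError(f"batch Nv={batch.shape[2]} does not match W Nv={params.nv}")

    v0 = batch
    ph0 = hidden_conditional(params, v0)
    h = (rng.random(ph0.shape) < ph0).astype(float)
    vk = v0
    for _ in range(cfg.k_steps):
        mu = visible_conditional_mean(params, h)
        vk = mu + rng.standard_normal(mu.shape) if cfg.sample_visible else mu
        phk = hidden_conditional(params, vk)
        h = (rng.random(phk.shape) < phk).astype(float)
    phk = hidden_conditional(params, vk)

    pos = _moments(v0, ph0)
    neg = _moments(vk, phk)
    lr = cfg.learning_rate
    new = MCRBMParams(
        params.W + lr * (pos[0] - neg[0]),
        params.a + lr * (pos[1] - neg[1]),
        params.b + lr * (pos[2] - neg[2]),
    )
    stats = {
        "recon_error": float(np.mean((v0 - vk) ** 2)),
        "dW_norm": float(np.linalg.norm(pos[0] - neg[0])),
        "grad_W": pos[0] - neg[0],
        "grad_a": pos[1] - neg[1],
        "grad_b": pos[2] - neg[2],
    }
    return new, stats


def pretrain(
    data: np.ndarray,
    n_hidden: int,
    cfg: CDConfig | None = None,
) -> tuple[MCRBMParams, list[float]]:
    """CD training over epochs of shuffled mini-batches.

    ``data`` is ``[n_trials, Nc, Nv]`` (already standardized). Returns the
    trained parameters and the per-epoch mean reconstruction error.
    """
    cfg = cfg or CDConfig()
    data = np.asarray(data, dtype=float)
    n, _, nv = data.shape
    params = MCRBMParams.init(nv, n_hidden, cfg.init_scale, cfg.seed)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    history: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        errs = []
        for start in range(0, n, cfg.batch_size):
            batch = data[order[start : start + cfg.batch_size]]
            params, stats = cd_update(params, batch, cfg, rng)
            errs.append(stats["recon_error"])
        history.append(float(np.mean(errs)))
    return params, history


def extract_features(
    params: MCRBMParams, trial: TrialSample | np.ndarray, standardize: bool = True
) -> np.ndarray:
    """Deterministic ``[C, Nh]`` feature map: hidden probabilities per channel."""
    sig = trial.signal if isinstance(trial, TrialSample) else np.asarray(trial, dtype=float)
    if sig.shape[1] != params.nv:
        raise ShapeError(
            f"trial length T={sig.shape[1]} must equal visible size Nv={params.nv}"
        )
    if standardize:
        sig = standardize_channels(sig)
    return hidden_conditional(params, sig)


# ---------------------------------------------------------------------------
# exact oracles (small Nh)
# ---------------------------------------------------------------------------

MAX_EXACT_NH = 12


def _enumerate_hidden(nh: int) -> np.ndarray:
    """All 2^nh binary hidden configurations as a ``[2^nh, nh]`` array."""
    if nh > MAX_EXACT_NH:
        raise ValueError(f"exact enumeration limited to Nh <= {MAX_EXACT_NH}, got {nh}")
    return ((np.arange(2**nh)[:, None] >> np.arange(nh)) & 1).astype(float)


def _hidden_log_weights(params: MCRBMParams) -> tuple[np.ndarray, np.ndarray]:
    """log of the marginal weight of each hidden configuration (visibles integrated)."""
    hs = _enumerate_hidden(params.nh)
    mu = hs @ params.W.T + params.a  # [M, Nv]
    lw = hs @ params.b + 0.5 * np.sum(mu**2, axis=1)
    return hs, lw


def exact_log_partition(params: MCRBMParams, n_channels: int = 1) -> float:
    """log Z = Nc * [ (Nv/2) log 2pi + logsumexp_h (b.h + ||W h + a||^2 / 2) ]."""
    _, lw = _hidden_log_weights(params)
    single = 0.5 * params.nv * np.log(2 * np.pi) + scipy.special.logsumexp(lw)
    return float(n_channels * single)


def exact_log_likelihood(params: MCRBMParams, v: np.ndarray) -> float:
    """log p(v) by enumerating hidden configurations (requires small Nh)."""
    v = np.atleast_2d(np.asarray(v, dtype=float))
    if v.shape[1] != params.nv:
        raise ShapeError(f"v has Nv={v.shape[1]}, params have Nv={params.nv}")
    nc = v.shape[0]
    # unnormalized per-channel log marginal: -||v||^2/2 + a.v + sum_j softplus(v.w_j + b_j)
    act = v @ params.W + params.b
    log_pstar = (
        -0.5 * np.sum(v**2, axis=1)
        + v @ params.a
        + np.sum(np.logaddexp(0.0, act), axis=1)
    )
    return float(np.sum(log_pstar) - exact_log_partition(params, nc))


def exact_hidden_marginals(params: MCRBMParams) -> np.ndarray:
    """Exact marginal ``P(h_j = 1)`` under the model, per hidden unit (one channel)."""
    hs, lw = _hidden_log_weights(params)
    p = np.exp(lw - scipy.special.logsumexp(lw))
    return p @ hs


def exact_log_likelihood_grad(
    params: MCRBMParams, v: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact gradient of mean log p(v) w.r.t. (W, a, b).

    ``v`` is ``[Nc, Nv]`` (or ``[B, Nc, Nv]``); statistics carry the same
    1/(B*Nc) averaging as the CD update, so directions are directly comparable.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim == 2:
        v = v[None]
    b_, nc, nv = v.shape
    flat = v.reshape(-1, nv)
    ph = hidden_conditional(params, flat)
    n = flat.shape[0]
    pos_w = flat.T @ ph / n
    pos_a = flat.mean(axis=0)
    pos_b = ph.mean(axis=0)

    hs, lw = _hidden_log_weights(params)
    p = np.exp(lw - scipy.special.logsumexp(lw))  # model dist over hidden configs
    mu = hs @ params.W.T + params.a  # E[v | h]
    neg_w = np.einsum("m,mi,mj->ij", p, mu, hs)
    neg_a = p @ mu
    neg_b = p @ hs
    return pos_w - neg_w, pos_a - neg_a, pos_b - neg_b


# ---------------------------------------------------------------------------
# Gibbs sampling (diagnostics)
# ---------------------------------------------------------------------------

def gibbs_chain_hidden_samples(
    params: MCRBMParams,
    n_sweeps: int,
    seed: int = 0,
    burn_in: int = 1000,
) -> np.ndarray:
    """Binary hidden samples ``[n_sweeps, Nh]`` from a long alternating Gibbs
    chain (one channel), after burn-in.

    Both conditionals are sampled (Bernoulli hidden, Gaussian visible), so the
    chain's stationary law is the model's Boltzmann distribution. Successive
    sweeps are autocorrelated; uncertainty on chain averages should use a
    batch-means standard error, not the independent-sample formula.
    """
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((1, params.nv))
    out = np.empty((n_sweeps, params.nh))
    for sweep in range(n_sweeps + burn_in):
        h = sample_hidden(params, v, rng)
        v = sample_visible(params, h, rng)
        if sweep >= burn_in:
            out[sweep - burn_in] = h[0]
    return out


def gibbs_chain_hidden_marginals(
    params: MCRBMParams, n_sweeps: int, seed: int = 0, burn_in: int = 1000
) -> np.ndarray:
    """Empirical ``P(h_j = 1)`` over a long Gibbs chain (one channel)."""
    return gibbs_chain_hidden_samples(params, n_sweeps, seed, burn_in).mean(axis=0)


def batch_means_se(samples: np.ndarray, n_batches: int = 50) -> np.ndarray:
    """Standard error of the chain mean by the method of batch means.

    Splits the chain into ``n_batches`` contiguous batches; the variance of
    the batch means absorbs the chain's autocorrelation.
    """
    n = samples.shape[0] // n_batches
    means = samples[: n * n_batches].reshape(n_batches, n, -1).mean(axis=1)
    return means.std(axis=0, ddof=1) / np.sqrt(n_batches)


# ---------------------------------------------------------------------------
# parameter container I/O
# ---------------------------------------------------------------------------

def save_params(params: MCRBMParams, path) -> None:
    np.savez(path, W=params.W, a=params.a, b=params.b)


def load_params(path) -> MCRBMParams:
    with np.load(path) as f:
        return MCRBMParams(f["W"], f["a"], f["b"])
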