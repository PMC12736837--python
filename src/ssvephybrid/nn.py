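"""Minimal feed-forward neural-network engine in numpy.

Layers operate on float64 arrays, keep their parameters and gradient buffers
as parallel lists, and implement explicit ``forward``/``backward`` passes.
Signal tensors are ``[N, F, L]`` (batch, feature maps, time) for the
convolutional stages and ``[N, D]`` after flattening; the "spatial" stage of
the classifier collapses the electrode axis, so all later convolutions are
1-D along time and no 4-D tensors are needed.

Gradient correctness is verified against central finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np

from .errors import ShapeError


class Layer:
    """Base layer: parameter/gradient lists plus forward/backward."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class ChannelConv(Layer):
    """Spatial convolution with a ``C x 1`` kernel: collapses the electrode axis.

    Input ``[N, C, L]`` -> output ``[N, F, L]`` with
    ``out[n, f, t] = sum_c W[f, c] x[n, c, t] + b[f]``.
    """

    def __init__(self, in_channels: int, filters: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.W = _glorot(rng, (filters, in_channels), in_channels, filters)
        self.b = np.zeros(filters)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return np.einsum("fc,ncl->nfl", self.W, x) + self.b[None, :, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.grads[0] += np.einsum("nfl,ncl->fc", gout, self._x)
        self.grads[1] += gout.sum(axis=(0, 2))
        return np.einsum("fc,nfl->ncl", self.W, gout)


class TemporalConv(Layer):
    """Valid 1-D convolution along time: ``[N, G, L] -> [N, F, L - K + 1]``."""

    def __init__(self, in_maps: int, filters: int, kernel: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.kernel = kernel
        fan_in, fan_out = in_maps * kernel, filters * kernel
        self.W = _glorot(rng, (filters, in_maps, kernel), fan_in, fan_out)
        self.b = np.zeros(filters)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k = self.kernel
        if x.shape[2] < k:
            raise ShapeError(f"input length {x.shape[2]} shorter than kernel {k}")
        xw = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)  # [N, G, Lout, K]
        self._xw = xw
        return np.einsum("fgk,nglk->nfl", self.W, xw) + self.b[None, :, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        k = self.kernel
        self.grads[0] += np.einsum("nfl,nglk->fgk", gout, self._xw)
        self.grads[1] += gout.sum(axis=(0, 2))
        gp = np.pad(gout, ((0, 0), (0, 0), (k - 1, k - 1)))
        gw = np.lib.stride_tricks.sliding_window_view(gp, k, axis=2)  # [N, F, Lin, K]
        return np.einsum("fgk,nflk->ngl", self.W[:, :, ::-1], gw)


class BatchNorm(Layer):
    """Batch normalization over batch and time axes, per feature map.

    Accepts ``[N, F, L]`` (normalizes over axes 0 and 2) or ``[N, D]``
    (over axis 0). Running statistics (momentum 0.1) are used in eval mode, so
    eval-mode outputs are independent of batch composition.
    """

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def _axes(self, x: np.ndarray) -> tuple[int, ...]:
        return (0, 2) if x.ndim == 3 else (0,)

    def _expand(self, v: np.ndarray, ndim: int) -> np.ndarray:
        return v[None, :, None] if ndim == 3 else v[None, :]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = self._axes(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        e = lambda v: self._expand(v, x.ndim)
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - e(mean)) * e(self._inv_std)
        self._train = train
        self._n = int(np.prod([x.shape[ax] for ax in axes]))
        return e(self.gamma) * self._xhat + e(self.beta)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        axes = self._axes(gout)
        e = lambda v: self._expand(v, gout.ndim)
        self.grads[0] += np.sum(gout * self._xhat, axis=axes)
        self.grads[1] += np.sum(gout, axis=axes)
        gxhat = gout * e(self.gamma)
        if not self._train:
            return gxhat * e(self._inv_std)
        n = self._n
        return (
            e(self._inv_std)
            / n
            * (
                n * gxhat
                - e(np.sum(gxhat, axis=axes))
                - self._xhat * e(np.sum(gxhat * self._xhat, axis=axes))
            )
        )


class ELU(Layer):
    def __init__(self, alpha: float = 1.0) -> None:
        super().__init__()
        self.alpha = alpha

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return np.where(x > 0, x, self.alpha * np.expm1(x))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * np.where(self._x > 0, 1.0, self.alpha * np.exp(self._x))


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask


class MaxPool(Layer):
    """Non-overlapping 1-D max pooling along time (floor division of length)."""

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, f, l = x.shape
        lo = l // self.size
        if lo < 1:
            raise ShapeError(f"length {l} too short for pool size {self.size}")
        xt = x[:, :, : lo * self.size].reshape(n, f, lo, self.size)
        self._idx = xt.argmax(axis=3)
        self._in_shape = x.shape
        return np.take_along_axis(xt, self._idx[..., None], axis=3)[..., 0]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, f, lo = gout.shape
        gx = np.zeros(self._in_shape)
        gt = gx[:, :, : lo * self.size].reshape(n, f, lo, self.size)
        np.put_along_axis(gt, self._idx[..., None], gout[..., None], axis=3)
        return gx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.W = _glorot(rng, (d_in, d_out), d_in, d_out)
        self.b = np.zeros(d_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.grads[0] += self._x.T @ gout
        self.grads[1] += gout.sum(axis=0)
        return gout @ self.W.T


class SigmoidFeature(Layer):
    """Shared-weight per-channel sigmoid feature map: ``[N, C, Nv] -> [N, C, Nh]``.

    This is the deterministic hidden-probability map of a Gaussian-Bernoulli
    RBM, exposed as a differentiable layer so the whole stack can be
    fine-tuned end-to-end after unsupervised pretraining.
    """

    def __init__(self, W: np.ndarray, b: np.ndarray) -> None:
        super().__init__()
        self.W = np.array(W, dtype=float)
        self.b = np.array(b, dtype=float)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[-1] != self.W.shape[0]:
            raise ShapeError(
                f"input length {x.shape[-1]} must equal visible size {self.W.shape[0]}"
            )
        self._x = x
        z = x @ self.W + self.b
        self._y = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
        return self._y

    def backward(self, gout: np.ndarray) -> np.ndarray:
        gz = gout * self._y * (1.0 - self._y)  # [N, C, Nh]
        self.grads[0] += np.einsum("ncv,nch->vh", self._x, gz)
        self.grads[1] += gz.sum(axis=(0, 1))
        return np.einsum("vh,nch->ncv", self.W, gz)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    @property
    def all_params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def all_grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.all_params))

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name->array map of all parameters and batch-norm statistics."""
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                out[f"layer{i}_param{j}"] = p
            if isinstance(layer, BatchNorm):
                out[f"layer{i}_running_mean"] = layer.running_mean
                out[f"layer{i}_running_var"] = layer.running_var
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                p[...] = arrays[f"layer{i}_param{j}"]
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = arrays[f"layer{i}_running_mean"]
                layer.running_var[...] = arrays[f"layer{i}_running_var"]


# ---------------------------------------------------------------------------
# loss and optimizer
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = -float(np.mean(np.log(p[np.arange(n), labels] + eps)))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Adam:
    """Adam optimizer over (param, grad) buffer pairs updated in place."""

    def __init__(
        self,
        params: list[np.ndarray],
        grads: list[np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        if len(params) != len(grads):
            raise ValueError("params and grads must pair one-to-one")
        self.params = params
        self.grads = grads
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g**2
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def fit(
    model: Sequential,
    x: np.ndarray,
    y: np.ndarray,
    epochs: int,
    batch_size: int,
    lr: float,
    seed: int = 0,
    trainable: list[Layer] | None = None,
) -> list[float]:
    """Mini-batch Adam training with cross-entropy loss.

    ``trainable`` restricts the optimizer to a subset of layers (the gradients
    of all layers are still computed during backprop). Returns per-epoch mean
    loss; ``epochs=0`` leaves the model untouched.
    """
    layers = trainable if trainable is not None else model.layers
    params = [p for layer in layers for p in layer.params]
    grads = [g for layer in layers for g in layer.grads]
    opt = Adam(params, grads, lr=lr)
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    history: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            model.zero_grad()
            logits = model.forward(x[idx], train=True)
            loss, dlogits = cross_entropy(logits, y[idx])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history
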