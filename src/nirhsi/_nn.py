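"""Minimal numpy neural-net core used by the autoencoder and classifier.

Implements exactly the pieces the pipeline's training recipes need —
dense and valid-convolution layers (2 or 3 spatial dims via im2col),
batch normalization, ReLU/ELU/GELU, inverted dropout, a softmax feature
attention gate, Adam/AdamW with decoupled weight decay, cosine-annealing
schedules, global-norm gradient clipping, and cross-entropy with label
smoothing and class weights. Everything is deterministic given the
``numpy.random.Generator`` passed in; stochastic layers (dropout, input
noise) are active only when ``train=True``.

All arrays are float64 params / float32 activations; shapes are
channels-last: dense ``(N, F)``, conv ``(N, *spatial, C)``.
"""

from __future__ import annotations

import numpy as np

from .errors import TrainingDivergedError

#: working dtype for parameters and activations
DTYPE = np.float32

__all__ = [
    "Dense",
    "Conv",
    "BatchNorm",
    "Activation",
    "Dropout",
    "Flatten",
    "Reshape",
    "AttentionGate",
    "GaussianNoise",
    "Sequential",
    "AdamW",
    "cosine_lr",
    "clip_global_norm",
    "softmax",
    "softmax_cross_entropy",
    "mse_loss",
]


class Layer:
    """Base layer: subclasses define forward/backward and expose params."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class Conv(Layer):
    """Valid convolution, stride 1, over 2 or 3 trailing spatial dims.

    Input ``(N, *spatial, C_in)``, kernel ``k`` per spatial dim, output
    ``(N, *(s - k + 1), C_out)``. Backward computes the input gradient as
    a full correlation with the flipped kernel (conv-transpose identity).
    """

    def __init__(
        self, n_spatial: int, c_in: int, c_out: int, k: int, rng, needs_input_grad: bool = True
    ) -> None:
        super().__init__()
        self.nd = n_spatial
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        self.needs_input_grad = needs_input_grad
        fan_in = c_in * k**n_spatial
        self.W = (
            rng.standard_normal((*([k] * n_spatial), c_in, c_out)) * np.sqrt(2.0 / fan_in)
        ).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # x: (N, *spatial, C) -> (N, *out_spatial, k**nd * C)
        win = (self.k,) * self.nd
        axes = tuple(range(1, 1 + self.nd))
        v = np.lib.stride_tricks.sliding_window_view(x, win, axis=axes)
        # v: (N, *out_spatial, C, *win)  -> move C after windows
        v = np.moveaxis(v, 1 + self.nd, -1)  # (N, *out, *win, C)
        return v.reshape(*v.shape[: 1 + self.nd], -1)

    def forward(self, x, train, rng):
        self._xshape = x.shape
        cols = self._im2col(x)  # (N, *out, K)
        self._cols = cols
        Wm = self.W.reshape(-1, self.c_out)
        out = cols @ Wm + self.b
        self._out_spatial = out.shape[1 : 1 + self.nd]
        return out

    def backward(self, grad):
        Wm = self.W.reshape(-1, self.c_out)
        cols2d = self._cols.reshape(-1, Wm.shape[0])
        g2d = grad.reshape(-1, self.c_out)
        self.grads[0][...] = (cols2d.T @ g2d).reshape(self.W.shape)
        self.grads[1][...] = g2d.sum(axis=0)
        if not self.needs_input_grad:
            return None
        # input grad: pad grad by k-1 per spatial dim, correlate with flipped W
        pad = [(0, 0)] + [(self.k - 1, self.k - 1)] * self.nd + [(0, 0)]
        gpad = np.pad(grad, pad)
        Wf = self.W
        for ax in range(self.nd):
            Wf = np.flip(Wf, axis=ax)
        # treat as conv with c_in/c_out swapped: kernel (.., c_out, c_in)
        Wf = np.swapaxes(Wf, -1, -2)
        win = (self.k,) * self.nd
        axes = tuple(range(1, 1 + self.nd))
        v = np.lib.stride_tricks.sliding_window_view(gpad, win, axis=axes)
        v = np.moveaxis(v, 1 + self.nd, -1)
        cols = v.reshape(*v.shape[: 1 + self.nd], -1)
        gx = cols @ Wf.reshape(-1, self.c_in)
        return gx.reshape(self._xshape)


class BatchNorm(Layer):
    """Normalizes over all axes but the last; tracks running stats for eval."""

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = np.ones(dim, dtype=DTYPE)
        self.beta = np.zeros(dim, dtype=DTYPE)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.run_mean = np.zeros(dim, dtype=DTYPE)
        self.run_var = np.ones(dim, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train, rng):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._axes = axes
        self._n = x.size // x.shape[-1]
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._train = train
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        axes = self._axes
        self.grads[0][...] = (grad * self._xhat).sum(axis=axes)
        self.grads[1][...] = grad.sum(axis=axes)
        if not self._train:
            return grad * self.gamma / self._std
        n = self._n
        gx = grad * self.gamma
        return (
            gx - gx.mean(axis=axes) - self._xhat * (gx * self._xhat).mean(axis=axes)
        ) / self._std


class Activation(Layer):
    def __init__(self, kind: str) -> None:
        super().__init__()
        if kind not in ("relu", "elu", "gelu", "linear"):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind

    def forward(self, x, train, rng):
        self._x = x
        if self.kind == "relu":
            return np.maximum(x, 0)
        if self.kind == "elu":
            return np.where(x > 0, x, np.expm1(np.minimum(x, 0)))
        if self.kind == "gelu":
            c = np.sqrt(2 / np.pi)
            self._t = np.tanh(c * (x + 0.044715 * x**3))
            return 0.5 * x * (1 + self._t)
        return x

    def backward(self, grad):
        x = self._x
        if self.kind == "relu":
            return grad * (x > 0)
        if self.kind == "elu":
            return grad * np.where(x > 0, 1.0, np.exp(np.minimum(x, 0)))
        if self.kind == "gelu":
            c = np.sqrt(2 / np.pi)
            t = self._t
            dt = (1 - t**2) * c * (1 + 3 * 0.044715 * x**2)
            return grad * (0.5 * (1 + t) + 0.5 * x * dt)
        return grad


class Dropout(Layer):
    def __init__(self, p: float) -> None:
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p

    def forward(self, x, train, rng):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = ((rng.random(x.shape, dtype=np.float32) >= self.p) / (1 - self.p)).astype(x.dtype)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class GaussianNoise(Layer):
    """Additive input noise, train-time only (regularizer)."""

    def __init__(self, sd: float) -> None:
        super().__init__()
        self.sd = sd

    def forward(self, x, train, rng):
        if train and self.sd > 0:
            return x + self.sd * rng.standard_normal(x.shape).astype(x.dtype)
        return x

    def backward(self, grad):
        return grad


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]) -> None:
        super().__init__()
        self.shape = shape

    def forward(self, x, train, rng):
        return x.reshape(x.shape[0], *self.shape)

    def backward(self, grad):
        return grad.reshape(grad.shape[0], -1)


class AttentionGate(Layer):
    """Softmax gate over input features, applied multiplicatively.

    ``a = softmax(logits)`` sums to 1 over the F features; the forward
    pass uses ``x * a * F`` so an indifferent gate (uniform attention) is
    the identity. ``weights`` exposes the normalized attention vector.
    """

    def __init__(self, n_features: int) -> None:
        super().__init__()
        self.logits = np.zeros(n_features)
        self.params = [self.logits]
        self.grads = [np.zeros_like(self.logits)]
        self.F = n_features

    @property
    def weights(self) -> np.ndarray:
        return softmax(self.logits[None, :])[0]

    def forward(self, x, train, rng):
        self._x = x
        self._a = self.weights
        return x * (self._a * self.F)

    def backward(self, grad):
        a = self._a
        # d(loss)/d(logits) through softmax jacobian
        s = (grad * self._x).sum(axis=0) * self.F
        self.grads[0][...] = a * (s - (a * s).sum())
        return grad * (a * self.F)


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray | None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
            if grad is None:  # a layer declared it needs no input gradient
                break
        return grad

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def state(self) -> list[np.ndarray]:
        out = [p.copy() for p in self.params]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                out.extend([layer.run_mean.copy(), layer.run_var.copy()])
        return out

    def load_state(self, state: list[np.ndarray]) -> None:
        n = len(self.params)
        for p, s in zip(self.params, state[:n]):
            p[...] = s
        rest = iter(state[n:])
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.run_mean[...] = next(rest)
                layer.run_var[...] = next(rest)


class AdamW:
    """Adam with decoupled weight decay (set decay 0 for plain Adam)."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        weight_decay: float = 0.0,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            if self.wd:
                p *= 1 - lr * self.wd
            p -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def cosine_lr(lr0: float, epoch: int, max_epochs: int, floor_frac: float = 0.01) -> float:
    """Cosine annealing from ``lr0`` down to ``floor_frac * lr0``."""
    if max_epochs <= 1:
        return lr0
    frac = 0.5 * (1 + np.cos(np.pi * epoch / (max_epochs - 1)))
    return lr0 * (floor_frac + (1 - floor_frac) * frac)


def clip_global_norm(grads: list[np.ndarray], max_norm: float) -> float:
    total = np.sqrt(sum(float((g**2).sum()) for g in grads))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for g in grads:
            g *= scale
    return total


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray,
    labels: np.ndarray,
    class_weights: np.ndarray | None = None,
    label_smoothing: float = 0.0,
) -> tuple[float, np.ndarray]:
    """Class-weighted CE with label smoothing; returns (loss, dlogits).

    Smoothed target for the true class is ``1 - eps + eps/K`` (the
    standard uniform-mixture convention); per-sample weight is the true
    class's weight; the loss is the weighted mean.
    """
    n, k = logits.shape
    p = softmax(logits)
    eps = label_smoothing
    targets = np.full((n, k), eps / k)
    targets[np.arange(n), labels] += 1 - eps
    w = np.ones(n) if class_weights is None else class_weights[labels]
    logp = np.log(np.clip(p, 1e-12, None))
    loss = float(-(w[:, None] * targets * logp).sum() / w.sum())
    if not np.isfinite(loss):
        raise TrainingDivergedError("non-finite cross-entropy loss")
    grad = (w[:, None] * (p - targets)) / w.sum()
    return loss, grad


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared (L2) reconstruction loss over all elements."""
    diff = pred - target
    loss = float((diff**2).mean())
    if not np.isfinite(loss):
        raise TrainingDivergedError("non-finite reconstruction loss")
    return loss, 2 * diff / diff.size
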