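"""Trainable layer primitives with analytic backprop.

Each layer caches what its backward pass needs during ``forward`` and
accumulates parameter gradients in ``Param.grad``; correctness of every
backward formula is guarded by a finite-difference check in the test suite.
Initialisation follows the Xavier/Glorot-normal scheme throughout.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array plus its gradient accumulator.

    ``weight_decay`` marks parameters included in the L2 penalty (dense and
    convolution kernels; never biases, batch-norm or the embedding table).
    """

    __slots__ = ("value", "grad", "name", "weight_decay")

    def __init__(self, value: np.ndarray, name: str, weight_decay: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name
        self.weight_decay = weight_decay

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def glorot_normal(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, size=shape)


class Embedding:
    """Lookup table mapping integer labels to trainable row vectors."""

    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator, name: str):
        self.table = Param(glorot_normal(rng, n_tokens, dim, (n_tokens, dim)), name)
        self._labels: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.table]

    def forward(self, labels: np.ndarray) -> np.ndarray:
        self._labels = labels
        return self.table.value[labels]

    def backward(self, grad_out: np.ndarray) -> None:
        np.add.at(self.table.grad, self._labels, grad_out)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str):
        self.W = Param(glorot_normal(rng, n_in, n_out, (n_in, n_out)), f"{name}.W",
                       weight_decay=True)
        self.b = Param(np.zeros(n_out), f"{name}.b")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ grad_out
        self.b.grad += grad_out.sum(axis=0)
        return grad_out @ self.W.value.T


class BatchNorm:
    """Per-feature batch normalisation with learned scale and shift.

    Training mode normalises by minibatch statistics and updates exponential
    running averages; inference mode uses the frozen running statistics.
    """

    def __init__(self, dim: int, name: str, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(dim), f"{name}.gamma")
        self.beta = Param(np.zeros(dim), f"{name}.beta")
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std, training, x.shape[0])
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xhat, inv_std, training, n = self._cache
        self.gamma.grad += (grad_out * xhat).sum(axis=0)
        self.beta.grad += grad_out.sum(axis=0)
        if not training:
            return grad_out * self.gamma.value * inv_std
        # train mode: minibatch mean/var depend on x
        g = grad_out * self.gamma.value
        return (inv_std / n) * (
            n * g - g.sum(axis=0) - xhat * (g * xhat).sum(axis=0)
        )


class ELU:
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.where(x >= 0, x, self.alpha * np.expm1(x))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x = self._x
        return grad_out * np.where(x >= 0, 1.0, self.alpha * np.exp(x))


class Dropout:
    """Inverted dropout; identity at inference or rate 0."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask: np.ndarray | float = 1.0

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = 1.0
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * self._mask


class WindowConv1D:
    """1-D convolution over the residue axis with stride 1, one window size.

    Implements out[b, j, f] = sum_{a<ES, t<WS} w[f, a, t] * x[b, j+t, a]
    (+ optional per-filter bias), j = 0 .. L-WS, via an im2col matmul.
    """

    def __init__(self, embedding_size: int, window_size: int, n_filters: int,
                 rng: np.random.Generator, name: str, bias: bool = True):
        self.es = embedding_size
        self.ws = window_size
        self.nf = n_filters
        fan_in = embedding_size * window_size
        self.W = Param(glorot_normal(rng, fan_in, n_filters, (fan_in, n_filters)),
                       f"{name}.W", weight_decay=True)
        self.b = Param(np.zeros(n_filters), f"{name}.b") if bias else None
        self._xcol: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def params(self) -> list[Param]:
        return [self.W] if self.b is None else [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (B, L, ES) -> (B, L-WS+1, F)
        b_, l_, _ = x.shape
        lo = l_ - self.ws + 1
        if lo < 1:
            raise ValueError(f"window size {self.ws} exceeds input length {l_}")
        # (B, L_out, ES, WS) view; flattened index = a * WS + t
        win = np.lib.stride_tricks.sliding_window_view(x, self.ws, axis=1)
        xcol = win.reshape(b_, lo, self.es * self.ws)
        self._xcol = xcol
        self._in_shape = x.shape
        out = xcol @ self.W.value
        if self.b is not None:
            out += self.b.value
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        b_, l_, es = self._in_shape
        lo = grad_out.shape[1]
        self.W.grad += np.einsum("blk,blf->kf", self._xcol, grad_out, optimize=True)
        if self.b is not None:
            self.b.grad += grad_out.sum(axis=(0, 1))
        gcol = (grad_out @ self.W.value.T).reshape(b_, lo, es, self.ws)
        gx = np.zeros((b_, l_, es))
        for t in range(self.ws):
            gx[:, t:t + lo, :] += gcol[:, :, :, t]
        return gx


class MaskedGlobalMaxPool:
    """Global max over convolution positions, restricted to valid windows.

    ``n_valid[b]`` is the number of start positions lying entirely within the
    true (un-padded) sequence of sample ``b``; positions beyond it are
    excluded so a trainable pad embedding can never win the max. Ties break
    to the earliest position. With no valid position at all the pooled value
    is defined as 0 and the argmax flagged as -1.
    """

    def __init__(self):
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, conv: np.ndarray, n_valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        b_, lo, nf = conv.shape
        n_valid = np.minimum(n_valid, lo)
        masked = np.where(np.arange(lo)[None, :, None] < n_valid[:, None, None],
                          conv, -np.inf)
        pooled = masked.max(axis=1)
        argmax = masked.argmax(axis=1)  # first occurrence on ties
        empty = n_valid <= 0
        pooled[empty] = 0.0
        argmax[empty] = -1
        self._cache = (argmax, empty, conv.shape)
        return pooled, argmax

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        argmax, empty, shape = self._cache
        gx = np.zeros(shape)
        b_, _, nf = shape
        bi = np.repeat(np.arange(b_), nf)
        fi = np.tile(np.arange(nf), b_)
        ji = argmax.ravel()
        keep = ~np.repeat(empty, nf)
        np.add.at(gx, (bi[keep], ji[keep], fi[keep]), grad_out.ravel()[keep])
        return gx


class Adam:
    """Adam optimiser with the canonical defaults (b1=0.9, b2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Param], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
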