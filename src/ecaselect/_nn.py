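"""Minimal NumPy layer framework used by the ECA-DeepNet runtime.

Each layer implements ``forward(x, training)`` and ``backward(grad)`` and
exposes its trainable tensors as :class:`Param` objects.  Tensors between
layers use these layouts:

* EEG input: ``(N, C, T)`` — batch, electrodes, time.
* After the temporal convolution: ``(N, F, L, C)`` — feature maps, time, space.
* After the spatial convolution and in all later blocks: ``(N, F, L)``.

Convolutions are cross-correlations (no kernel flip), evaluated with
``sliding_window_view`` + ``tensordot`` so the inner loops stay in BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view as _swv
from scipy.special import expit

from .attention import adaptive_kernel_size

__all__ = [
    "Param",
    "Layer",
    "CALayer",
    "TemporalConv",
    "SpatialConv",
    "MapConv",
    "BatchNorm",
    "Elu",
    "MaxPool",
    "EcaModule",
    "Dropout",
    "log_softmax",
    "nll_loss_and_grad",
    "AdamW",
    "Adagrad",
    "Adadelta",
    "make_optimizer",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("name", "value", "grad", "decay")

    def __init__(self, name: str, value: np.ndarray, decay: bool = True):
        self.name = name
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.decay = decay  # participates in weight decay (biases/norms do not)

    @property
    def size(self) -> int:
        return self.value.size


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    name = "layer"

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class CALayer(Layer):
    """Input-facing attention over EEG electrodes via a full linear map.

    Pools each electrode over time, maps the pooled vector through a square
    ``C x C`` linear layer plus bias, gates electrodes with the sigmoid
    output, and remembers the per-sample attention for later extraction.
    """

    def __init__(self, n_channels: int, rng: np.random.Generator, name: str = "CA-Layer"):
        self.name = name
        c = n_channels
        self.w = Param(f"{name}.weight", _glorot(rng, (c, c), c, c))
        self.b = Param(f"{name}.bias", np.zeros(c), decay=False)
        self.last_attention: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = x.mean(axis=2)  # (N, C)
        z = y @ self.w.value.T + self.b.value
        att = expit(z)
        self._cache = (x, y, att)
        self.last_attention = att
        return x * att[:, :, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        x, y, att = self._cache
        t = x.shape[2]
        dx = g * att[:, :, None]
        datt = np.einsum("nct,nct->nc", g, x)
        dz = datt * att * (1.0 - att)
        self.w.grad += dz.T @ y
        self.b.grad += dz.sum(axis=0)
        dy = dz @ self.w.value
        dx += dy[:, :, None] / t
        return dx


class TemporalConv(Layer):
    """Convolution along time, shared across electrodes: (N,C,T) -> (N,F,L,C)."""

    def __init__(self, n_filters: int, kernel: int, rng: np.random.Generator, name: str = "Conv-Time"):
        self.name = name
        self.kernel = kernel
        self.w = Param(f"{name}.weight", _glorot(rng, (n_filters, kernel), kernel, n_filters * kernel))

    def params(self) -> list[Param]:
        return [self.w]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        xw = _swv(x, self.kernel, axis=2)  # (N, C, L, k)
        self._cache = xw
        out = np.tensordot(xw, self.w.value, axes=([3], [1]))  # (N, C, L, F)
        return out.transpose(0, 3, 2, 1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        xw = self._cache
        k = self.kernel
        gt = g.transpose(0, 3, 2, 1)  # (N, C, L, F)
        self.w.grad += np.tensordot(gt, xw, axes=([0, 1, 2], [0, 1, 2]))
        pad = np.pad(gt, ((0, 0), (0, 0), (k - 1, k - 1), (0, 0)))
        win = _swv(pad, k, axis=2)  # (N, C, T, F, k)
        wr = self.w.value[:, ::-1]  # (F, k)
        return np.tensordot(win, wr, axes=([3, 4], [0, 1]))  # (N, C, T)


class SpatialConv(Layer):
    """Convolution across electrodes mixing feature maps: (N,Fin,L,C) -> (N,Fout,L)."""

    def __init__(self, n_out: int, n_in: int, n_channels: int, rng: np.random.Generator, name: str = "Conv-Spat"):
        self.name = name
        fan_in = n_in * n_channels
        self.w = Param(f"{name}.weight", _glorot(rng, (n_out, n_in, n_channels), fan_in, n_out * n_channels))

    def params(self) -> list[Param]:
        return [self.w]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._cache = x
        out = np.tensordot(x, self.w.value, axes=([1, 3], [1, 2]))  # (N, L, Fout)
        return out.transpose(0, 2, 1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._cache
        self.w.grad += np.einsum("nfl,nglc->fgc", g, x)
        return np.einsum("nfl,fgc->nglc", g, self.w.value)


class MapConv(Layer):
    """Convolution along time over feature maps: (N,Fin,L) -> (N,Fout,Lo)."""

    def __init__(
        self,
        n_out: int,
        n_in: int,
        kernel: int,
        rng: np.random.Generator,
        bias: bool = False,
        name: str = "Conv",
    ):
        self.name = name
        self.kernel = kernel
        fan_in = n_in * kernel
        self.w = Param(f"{name}.weight", _glorot(rng, (n_out, n_in, kernel), fan_in, n_out * kernel))
        self.b = Param(f"{name}.bias", np.zeros(n_out), decay=False) if bias else None

    def params(self) -> list[Param]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        xw = _swv(x, self.kernel, axis=2)  # (N, Fin, Lo, k)
        self._cache = xw
        out = np.tensordot(xw, self.w.value, axes=([1, 3], [1, 2]))  # (N, Lo, Fout)
        out = out.transpose(0, 2, 1)
        if self.b is not None:
            out = out + self.b.value[:, None]
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        xw = self._cache
        k = self.kernel
        self.w.grad += np.einsum("nfo,ngok->fgk", g, xw)
        if self.b is not None:
            self.b.grad += g.sum(axis=(0, 2))
        pad = np.pad(g, ((0, 0), (0, 0), (k - 1, k - 1)))
        win = _swv(pad, k, axis=2)  # (N, Fout, L, k)
        return np.einsum("nftk,fgk->ngt", win, self.w.value[:, :, ::-1])


class BatchNorm(Layer):
    """Per-feature-map batch normalization over (batch, time)."""

    def __init__(self, n_maps: int, rng: np.random.Generator | None = None, eps: float = 1e-5, momentum: float = 0.1, name: str = "BatchNorm"):
        self.name = name
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(f"{name}.gamma", np.ones(n_maps), decay=False)
        self.beta = Param(f"{name}.beta", np.zeros(n_maps), decay=False)
        self.running_mean = np.zeros(n_maps)
        self.running_var = np.ones(n_maps)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[:, None]) * invstd[:, None]
        self._cache = (xhat, invstd, x.shape[0] * x.shape[2], training)
        return self.gamma.value[:, None] * xhat + self.beta.value[:, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, invstd, m, training = self._cache
        self.beta.grad += g.sum(axis=(0, 2))
        self.gamma.grad += (g * xhat).sum(axis=(0, 2))
        dxhat = g * self.gamma.value[:, None]
        if not training:
            return dxhat * invstd[:, None]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (invstd[:, None] / m) * (m * dxhat - s1 - xhat * s2)


class Elu(Layer):
    """Exponential linear unit: x for x > 0, exp(x) - 1 otherwise."""

    def __init__(self, name: str = "Activation"):
        self.name = name

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))
        self._cache = (x > 0, out)
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        pos, out = self._cache
        return g * np.where(pos, 1.0, out + 1.0)


class MaxPool(Layer):
    """Non-overlapping max pooling along time; trailing remainder is dropped."""

    def __init__(self, size: int, name: str = "Pool"):
        self.name = name
        self.size = size

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        p = self.size
        lp = x.shape[-1] // p
        xt = x[..., : lp * p].reshape(x.shape[:-1] + (lp, p))
        idx = xt.argmax(axis=-1)
        self._cache = (idx, x.shape, lp)
        return np.take_along_axis(xt, idx[..., None], axis=-1)[..., 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        idx, shape, lp = self._cache
        p = self.size
        dz = np.zeros(g.shape + (p,))
        np.put_along_axis(dz, idx[..., None], g[..., None], axis=-1)
        dx = np.zeros(shape)
        dx[..., : lp * p] = dz.reshape(g.shape[:-1] + (lp * p,))
        return dx


class EcaModule(Layer):
    """Inter-layer attention over feature maps via a shared adaptive-kernel
    1-D convolution with a single bias: k + 1 trainable scalars."""

    def __init__(self, n_maps: int, rng: np.random.Generator, name: str = "ECA"):
        self.name = name
        self.k = adaptive_kernel_size(n_maps)
        bound = 1.0 / np.sqrt(self.k)
        self.kern = Param(f"{name}.kernel", rng.uniform(-bound, bound, size=self.k))
        self.bias = Param(f"{name}.bias", np.zeros(1), decay=False)

    def params(self) -> list[Param]:
        return [self.kern, self.bias]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = x.mean(axis=2)  # (N, F)
        pad = (self.k - 1) // 2
        yp = np.pad(y, ((0, 0), (pad, pad)))
        yw = _swv(yp, self.k, axis=1)  # (N, F, k)
        z = yw @ self.kern.value + self.bias.value[0]
        att = expit(z)
        self._cache = (x, yw, att)
        return x * att[:, :, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        x, yw, att = self._cache
        l = x.shape[2]
        pad = (self.k - 1) // 2
        dx = g * att[:, :, None]
        datt = np.einsum("nfl,nfl->nf", g, x)
        dz = datt * att * (1.0 - att)
        self.kern.grad += np.einsum("nfk,nf->k", yw, dz)
        self.bias.grad += dz.sum()
        zp = np.pad(dz, ((0, 0), (pad, pad)))
        zw = _swv(zp, self.k, axis=1)
        dy = zw @ self.kern.value[::-1]
        dx += dy[:, :, None] / l
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator, name: str = "dropout"):
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must lie in [0, 1)")
        self.name = name
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._cache = None
            return x
        mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        self._cache = mask
        return x * mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._cache is None else g * self._cache


# ---------------------------------------------------------------------------
# Loss


def log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


def nll_loss_and_grad(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean negative log-likelihood of the log-softmax head and its gradient."""
    n = logits.shape[0]
    logp = log_softmax(logits)
    loss = -logp[np.arange(n), labels].mean()
    grad = np.exp(logp)
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


# ---------------------------------------------------------------------------
# Optimizers


class _Optimizer:
    def __init__(self, params: list[Param], lr: float, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:  # pragma: no cover
        raise NotImplementedError


class AdamW(_Optimizer):
    """Adam with decoupled weight decay (decay skipped on biases/norms)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        super().__init__(params, lr, weight_decay)
        self.betas = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.decay and self.weight_decay:
                p.value *= 1.0 - self.lr * self.weight_decay
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Adagrad(_Optimizer):
    def __init__(self, params, lr=1e-2, eps=1e-10, weight_decay=0.0):
        super().__init__(params, lr, weight_decay)
        self.eps = eps
        self.acc = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, a in zip(self.params, self.acc):
            g = p.grad + (self.weight_decay * p.value if p.decay else 0.0)
            a += g**2
            p.value -= self.lr * g / (np.sqrt(a) + self.eps)


class Adadelta(_Optimizer):
    def __init__(self, params, lr=1.0, rho=0.9, eps=1e-6, weight_decay=0.0):
        super().__init__(params, lr, weight_decay)
        self.rho = rho
        self.eps = eps
        self.eg = [np.zeros_like(p.value) for p in params]
        self.ed = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, eg, ed in zip(self.params, self.eg, self.ed):
            g = p.grad + (self.weight_decay * p.value if p.decay else 0.0)
            eg *= self.rho
            eg += (1 - self.rho) * g**2
            delta = np.sqrt((ed + self.eps) / (eg + self.eps)) * g
            ed *= self.rho
            ed += (1 - self.rho) * delta**2
            p.value -= self.lr * delta


_OPTIMIZERS = {"adamw": AdamW, "adagrad": Adagrad, "adadelta": Adadelta}


def make_optimizer(name: str, params: list[Param], lr: float, weight_decay: float) -> _Optimizer:
    try:
        cls = _OPTIMIZERS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown optimizer {name!r}; choose from AdamW, Adagrad, Adadelta")
    return cls(params, lr=lr, weight_decay=weight_decay)
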