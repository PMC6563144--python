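"""Layers with explicit forward/backward passes.

Conventions: images are (N, C, H, W) float32; every layer caches what its
backward pass needs on ``forward`` and releases it after ``backward``.
Convolutions use im2col + BLAS matmul; the transpose convolution is the
data-gradient of a stride-s convolution, so stride-2 layers exactly double
the spatial size (kernel 3, padding 1, output padding 1 semantics).
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


# ---------------------------------------------------------------- im2col

def im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Return (cols, out_shape): cols is (N, Ho*Wo, C*k*k)."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]          # N,C,Ho,Wo,k,k
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)
    return np.ascontiguousarray(cols), (ho, wo)


def col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    """Scatter-add inverse of :func:`im2col`. dcols is (N, Ho*Wo, C*k*k)."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    dx = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    d6 = dcols.reshape(n, ho, wo, c, k, k)
    for i in range(k):
        for j in range(k):
            dx[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += (
                d6[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            )
    if pad:
        dx = dx[:, :, pad:hp - pad, pad:wp - pad]
    return dx


# ---------------------------------------------------------------- layers

class Layer:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class Conv2d(Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.pad = kernel, stride, pad
        self.in_ch, self.out_ch = in_ch, out_ch
        fan_in = in_ch * kernel * kernel
        self.w = Param(_he_init(rng, (out_ch, fan_in), fan_in))
        self.b = Param(np.zeros(out_ch, dtype=np.float32))
        self._cache = None

    def forward(self, x, train=True):
        cols, (ho, wo) = im2col(x, self.k, self.stride, self.pad)
        y = cols @ self.w.value.T + self.b.value          # N, L, out
        self._cache = (cols, x.shape, ho, wo)
        return y.transpose(0, 2, 1).reshape(x.shape[0], self.out_ch, ho, wo)

    def backward(self, grad):
        cols, x_shape, ho, wo = self._cache
        self._cache = None
        n = grad.shape[0]
        g = grad.reshape(n, self.out_ch, ho * wo).transpose(0, 2, 1)  # N,L,out
        self.w.grad += np.einsum("nlo,nlc->oc", g, cols, optimize=True)
        self.b.grad += g.sum(axis=(0, 1))
        dcols = g @ self.w.value                                       # N,L,Ckk
        return col2im(dcols, x_shape, self.k, self.stride, self.pad)

    def params(self):
        return [self.w, self.b]


class ConvTranspose2d(Layer):
    """Stride-s transpose convolution doubling (for s=2, k=3, p=1) spatial size."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 2,
                 pad: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.pad = kernel, stride, pad
        self.in_ch, self.out_ch = in_ch, out_ch
        fan_in = in_ch * kernel * kernel
        # stored as (in_ch, out_ch*k*k): forward is the data-gradient of a conv
        self.w = Param(_he_init(rng, (in_ch, out_ch * kernel * kernel), fan_in))
        self.b = Param(np.zeros(out_ch, dtype=np.float32))
        self._cache = None

    def _out_hw(self, h, w):
        # inverse of conv output formula with output_padding = stride - 1
        return self.stride * h, self.stride * w

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        ho, wo = self._out_hw(h, w)
        g = x.reshape(n, c, h * w).transpose(0, 2, 1)      # N, L, in
        dcols = g @ self.w.value                           # N, L, out*k*k
        y = col2im(dcols, (n, self.out_ch, ho, wo), self.k, self.stride, self.pad)
        y += self.b.value[None, :, None, None]
        self._cache = (g, (n, c, h, w), (ho, wo))
        return y

    def backward(self, grad):
        g, x_shape, _ = self._cache
        self._cache = None
        n, c, h, w = x_shape
        cols, _ = im2col(grad, self.k, self.stride, self.pad)  # N, L, out*k*k
        self.w.grad += np.einsum("nli,nlc->ic", g, cols, optimize=True)
        self.b.grad += grad.sum(axis=(0, 2, 3))
        dg = cols @ self.w.value.T                             # N, L, in
        return dg.transpose(0, 2, 1).reshape(n, c, h, w)

    def params(self):
        return [self.w, self.b]


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(_he_init(rng, (out_dim, in_dim), in_dim))
        self.b = Param(np.zeros(out_dim, dtype=np.float32))
        self._x = None

    def forward(self, x, train=True):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, grad):
        x = self._x
        self._x = None
        self.w.grad += grad.T @ x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value

    def params(self):
        return [self.w, self.b]


class _BatchNormBase(Layer):
    def __init__(self, n_feat: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_feat, dtype=np.float32))
        self.beta = Param(np.zeros(n_feat, dtype=np.float32))
        self.running_mean = np.zeros(n_feat, dtype=np.float32)
        self.running_var = np.ones(n_feat, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def _axes(self, x):
        raise NotImplementedError

    def _shape(self, x):
        raise NotImplementedError

    def forward(self, x, train=True):
        axes = self._axes(x)
        shape = self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
        if train:
            self._cache = (xhat, inv, axes, shape,
                           float(np.prod([x.shape[a] for a in axes])))
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)

    def backward(self, grad):
        xhat, inv, axes, shape, m = self._cache
        self._cache = None
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.value.reshape(shape)
        term = (g - g.mean(axis=axes).reshape(shape)
                - xhat * (g * xhat).mean(axis=axes).reshape(shape))
        return term * inv.reshape(shape)

    def params(self):
        return [self.gamma, self.beta]

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class BatchNorm2d(_BatchNormBase):
    def _axes(self, x):
        return (0, 2, 3)

    def _shape(self, x):
        return (1, -1, 1, 1)


class BatchNorm1d(_BatchNormBase):
    def _axes(self, x):
        return (0,)

    def _shape(self, x):
        return (1, -1)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        g = grad * self._mask
        self._mask = None
        return g


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.1):
        self.alpha = alpha

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad):
        g = np.where(self._mask, grad, self.alpha * grad)
        self._mask = None
        return g


class Sigmoid(Layer):
    def forward(self, x, train=True):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, grad):
        g = grad * self._y * (1.0 - self._y)
        self._y = None
        return g


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape):
        self.shape = tuple(shape)          # per-sample shape

    def forward(self, x, train=True):
        self._in = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad):
        return grad.reshape(self._in)


class GlobalAvgPool2d(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w), self._shape).copy()


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    # ---- (de)serialization of params + batchnorm running stats ----
    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.params()):
            arrays[f"p{i}"] = p.value
        bn = [l for l in self.layers if isinstance(l, _BatchNormBase)]
        for i, layer in enumerate(bn):
            arrays[f"bn{i}_mean"] = layer.running_mean
            arrays[f"bn{i}_var"] = layer.running_var
        return arrays

    def load_state_arrays(self, arrays) -> None:
        for i, p in enumerate(self.params()):
            p.value = np.ascontiguousarray(arrays[f"p{i}"], dtype=np.float32)
            p.grad = np.zeros_like(p.value)
        bn = [l for l in self.layers if isinstance(l, _BatchNormBase)]
        for i, layer in enumerate(bn):
            layer.running_mean = np.asarray(arrays[f"bn{i}_mean"], dtype=np.float32)
            layer.running_var = np.asarray(arrays[f"bn{i}_var"], dtype=np.float32)


def zero_grads(params: list[Param]) -> None:
    for p in params:
        p.grad[...] = 0.0
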