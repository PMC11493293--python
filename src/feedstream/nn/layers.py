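"""Minimal CPU neural-network layer library (numpy, manual backprop).

Layers operate on float64 arrays in NCHW (2-D) or NCL (1-D) layout. Each
layer caches what its backward pass needs during ``forward(train=True)``;
``backward`` returns the gradient w.r.t. the input and accumulates
parameter gradients in ``Param.grad``. Convolutions use im2col + BLAS
matmul, which is the fastest portable route for the small models trained
here. Max pooling is 2×2/stride-2 (2-D) and width-2 (1-D), which preserves
the canonical stage output sizes of the residual backbone at both 224 and
64 pixel inputs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Sequential",
    "Conv2d",
    "Conv1d",
    "BatchNorm",
    "ReLU",
    "MaxPool2d",
    "MaxPool1d",
    "GlobalAvgPool2d",
    "Flatten",
    "Dense",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]


class Param:
    """A learnable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Sequential(Layer):
    """A chain of layers; also the container for whole models."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Layer):
    """2-D convolution (cross-correlation), NCHW, He-initialized."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        rng: np.random.Generator | None = None,
        bias: bool = True,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        k = kernel
        fan_in = in_ch * k * k
        self.W = Param(_he_init(rng, (out_ch, in_ch, k, k), fan_in), "conv2d.W")
        self.b = Param(np.zeros(out_ch), "conv2d.b") if bias else None
        self.kernel, self.stride, self.pad = k, stride, pad
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        windows = windows[:, :, ::s, ::s]  # (n, c, oh, ow, k, k)
        cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
        return np.ascontiguousarray(cols), (n, c, h, w, oh, ow)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        cols, meta = self._im2col(x)
        n, c, h, w, oh, ow = meta
        out_ch = self.W.value.shape[0]
        out = cols @ self.W.value.reshape(out_ch, -1).T
        if self.b is not None:
            out += self.b.value
        if train:
            self._cache = (cols, meta)
        return out.reshape(n, oh, ow, out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w, oh, ow) = self._cache
        out_ch = dout.shape[1]
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * oh * ow, out_ch)
        self.W.grad += (dmat.T @ cols).reshape(self.W.value.shape)
        if self.b is not None:
            self.b.grad += dmat.sum(axis=0)
        dcols = dmat @ self.W.value.reshape(out_ch, -1)
        k, s, p = self.kernel, self.stride, self.pad
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        dcols = dcols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 4, 5, 1, 2)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += dcols[:, :, i, j]
        self._cache = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class Conv1d(Layer):
    """1-D convolution over (N, C, L) with 'same'-style zero padding."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        pad: int = 0,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel
        self.W = Param(_he_init(rng, (out_ch, in_ch, kernel), fan_in), "conv1d.W")
        self.b = Param(np.zeros(out_ch), "conv1d.b")
        self.kernel, self.pad = kernel, pad
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, length = x.shape
        k, p = self.kernel, self.pad
        if length + 2 * p < k:
            raise ValueError(
                f"kernel of width {k} wider than padded input length {length + 2 * p}"
            )
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p)))
        ol = length + 2 * p - k + 1
        windows = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)  # (n, c, ol, k)
        cols = windows.transpose(0, 2, 1, 3).reshape(n * ol, c * k)
        out = cols @ self.W.value.reshape(self.W.value.shape[0], -1).T + self.b.value
        if train:
            self._cache = (np.ascontiguousarray(cols), (n, c, length, ol))
        return out.reshape(n, ol, -1).transpose(0, 2, 1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (n, c, length, ol) = self._cache
        out_ch = dout.shape[1]
        k, p = self.kernel, self.pad
        dmat = dout.transpose(0, 2, 1).reshape(n * ol, out_ch)
        self.W.grad += (dmat.T @ cols).reshape(self.W.value.shape)
        self.b.grad += dmat.sum(axis=0)
        dcols = (dmat @ self.W.value.reshape(out_ch, -1)).reshape(n, ol, c, k)
        dxp = np.zeros((n, c, length + 2 * p))
        for i in range(k):
            dxp[:, :, i : i + ol] += dcols[:, :, :, i].transpose(0, 2, 1)
        self._cache = None
        return dxp[:, :, p : p + length] if p else dxp


class BatchNorm(Layer):
    """Batch normalization over all axes except the channel axis (axis 1)."""

    def __init__(self, n_ch: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(n_ch), "bn.gamma")
        self.beta = Param(np.zeros(n_ch), "bn.beta")
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    @staticmethod
    def _shape(x: np.ndarray, vec: np.ndarray) -> np.ndarray:
        return vec.reshape((1, -1) + (1,) * (x.ndim - 2))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = (0,) + tuple(range(2, x.ndim))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - self._shape(x, mean)) / self._shape(x, std)
        if train:
            self._cache = (xhat, std, axes)
        return self._shape(x, self.gamma.value) * xhat + self._shape(x, self.beta.value)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, std, axes = self._cache
        m = dout.size // dout.shape[1]
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self._shape(dout, self.gamma.value)
        term = (
            m * dxhat
            - self._shape(dout, dxhat.sum(axis=axes))
            - xhat * self._shape(dout, (dxhat * xhat).sum(axis=axes))
        )
        self._cache = None
        return term / (m * self._shape(dout, std))


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2d(Layer):
    """2×2 stride-2 max pooling (requires even spatial dimensions)."""

    def __init__(self) -> None:
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
        r = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = r.max(axis=(3, 5))
        if train:
            self._cache = (r, out, (n, c, h, w))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        r, out, (n, c, h, w) = self._cache
        mask = r == out[:, :, :, None, :, None]
        # Split gradient evenly among tied maxima within a window.
        counts = mask.sum(axis=(3, 5), keepdims=True)
        dx = mask / counts * dout[:, :, :, None, :, None]
        self._cache = None
        return dx.reshape(n, c, h, w)


class MaxPool1d(Layer):
    """Width-2 stride-2 max pooling over (N, C, L), even L required."""

    def __init__(self) -> None:
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, length = x.shape
        if length % 2:
            raise ValueError(f"length must be even for width-2 pooling, got {length}")
        r = x.reshape(n, c, length // 2, 2)
        out = r.max(axis=3)
        if train:
            self._cache = (r, out, (n, c, length))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        r, out, (n, c, length) = self._cache
        mask = r == out[..., None]
        counts = mask.sum(axis=3, keepdims=True)
        dx = mask / counts * dout[..., None]
        self._cache = None
        return dx.reshape(n, c, length)


class GlobalAvgPool2d(Layer):
    """Spatial mean per channel: (N, C, H, W) → (N, C)."""

    def __init__(self) -> None:
        self._shape_in = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape_in = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape_in
        return np.broadcast_to(dout[:, :, None, None], (n, c, h, w)) / (h * w)


class Flatten(Layer):
    def __init__(self) -> None:
        self._shape_in = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape_in = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape_in)


class Dense(Layer):
    """Fully connected layer, (N, in) → (N, out)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng(0)
        self.W = Param(_he_init(rng, (n_in, n_out), n_in), "dense.W")
        self.b = Param(np.zeros(n_out), "dense.b")
        self._x = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        dx = dout @ self.W.value.T
        self._x = None
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. logits for int labels."""
    n = logits.shape[0]
    probs = softmax(logits)
    loss = float(-np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


class Adam:
    """Adaptive-moment gradient descent over a list of :class:`Param`."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
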