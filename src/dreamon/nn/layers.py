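"""Minimal CPU layer framework with explicit forward/backward passes.

Each layer caches what its backward pass needs during ``forward`` and
accumulates parameter gradients into :class:`Param` objects during
``backward``.  Image tensors are ``(N, C, H, W)`` float64 arrays.
Convolution is implemented with an im2col/col2im pair so the heavy work is
a single matrix multiply.  Everything is deterministic for a fixed
``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Layer:
    """Base layer: stateless unless it declares parameters."""

    def __init__(self) -> None:
        self.params: list[Param] = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def children(self) -> list["Layer"]:
        return []


def iter_layers(layer: "Layer"):
    """Depth-first iteration over a layer tree (the layer itself included)."""
    yield layer
    for child in layer.children():
        yield from iter_layers(child)


# --------------------------------------------------------------------- dense


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in)))
        self.b = Param(np.zeros(n_out))
        self.params = [self.W, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, grad):
        self.W.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value


# --------------------------------------------------------------- convolution


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s0, s1, s2, s3 = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, kh, kw, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    # (N, Ho, Wo, C, kh, kw) -> (N*Ho*Wo, C*kh*kw)
    col = np.ascontiguousarray(windows.transpose(0, 4, 5, 1, 2, 3))
    return col.reshape(n * ho * wo, c * kh * kw), ho, wo


def _col2im(dcol: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x_shape
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    dcol = dcol.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dcol[
                :, :, i, j
            ]
    return dxp[:, :, pad : pad + h, pad : pad + w]


class Conv2d(Layer):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int,
        pad: int,
        rng: np.random.Generator,
    ):
        super().__init__()
        fan_in = c_in * kernel * kernel
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in)))
        self.b = Param(np.zeros(c_out))
        self.params = [self.W, self.b]
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x, train=True):
        self._x_shape = x.shape
        col, ho, wo = _im2col(x, self.kernel, self.kernel, self.stride, self.pad)
        self._col = col
        out = col @ self.W.value.T + self.b.value
        n = x.shape[0]
        return out.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, c_out, ho, wo = grad.shape
        g = grad.transpose(0, 2, 3, 1).reshape(n * ho * wo, c_out)
        self.W.grad += g.T @ self._col
        self.b.grad += g.sum(axis=0)
        dcol = g @ self.W.value
        return _col2im(dcol, self._x_shape, self.kernel, self.kernel, self.stride, self.pad)


# ------------------------------------------------------------- normalization


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.params = [self.gamma, self.beta]
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        m = mean[None, :, None, None]
        v = var[None, :, None, None]
        self._std = np.sqrt(v + self.eps)
        self._xhat = (x - m) / self._std
        self._train = train
        return self.gamma.value[None, :, None, None] * self._xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, grad):
        self.gamma.grad += (grad * self._xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        dxhat = grad * self.gamma.value[None, :, None, None]
        if not self._train:
            return dxhat / self._std
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        # batch statistics participate in the normalization
        sum_dxhat = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_dxhat_xhat = (dxhat * self._xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (dxhat - sum_dxhat / n - self._xhat * sum_dxhat_xhat / n) / self._std


# ------------------------------------------------------------- element-wise


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


class Sigmoid(Layer):
    def forward(self, x, train=True):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


# ------------------------------------------------------------------- shape


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]):
        super().__init__()
        self.shape = shape

    def forward(self, x, train=True):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class UpsampleNearest(Layer):
    """Nearest-neighbour 2x upsampling (used instead of transposed convolution)."""

    def forward(self, x, train=True):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad):
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class MaxPool2x2(Layer):
    def forward(self, x, train=True):
        n, c, h, w = x.shape
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = blocks.max(axis=(3, 5))
        self._mask = blocks == out[:, :, :, None, :, None]
        # break ties: keep only the first max per block
        flat = self._mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        first = np.cumsum(flat, axis=-1) == 1
        self._mask = (flat & first).reshape(n, c, h // 2, w // 2, 2, 2).transpose(
            0, 1, 2, 4, 3, 5
        )
        return out

    def backward(self, grad):
        g = grad[:, :, :, None, :, None] * self._mask
        n, c, h2, _, w2, _ = g.shape
        return g.reshape(n, c, h2 * 2, w2 * 2)


class GlobalAvgPool(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


# -------------------------------------------------------------- containers


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers
        self.params = [p for layer in layers for p in layer.params]

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def children(self):
        return list(self.layers)


class ResidualBlock(Layer):
    """Two 3x3 conv/BN layers with an identity (or 1x1-projected) skip."""

    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(c_in, c_out, 3, stride, 1, rng)
        self.bn1 = BatchNorm2d(c_out)
        self.relu = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, 1, 1, rng)
        self.bn2 = BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.proj: Conv2d | None = Conv2d(c_in, c_out, 1, stride, 0, rng)
            self.bn_proj: BatchNorm2d | None = BatchNorm2d(c_out)
        else:
            self.proj = None
            self.bn_proj = None
        for sub in (self.conv1, self.bn1, self.conv2, self.bn2, self.proj, self.bn_proj):
            if sub is not None:
                self.params.extend(sub.params)

    def forward(self, x, train=True):
        h = self.relu.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        h = self.bn2.forward(self.conv2.forward(h, train), train)
        if self.proj is not None:
            skip = self.bn_proj.forward(self.proj.forward(x, train), train)
        else:
            skip = x
        y = h + skip
        self._pre_mask = y > 0
        return y * self._pre_mask

    def backward(self, grad):
        grad = grad * self._pre_mask
        gh = self.bn2.backward(grad)
        gh = self.conv2.backward(gh)
        gh = self.relu.backward(gh)
        gh = self.bn1.backward(gh)
        gh = self.conv1.backward(gh)
        if self.proj is not None:
            gs = self.proj.backward(self.bn_proj.backward(grad))
        else:
            gs = grad
        return gh + gs

    def children(self):
        subs = [self.conv1, self.bn1, self.relu, self.conv2, self.bn2]
        if self.proj is not None:
            subs.extend([self.proj, self.bn_proj])
        return subs
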