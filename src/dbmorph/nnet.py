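"""Minimal seeded neural-network engine for small 3D convolutional models.

The networks used in this package are small (a three-stage strided 3D
convolutional encoder/decoder and a one-convolution classifier head), so the
whole engine is written directly on numpy: every layer implements an explicit
``forward``/``backward`` pair, parameters are plain arrays updated by Adam,
and all randomness (weight initialisation, dropout masks, batch sampling)
flows from :class:`numpy.random.Generator` objects, which makes training
bit-reproducible for a fixed seed on a fixed platform.

Shape convention: batched volumetric activations are ``(N, C, D, H, W)``;
dense activations are ``(N, F)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "HalvingConv3d",
    "DoublingConvT3d",
    "StridedConv3d",
    "Dense",
    "BatchNorm",
    "Dropout",
    "ReLU",
    "Sigmoid",
    "Flatten",
    "Sequential",
    "Adam",
    "mse_loss",
    "bce_with_logits",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class Param:
    value: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.grad = np.zeros_like(self.value)


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def _glorot_init(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


class Layer:
    """Base layer: subclasses cache what backward needs during forward."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def params(self) -> list[Param]:
        return []

    def state_arrays(self) -> list[np.ndarray]:
        """Arrays beyond params that define inference behaviour (e.g. BN stats)."""
        return []


class HalvingConv3d(Layer):
    """3D convolution with kernel 2, stride 2, no padding.

    Output spatial dims are the floor-halved input dims; with this kernel the
    receptive fields are non-overlapping 2x2x2 blocks, so the operation is a
    block reshape followed by a tensor contraction. A trailing odd slice of the
    input is dropped, matching valid convolution.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 init: str = "he"):
        fan_in = c_in * 8
        if init == "he":
            w = _he_init(rng, (c_out, c_in, 2, 2, 2), fan_in)
        else:
            w = _glorot_init(rng, (c_out, c_in, 2, 2, 2), fan_in, c_out)
        self.w = Param(w)
        self.b = Param(np.zeros(c_out))
        self._cache = None

    def forward(self, x, train=False):
        n, c, d, h, w = x.shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        xt = x[:, :, : 2 * d2, : 2 * h2, : 2 * w2]
        blocks = xt.reshape(n, c, d2, 2, h2, 2, w2, 2)
        # (N, d2, h2, w2, C, 2, 2, 2)
        patches = blocks.transpose(0, 2, 4, 6, 1, 3, 5, 7)
        out = np.tensordot(patches, self.w.value, axes=([4, 5, 6, 7], [1, 2, 3, 4]))
        self._cache = (patches, x.shape)
        return np.moveaxis(out, -1, 1) + self.b.value[None, :, None, None, None]

    def backward(self, grad):
        patches, in_shape = self._cache
        n, c, d, h, w = in_shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        gm = np.moveaxis(grad, 1, -1)  # (N, d2, h2, w2, C_out)
        self.w.grad += np.tensordot(gm, patches, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
        self.b.grad += grad.sum(axis=(0, 2, 3, 4))
        dp = np.tensordot(gm, self.w.value, axes=([4], [0]))
        dblocks = dp.transpose(0, 4, 1, 5, 2, 6, 3, 7)
        dx = np.zeros(in_shape, dtype=grad.dtype)
        dx[:, :, : 2 * d2, : 2 * h2, : 2 * w2] = dblocks.reshape(
            n, c, 2 * d2, 2 * h2, 2 * w2)
        return dx

    @property
    def params(self):
        return [self.w, self.b]


class DoublingConvT3d(Layer):
    """Transposed 3D convolution with kernel 2, stride 2.

    Each input voxel expands to a 2x2x2 output block. ``out_dims`` may request
    one extra trailing voxel per axis (for odd targets); that slice receives
    only the bias, mirroring output padding in standard frameworks, so a
    round trip through the halving convolution restores the original shape.
    """

    def __init__(self, c_in: int, c_out: int, out_dims: tuple,
                 rng: np.random.Generator, init: str = "he"):
        fan_in = c_in
        if init == "he":
            w = _he_init(rng, (c_in, c_out, 2, 2, 2), fan_in)
        else:
            w = _glorot_init(rng, (c_in, c_out, 2, 2, 2), fan_in, c_out * 8)
        self.w = Param(w)
        self.b = Param(np.zeros(c_out))
        self.out_dims = tuple(out_dims)
        self._cache = None

    def forward(self, x, train=False):
        n, c, d, h, w = x.shape
        od, oh, ow = self.out_dims
        if not (od in (2 * d, 2 * d + 1) and oh in (2 * h, 2 * h + 1)
                and ow in (2 * w, 2 * w + 1)):
            raise ValueError(f"out_dims {self.out_dims} incompatible with input {(d, h, w)}")
        zm = np.moveaxis(x, 1, -1)  # (N, d, h, w, C_in)
        y = np.tensordot(zm, self.w.value, axes=([4], [0]))  # (N,d,h,w,C_out,2,2,2)
        y = y.transpose(0, 4, 1, 5, 2, 6, 3, 7).reshape(n, -1, 2 * d, 2 * h, 2 * w)
        if (od, oh, ow) != (2 * d, 2 * h, 2 * w):
            y = np.pad(y, ((0, 0), (0, 0), (0, od - 2 * d),
                           (0, oh - 2 * h), (0, ow - 2 * w)))
        self._cache = (zm, x.shape)
        return y + self.b.value[None, :, None, None, None]

    def backward(self, grad):
        zm, in_shape = self._cache
        n, c, d, h, w = in_shape
        g = grad[:, :, : 2 * d, : 2 * h, : 2 * w]
        c_out = g.shape[1]
        g6 = g.reshape(n, c_out, d, 2, h, 2, w, 2).transpose(0, 2, 4, 6, 1, 3, 5, 7)
        self.w.grad += np.tensordot(zm, g6, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
        self.b.grad += grad.sum(axis=(0, 2, 3, 4))
        dz = np.tensordot(g6, self.w.value, axes=([4, 5, 6, 7], [1, 2, 3, 4]))
        return np.moveaxis(dz, -1, 1)

    @property
    def params(self):
        return [self.w, self.b]


class StridedConv3d(Layer):
    """General valid 3D convolution (default kernel 3, stride 2).

    Implemented as one strided-slice contraction per kernel offset; with a
    3x3x3 kernel that is 27 small matrix products, which is fast at the
    latent-grid sizes this layer sees.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3, stride: int = 2, init: str = "he"):
        self.k = kernel
        self.s = stride
        fan_in = c_in * kernel ** 3
        if init == "he":
            w = _he_init(rng, (c_out, c_in, kernel, kernel, kernel), fan_in)
        else:
            w = _glorot_init(rng, (c_out, c_in, kernel, kernel, kernel), fan_in, c_out)
        self.w = Param(w)
        self.b = Param(np.zeros(c_out))
        self._cache = None

    @staticmethod
    def out_dim(d: int, kernel: int = 3, stride: int = 2) -> int:
        if d < kernel:
            raise ValueError(f"spatial dim {d} smaller than kernel {kernel}")
        return (d - kernel) // stride + 1

    def forward(self, x, train=False):
        n, c, d, h, w = x.shape
        k, s = self.k, self.s
        od, oh, ow = (self.out_dim(v, k, s) for v in (d, h, w))
        out = np.zeros((n, od, oh, ow, self.w.value.shape[0]), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    xs = x[:, :, i: i + s * (od - 1) + 1: s,
                           j: j + s * (oh - 1) + 1: s,
                           l: l + s * (ow - 1) + 1: s]
                    out += np.tensordot(xs, self.w.value[:, :, i, j, l], axes=([1], [1]))
        self._cache = (x, (od, oh, ow))
        return np.moveaxis(out, -1, 1) + self.b.value[None, :, None, None, None]

    def backward(self, grad):
        x, (od, oh, ow) = self._cache
        k, s = self.k, self.s
        gm = np.moveaxis(grad, 1, -1)
        dx = np.zeros_like(x)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    sl = (slice(None), slice(None),
                          slice(i, i + s * (od - 1) + 1, s),
                          slice(j, j + s * (oh - 1) + 1, s),
                          slice(l, l + s * (ow - 1) + 1, s))
                    xs = x[sl]
                    self.w.grad[:, :, i, j, l] += np.tensordot(
                        gm, xs, axes=([0, 1, 2, 3], [0, 2, 3, 4]))
                    dx[sl] += np.moveaxis(
                        np.tensordot(gm, self.w.value[:, :, i, j, l], axes=([4], [0])),
                        -1, 1)
        self.b.grad += grad.sum(axis=(0, 2, 3, 4))
        return dx

    @property
    def params(self):
        return [self.w, self.b]


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 init: str = "he"):
        if init == "he":
            w = _he_init(rng, (n_in, n_out), n_in)
        else:
            w = _glorot_init(rng, (n_in, n_out), n_in, n_out)
        self.w = Param(w)
        self.b = Param(np.zeros(n_out))
        self._x = None

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T

    @property
    def params(self):
        return [self.w, self.b]


class BatchNorm(Layer):
    """Batch normalisation over the batch (and spatial axes for volumes).

    Training uses batch statistics and updates exponential running statistics
    (momentum 0.9); inference uses the stored running statistics, so
    prediction is deterministic regardless of batch composition.
    """

    def __init__(self, n_channels: int, spatial: bool, momentum: float = 0.9,
                 eps: float = 1e-5):
        self.gamma = Param(np.ones(n_channels))
        self.beta = Param(np.zeros(n_channels))
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)
        self.spatial = spatial
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def _shape(self, a: np.ndarray) -> np.ndarray:
        return a[None, :, None, None, None] if self.spatial else a[None, :]

    def forward(self, x, train=False):
        axes = (0, 2, 3, 4) if self.spatial else (0,)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._shape(mu)) * self._shape(ivstd)
        self._cache = (xhat, ivstd, axes, train)
        return self._shape(self.gamma.value) * xhat + self._shape(self.beta.value)

    def backward(self, grad):
        xhat, ivstd, axes, train = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        dxhat = grad * self._shape(self.gamma.value)
        if not train:
            return dxhat * self._shape(ivstd)
        m = np.prod([xhat.shape[a] for a in axes])
        dx = (dxhat - dxhat.mean(axis=axes, keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True))
        return dx * self._shape(ivstd)

    @property
    def params(self):
        return [self.gamma, self.beta]

    def state_arrays(self):
        return [self.running_mean, self.running_var]


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class ReLU(Layer):
    def forward(self, x, train=False):
        self._pos = x > 0
        return x * self._pos

    def backward(self, grad):
        return grad * self._pos


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = sigmoid(x)
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    def state_arrays(self):
        return [a for layer in self.layers for a in layer.state_arrays()]

    def get_state(self) -> list[np.ndarray]:
        return ([p.value.copy() for p in self.params]
                + [a.copy() for a in self.state_arrays()])

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.params
        for p, v in zip(params, state[: len(params)]):
            p.value[...] = v
        for a, v in zip(self.state_arrays(), state[len(params):]):
            a[...] = v


class Adam:
    """Adaptive-moment stochastic gradient descent (standard bias correction)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad ** 2
            p.value -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over every element; returns (loss, dL/dpred)."""
    diff = pred - target
    loss = float(np.mean(diff ** 2))
    return loss, 2.0 * diff / diff.size


def bce_with_logits(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on raw logits; returns (loss, dL/dlogits)."""
    z = logits.ravel()
    y = labels.ravel().astype(float)
    # log(1 + exp(-|z|)) form avoids overflow
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = (sigmoid(z) - y) / z.size
    return loss, grad.reshape(logits.shape)
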