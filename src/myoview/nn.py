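"""Minimal numpy layer engine with manual backpropagation.

Feature-image inputs here are tiny (channels × a dozen features), so a
dependency-free numpy implementation of the handful of layer types the
architectures need — dense, 2-D convolution with tied weights, locally
connected 2-D layers (convolution with untied weights per spatial
position), batch normalization and dropout — trains these networks in
seconds on one CPU.  Convolution and locally connected layers share an
im2col patch extraction so both reduce to (batched) matrix products.

Conventions: activations are ``(N, C, H, W)`` for image layers and
``(N, D)`` for dense layers; ``forward(x, train=...)`` caches what
``backward(dy)`` needs; parameters are :class:`Param` objects holding the
value and its accumulated gradient.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array and its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Extract 'same'-padded kh×kw patches: (N,C,H,W) → (N, H·W, C·kh·kw)."""
    n, c, h, w = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = np.empty((n, c, kh * kw, h * w))
    k = 0
    for i in range(kh):
        for j in range(kw):
            cols[:, :, k, :] = xp[:, :, i : i + h, j : j + w].reshape(n, c, h * w)
            k += 1
    # → (N, H·W, C·kh·kw)
    return cols.reshape(n, c * kh * kw, h * w).transpose(0, 2, 1)


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add patches back)."""
    n, c, h, w = x_shape
    ph, pw = kh // 2, kw // 2
    dxp = np.zeros((n, c, h + 2 * ph, w + 2 * pw))
    dcols = dcols.transpose(0, 2, 1).reshape(n, c, kh * kw, h * w)
    k = 0
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + h, j : j + w] += dcols[:, :, k, :].reshape(n, c, h, w)
            k += 1
    return dxp[:, :, ph : ph + h, pw : pw + w]


class Conv2D(Layer):
    """2-D convolution, 'same' zero padding, stride 1, tied weights."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator) -> None:
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        self.w = Param(_he_init(rng, (fan_in, out_channels), fan_in), "conv_w")
        self.b = Param(np.zeros(out_channels), "conv_b")
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(
                f"Conv2D expected {self.in_channels} input channels, got {c}"
            )
        cols = _im2col(x, self.k, self.k)  # (N, P, CKK)
        out = cols @ self.w.value + self.b.value  # (N, P, K)
        self._cache = (cols, x.shape)
        return out.transpose(0, 2, 1).reshape(n, self.out_channels, h, w)

    def backward(self, dy):
        cols, x_shape = self._cache
        n, _, h, w = x_shape
        dy_mat = dy.reshape(n, self.out_channels, h * w).transpose(0, 2, 1)
        self.w.grad += np.einsum("npq,npk->qk", cols, dy_mat)
        self.b.grad += dy_mat.sum(axis=(0, 1))
        dcols = dy_mat @ self.w.value.T
        return _col2im(dcols, x_shape, self.k, self.k)


class LocallyConnected2D(Layer):
    """Convolution-like layer with untied weights per spatial position."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 spatial: tuple[int, int], rng: np.random.Generator) -> None:
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        self.spatial = spatial
        p = spatial[0] * spatial[1]
        fan_in = in_channels * kernel_size * kernel_size
        self.w = Param(_he_init(rng, (p, fan_in, out_channels), fan_in), "lc_w")
        self.b = Param(np.zeros((p, out_channels)), "lc_b")
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if (h, w) != self.spatial or c != self.in_channels:
            raise ValueError(
                f"LocallyConnected2D expected input {self.in_channels}×{self.spatial},"
                f" got {c}×{(h, w)}"
            )
        cols = _im2col(x, self.k, self.k)  # (N, P, CKK)
        out = np.einsum("npq,pqk->npk", cols, self.w.value) + self.b.value
        self._cache = (cols, x.shape)
        return out.transpose(0, 2, 1).reshape(n, self.out_channels, h, w)

    def backward(self, dy):
        cols, x_shape = self._cache
        n, _, h, w = x_shape
        dy_mat = dy.reshape(n, self.out_channels, h * w).transpose(0, 2, 1)
        self.w.grad += np.einsum("npq,npk->pqk", cols, dy_mat)
        self.b.grad += dy_mat.sum(axis=0)
        dcols = np.einsum("npk,pqk->npq", dy_mat, self.w.value)
        return _col2im(dcols, x_shape, self.k, self.k)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator) -> None:
        self.in_features = in_features
        self.w = Param(_he_init(rng, (in_features, out_features), in_features),
                       "dense_w")
        self.b = Param(np.zeros(out_features), "dense_b")
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        if x.shape[1] != self.in_features:
            raise ValueError(
                f"Dense expected {self.in_features} input features, got {x.shape[1]}"
            )
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class BatchNorm(Layer):
    """Batch normalization over (N,) or (N, H, W) per channel/feature.

    Training uses batch statistics and updates exponential running moments;
    inference uses the running moments, making outputs independent of batch
    composition.
    """

    def __init__(self, n_channels: int, image: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> None:
        self.image = image
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(n_channels), "bn_gamma")
        self.beta = Param(np.zeros(n_channels), "bn_beta")
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def _axes(self):
        return (0, 2, 3) if self.image else (0,)

    def _shape(self, x):
        return (1, -1, 1, 1) if self.image else (1, -1)

    def forward(self, x, train=False):
        axes = self._axes()
        shp = self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shp)) * inv_std.reshape(shp)
        self._cache = (xhat, inv_std, train)
        return self.gamma.value.reshape(shp) * xhat + self.beta.value.reshape(shp)

    def backward(self, dy):
        xhat, inv_std, train = self._cache
        axes = self._axes()
        shp = self._shape(dy)
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.value.reshape(shp) * inv_std.reshape(shp)
        if not train:
            return g * dy
        m = dy.size / dy.shape[1] if dy.ndim == 2 else (
            dy.shape[0] * dy.shape[2] * dy.shape[3])
        mean_dy = dy.mean(axis=axes).reshape(shp)
        mean_dy_xhat = (dy * xhat).mean(axis=axes).reshape(shp)
        return g * (dy - mean_dy - xhat * mean_dy_xhat)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; active only in training mode."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        if not (0 <= rate < 1):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = float(-np.mean(np.log(p[np.arange(n), y] + 1e-300)))
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def numerical_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar ``f`` w.r.t. array ``x``
    (test utility)."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
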