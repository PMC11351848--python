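"""Minimal NumPy CNN layers with hand-written backpropagation.

Everything the segmentation network needs: 2D convolution (im2col + GEMM),
batch normalization with running statistics, ReLU, 2x2 max pooling, 2x
nearest-neighbour upsampling and a sigmoid head, plus an Adam optimizer
with global-norm gradient clipping.

Layers operate on channels-last (NHWC) float32 tensors: with channels
innermost, the im2col gather and the col2im scatter-add touch contiguous
memory, which is what keeps a pure-NumPy training loop usable on one CPU.
The network module converts from the NCHW interface at its boundary. Each
layer caches what its backward pass needs; ``backward`` consumes the
gradient w.r.t. the layer output and returns the gradient w.r.t. its input.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "ConvUnit",
    "MaxPool2",
    "Upsample2",
    "Sigmoid",
    "Adam",
    "global_grad_norm",
    "clip_gradients",
]


class Layer:
    """Base: parameterless unless ``params()`` is overridden."""

    def params(self) -> List[np.ndarray]:
        return []

    def grads(self) -> List[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """Same-padding 2D convolution on NHWC input, kernel 1x1 or 3x3."""

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.cin, self.cout, self.k = cin, cout, kernel
        fan_in = cin * kernel * kernel
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.W = rng.normal(0.0, std, (fan_in, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if self.k == 1:
            return x.reshape(n * h * w, c)
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        cols = np.empty((n, h, w, 9 * c), dtype=np.float32)
        for ki in range(3):
            for kj in range(3):
                cols[..., (ki * 3 + kj) * c : (ki * 3 + kj + 1) * c] = xp[
                    :, ki : ki + h, kj : kj + w, :
                ]
        return cols.reshape(n * h * w, 9 * c)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[-1] != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {x.shape[-1]}")
        n, h, w, _ = x.shape
        cols = self._im2col(x)
        out = cols @ self.W + self.b
        self._cache = (cols, x.shape) if train else None
        return out.reshape(n, h, w, self.cout)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, h, w, c = xshape
        g = gout.reshape(n * h * w, self.cout)
        self.dW[...] = cols.T @ g
        self.db[...] = g.sum(axis=0)
        dcols = g @ self.W.T  # (n*h*w, k*k*cin)
        if self.k == 1:
            return dcols.reshape(n, h, w, c)
        dcols = dcols.reshape(n, h, w, 9 * c)
        dxp = np.zeros((n, h + 2, w + 2, c), dtype=np.float32)
        for ki in range(3):
            for kj in range(3):
                dxp[:, ki : ki + h, kj : kj + w, :] += dcols[
                    ..., (ki * 3 + kj) * c : (ki * 3 + kj + 1) * c
                ]
        return dxp[:, 1 : 1 + h, 1 : 1 + w, :]


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W) on NHWC input."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat, inv)
        return (self.gamma * xhat + self.beta).astype(np.float32)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m = gout.shape[0] * gout.shape[1] * gout.shape[2]
        self.dgamma[...] = (gout * xhat).sum(axis=(0, 1, 2))
        self.dbeta[...] = gout.sum(axis=(0, 1, 2))
        gxhat = gout * self.gamma
        dx = (
            inv
            / m
            * (
                m * gxhat
                - gxhat.sum(axis=(0, 1, 2), keepdims=True)
                - xhat * (gxhat * xhat).sum(axis=(0, 1, 2), keepdims=True)
            )
        )
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask


class ConvUnit(Layer):
    """conv -> ReLU -> BN (the default order) or conv -> BN -> ReLU."""

    def __init__(
        self,
        cin: int,
        cout: int,
        rng: np.random.Generator,
        kernel: int = 3,
        order: str = "conv-relu-bn",
    ):
        if order not in ("conv-relu-bn", "conv-bn-relu"):
            raise ValueError(f"unknown unit order {order!r}")
        self.conv = Conv2d(cin, cout, kernel, rng)
        self.relu = ReLU()
        self.bn = BatchNorm2d(cout)
        self.order = order

    @property
    def _seq(self) -> Sequence[Layer]:
        if self.order == "conv-relu-bn":
            return (self.conv, self.relu, self.bn)
        return (self.conv, self.bn, self.relu)

    def params(self):
        return self.conv.params() + self.bn.params()

    def grads(self):
        return self.conv.grads() + self.bn.grads()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self._seq:
            x = layer.forward(x, train)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self._seq):
            gout = layer.backward(gout)
        return gout


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (even spatial sizes only), NHWC."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial size must be even for 2x2 pooling, got {h}x{w}")
        win = x.reshape(n, h // 2, 2, w // 2, 2, c)
        flat = win.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        idx, xshape = self._cache
        n, h, w, c = xshape
        flat = np.zeros((n, h // 2, w // 2, c, 4), dtype=np.float32)
        np.put_along_axis(flat, idx[..., None], gout[..., None], axis=-1)
        win = flat.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(win.reshape(n, h, w, c))


class Upsample2(Layer):
    """Parameter-free 2x nearest-neighbour upsampling, NHWC."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, h, w, c = gout.shape
        return (
            gout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))
        ).astype(np.float32)


class Sigmoid(Layer):
    """Logistic head; outputs pinched into the open interval (0, 1).

    float32 saturates to exactly 0/1 for |logit| > ~17, which would break
    the probability contract and the BCE epsilon convention downstream.
    """

    CLAMP = 1e-7

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-x.astype(np.float64)))
        out = np.clip(out, self.CLAMP, 1.0 - self.CLAMP).astype(np.float32)
        if train:
            self._out = out
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return (gout * self._out * (1.0 - self._out)).astype(np.float32)


def global_grad_norm(grads: Sequence[np.ndarray]) -> float:
    return float(np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads)))


def clip_gradients(grads: Sequence[np.ndarray], max_norm: float) -> float:
    """In-place global-norm clipping; returns the post-clip norm."""
    norm = global_grad_norm(grads)
    if norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for g in grads:
            g *= scale
        norm = max_norm
    return norm


class Adam:
    """Adam with per-call learning rate (so schedules can change it)."""

    def __init__(
        self,
        params: Sequence[np.ndarray],
        lr: float = 1e-4,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
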