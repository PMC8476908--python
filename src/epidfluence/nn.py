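"""A small, dependency-free neural-network engine on NumPy.

Implements exactly the pieces the four-branch fluence classifier needs:
3x3 same-padding convolution (im2col via stride tricks), ReLU, 2x2 max
pooling, global average pooling, dense layers, softmax cross-entropy and
Adam.  All math is float32; initialisation and batching are driven by an
explicit ``numpy`` generator, so training is bit-reproducible for a
fixed seed on a fixed BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_F32 = np.float32


class Layer:
    """Base layer: forward caches what backward needs."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 convolution, stride 1, same padding (spatial size preserved).

    Channels-last (N, H, W, C) layout throughout: im2col then one GEMM,
    which is the fastest formulation BLAS offers for small channel counts.
    The kernel is stored flattened as ``(C_in * 9, C_out)``.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / (c_in * 9))  # He initialisation for ReLU nets
        self.w = (rng.standard_normal((c_in * 9, c_out)) * scale).astype(_F32)
        self.b = np.zeros(c_out, dtype=_F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.params = [self.w, self.b]
        self.grads = [self.dw, self.db]
        self.c_in, self.c_out = c_in, c_out

    @staticmethod
    def _im2col(x: np.ndarray) -> np.ndarray:
        """(N, H, W, C) -> (N*H*W, C*9) patch matrix (same padding)."""
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (N,H,W,C,3,3)
        return win.reshape(n * h * w, c * 9)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        n, h, w, _ = x.shape
        self._col = self._im2col(x)
        out = self._col @ self.w + self.b
        return out.reshape(n, h, w, self.c_out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, _ = self._shape
        g2 = grad.reshape(n * h * w, self.c_out)
        self.dw[...] = self._col.T @ g2
        self.db[...] = g2.sum(axis=0)
        self._col = None
        # input gradient: full correlation with the spatially flipped kernel
        wk = self.w.reshape(self.c_in, 3, 3, self.c_out)
        wf = wk[:, ::-1, ::-1, :].transpose(3, 1, 2, 0).reshape(
            self.c_out * 9, self.c_in
        )
        gcol = self._im2col(grad)
        return (gcol @ wf).reshape(n, h, w, self.c_in)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, _F32(0))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, _F32(0))


class MaxPool2(Layer):
    """2x2 max pooling, stride 2: halves each spatial side (NHWC)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial size {h}x{w} not divisible by 2")
        v = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = v.max(axis=(2, 4))
        self._mask = v == out[:, :, None, :, None, :]
        self._shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        g = np.where(self._mask, grad[:, :, None, :, None, :], _F32(0))
        return g.reshape(n, h, w, c)


class GlobalAvgPool(Layer):
    """Reduce each channel to its spatial mean: (N, H, W, C) -> (N, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return np.broadcast_to(
            (grad / (h * w))[:, None, None, :], self._shape
        ).astype(_F32, copy=False)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(_F32)
        self.b = np.zeros(n_out, dtype=_F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.params = [self.w, self.b]
        self.grads = [self.dw, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.w.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(
    logits: np.ndarray, y_idx: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = len(y_idx)
    loss = float(-np.mean(np.log(p[np.arange(n), y_idx] + 1e-12)))
    grad = p
    grad[np.arange(n), y_idx] -= 1.0
    return loss, (grad / n).astype(_F32)


class Adam:
    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]
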