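"""Minimal CPU neural-network primitives (numpy, explicit backprop).

Implements exactly what the multi-task segmenter needs: same-padded 3x3 and
1x1 convolutions via im2col, ReLU, inverted dropout, 2x2 average pooling,
nearest-neighbour upsampling, softmax cross-entropy, and Adam. Layers cache
what their backward pass needs; gradients accumulate into ``Param.grad`` so a
joint loss over two heads can backpropagate additively through the shared
trunk.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Conv2D", "ReLU", "Dropout", "AvgPool2", "Upsample2",
    "Adam", "softmax", "cross_entropy_grad",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray, dtype=np.float64):
        self.value = np.asarray(value, dtype=dtype)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Conv2D:
    """Same-padded convolution, kernel size 1 or 3, stride 1.

    Input/output layout ``(N, C, H, W)``. Weight shape ``(C_out, C_in * k * k)``
    so the Fisher-score machinery can treat the kernel as a flat parameter
    block.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 dtype=np.float64):
        if k not in (1, 3):
            raise ValueError("kernel size must be 1 or 3")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, fan_in)), dtype)
        self.b = Param(np.zeros(c_out), dtype)
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        """Columns in (F, N*L) layout with F = (c, ky, kx) so the convolution
        is one large GEMM."""
        n, c, h, w = x.shape
        if self.k == 1:
            return np.ascontiguousarray(x.transpose(1, 0, 2, 3)).reshape(c, -1)
        xp = np.zeros((c, n, h + 2, w + 2), dtype=x.dtype)
        xp[:, :, 1:-1, 1:-1] = x.transpose(1, 0, 2, 3)
        cols = np.empty((c, 3, 3, n, h, w), dtype=x.dtype)
        for ky in range(3):
            for kx in range(3):
                cols[:, ky, kx] = xp[:, :, ky:ky + h, kx:kx + w]
        return cols.reshape(c * 9, n * h * w)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        cols = self._im2col(x)
        y = self.W.value @ cols + self.b.value[:, None]
        if train:
            self._cols, self._shape = cols, (n, c, h, w)
        return y.reshape(self.c_out, n, h, w).transpose(1, 0, 2, 3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dyf = np.ascontiguousarray(
            dy.transpose(1, 0, 2, 3)).reshape(self.c_out, n * h * w)
        self.W.grad += dyf @ self._cols.T
        self.b.grad += dyf.sum(axis=1)
        dcols = (self.W.value.T @ dyf).reshape(c, -1, n, h, w)
        if self.k == 1:
            return dcols.reshape(c, n, h, w).transpose(1, 0, 2, 3)
        dcols = dcols.reshape(c, 3, 3, n, h, w)
        dxp = np.zeros((c, n, h + 2, w + 2), dtype=dcols.dtype)
        for ky in range(3):
            for kx in range(3):
                dxp[:, :, ky:ky + h, kx:kx + w] += dcols[:, ky, kx]
        return dxp[:, :, 1:-1, 1:-1].transpose(1, 0, 2, 3)


class ReLU:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dropout:
    """Inverted dropout; active when a generator is supplied (training or MC)."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None,
                train: bool = False) -> np.ndarray:
        if rng is None or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class AvgPool2:
    """2x2 average pooling (even spatial dims required)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x2 pooling")
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) / 4.0


class Upsample2:
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy_grad(
    logits: np.ndarray, target: np.ndarray, pixel_weight: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Pixel-wise softmax cross-entropy, averaged with optional pixel weights.

    ``logits``: (N, K, H, W); ``target``: (N, H, W) integer classes. Returns
    (loss, dloss/dlogits). Weights are normalized so the loss is a weighted
    mean over pixels.
    """
    n, k, h, w = logits.shape
    p = softmax(logits, axis=1)
    onehot_ll = np.take_along_axis(p, target[:, None], axis=1)[:, 0]
    logp = -np.log(np.clip(onehot_ll, 1e-12, None))
    if pixel_weight is None:
        pixel_weight = np.ones((n, h, w))
    wsum = pixel_weight.sum()
    if wsum <= 0:
        return 0.0, np.zeros_like(logits)
    loss = float((logp * pixel_weight).sum() / wsum)
    grad = p.copy()
    np.put_along_axis(grad, target[:, None], (onehot_ll - 1.0)[:, None], axis=1)
    grad *= (pixel_weight / wsum)[:, None]
    return loss, grad


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - self.b1) * (p.grad - m)
            v += (1 - self.b2) * (p.grad ** 2 - v)
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
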