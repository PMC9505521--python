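"""Minimal NumPy neural-network kernels for the segmentation model.

Explicit forward/backward layers in NHWC float32 layout.  Convolutions run
as im2col matrix multiplications (BLAS-backed); the data gradient of a
same-padded stride-1 convolution is itself a convolution with the spatially
flipped, channel-transposed kernel, so no scatter-add col2im is needed.
2x2 stride-2 transposed convolutions and max-pools reduce to reshapes
because their windows do not overlap.

Weight initialisation is He-normal (fan-in), suited to the ReLU
nonlinearities used throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "ConvTranspose2x2",
    "MaxPool2x2",
    "ReLU",
    "Adam",
    "softmax",
    "cross_entropy_with_logits",
]


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Same-padded k x k patches of NHWC ``x`` as an (N*H*W, k*k*C) matrix."""
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    # windows: (N, H, W, C, k, k) -> (N*H*W, k*k*C) with kk-major ordering
    win = sliding_window_view(xp, (k, k), axis=(1, 2))
    n, h, w, c = x.shape
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, k * k * c)
    return np.ascontiguousarray(cols)


class Layer:
    """Base class: parameters and gradients live in dicts keyed by name."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def param_count(self) -> int:
        return sum(p.size for p in self.params.values())


class Conv2D(Layer):
    """Same-padded stride-1 convolution with odd kernel size (1 or 3 here)."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int, rng: np.random.Generator) -> None:
        super().__init__()
        if in_ch <= 0 or out_ch <= 0:
            raise ValueError("channel counts must be positive")
        if ksize % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, ksize
        fan_in = ksize * ksize * in_ch
        self.params["w"] = _he_init(rng, (fan_in, out_ch), fan_in)
        self.params["b"] = np.zeros(out_ch, dtype=np.float32)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, h, w, _ = x.shape
        if self.k == 1:
            y = x.reshape(-1, self.in_ch) @ self.params["w"]
        else:
            y = _im2col(x, self.k) @ self.params["w"]
        return (y + self.params["b"]).reshape(n, h, w, self.out_ch)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        n, h, w, _ = x.shape
        dy_flat = dy.reshape(-1, self.out_ch)
        self.grads["b"] = dy_flat.sum(axis=0)
        if self.k == 1:
            self.grads["w"] = x.reshape(-1, self.in_ch).T @ dy_flat
            dx = dy_flat @ self.params["w"].T
            return dx.reshape(x.shape)
        cols = _im2col(x, self.k)
        self.grads["w"] = cols.T @ dy_flat
        # data gradient: convolve dy with the flipped, transposed kernel
        w_k = self.params["w"].reshape(self.k, self.k, self.in_ch, self.out_ch)
        w_flip = w_k[::-1, ::-1].transpose(0, 1, 3, 2).reshape(-1, self.in_ch)
        dx = _im2col(dy, self.k) @ np.ascontiguousarray(w_flip)
        return dx.reshape(x.shape)


class ConvTranspose2x2(Layer):
    """2x2 stride-2 transposed convolution: doubles spatial size."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator) -> None:
        super().__init__()
        if in_ch <= 0 or out_ch <= 0:
            raise ValueError("channel counts must be positive")
        self.in_ch, self.out_ch = in_ch, out_ch
        self.params["w"] = _he_init(rng, (in_ch, 4 * out_ch), in_ch)
        self.params["b"] = np.zeros(out_ch, dtype=np.float32)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, h, w, _ = x.shape
        t = x.reshape(-1, self.in_ch) @ self.params["w"]
        t = t.reshape(n, h, w, 2, 2, self.out_ch).transpose(0, 1, 3, 2, 4, 5)
        return t.reshape(n, 2 * h, 2 * w, self.out_ch) + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        n, h, w, _ = x.shape
        dt = dy.reshape(n, h, 2, w, 2, self.out_ch).transpose(0, 1, 3, 2, 4, 5)
        dt = dt.reshape(-1, 4 * self.out_ch)
        self.grads["b"] = dy.reshape(-1, self.out_ch).sum(axis=0)
        self.grads["w"] = x.reshape(-1, self.in_ch).T @ dt
        dx = dt @ self.params["w"].T
        return dx.reshape(x.shape)


class MaxPool2x2(Layer):
    """2x2 stride-2 max pooling; gradient routed to the arg-max pixel."""

    def __init__(self) -> None:
        super().__init__()
        self._idx: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial size must be even for 2x2 pooling, got {h}x{w}")
        self._shape = x.shape
        blocks = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        blocks = blocks.reshape(n, h // 2, w // 2, c, 4)
        self._idx = blocks.argmax(axis=-1)
        return np.take_along_axis(blocks, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        dblocks = np.zeros((n, h // 2, w // 2, c, 4), dtype=dy.dtype)
        np.put_along_axis(dblocks, self._idx[..., None], dy[..., None], axis=-1)
        dx = dblocks.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dx.reshape(n, h, w, c)


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, np.float32(0))


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_with_logits(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Mean per-pixel cross-entropy on integer labels.

    Returns (loss, pixel accuracy, gradient w.r.t. logits).
    """
    probs = softmax(logits.astype(np.float64))
    n_pix = labels.size
    flat = probs.reshape(n_pix, -1)
    lab = labels.reshape(-1)
    picked = flat[np.arange(n_pix), lab]
    loss = float(-np.log(np.clip(picked, 1e-12, None)).mean())
    acc = float((flat.argmax(axis=1) == lab).mean())
    grad = flat.copy()
    grad[np.arange(n_pix), lab] -= 1.0
    grad /= n_pix
    return loss, acc, grad.reshape(logits.shape).astype(logits.dtype)


class Adam:
    """Adam optimiser over a flat dict of named parameter arrays."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, p in self.params.items():
            g = grads[k].astype(np.float32)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            m_hat = self.m[k] / b1t
            v_hat = self.v[k] / b2t
            p -= (self.lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(np.float32)
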