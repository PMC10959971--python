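"""Minimal NumPy inference layers for the backbone architectures.

Only the forward pass is needed: convolution is evaluated by im2col plus a
single BLAS matmul, pooling by strided window views.  All arrays are
``float32``; activations are ``(C, H, W)`` for a single image.
"""

from __future__ import annotations

import numpy as np

__all__ = ["conv2d", "maxpool2d", "avgpool2d", "global_avg_pool", "relu",
           "linear", "batchnorm", "he_conv", "he_fc"]


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, padding: int):
    """Unfold ``(C, H, W)`` into ``(out_h * out_w, C * kh * kw)`` patches."""
    if padding:
        x = np.pad(x, ((0, 0), (padding, padding), (padding, padding)))
    c, h, w = x.shape
    out_h = (h - kh) // stride + 1
    out_w = (w - kw) // stride + 1
    view = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    view = view[:, ::stride, ::stride]              # (C, out_h, out_w, kh, kw)
    cols = view.transpose(1, 2, 0, 3, 4).reshape(out_h * out_w, c * kh * kw)
    return np.ascontiguousarray(cols), out_h, out_w


def conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None,
           stride: int = 1, padding: int = 0) -> np.ndarray:
    """2-D convolution (cross-correlation); ``w`` is ``(C_out, C_in, kh, kw)``."""
    c_out, c_in, kh, kw = w.shape
    if x.shape[0] != c_in:
        raise ValueError(f"expected {c_in} input channels, got {x.shape[0]}")
    if kh == kw == 1 and padding == 0:
        # 1x1 conv: pure channel mixing, skip the unfold.
        c, h, w_ = x.shape
        xs = x[:, ::stride, ::stride]
        y = np.tensordot(w[:, :, 0, 0], xs, axes=([1], [0]))
        if b is not None:
            y += b[:, None, None]
        return np.ascontiguousarray(y, dtype=np.float32)
    cols, out_h, out_w = _im2col(x, kh, kw, stride, padding)
    y = cols @ w.reshape(c_out, -1).T
    if b is not None:
        y += b
    return np.ascontiguousarray(y.T.reshape(c_out, out_h, out_w))


def maxpool2d(x: np.ndarray, k: int, stride: int, padding: int = 0) -> np.ndarray:
    if padding:
        x = np.pad(x, ((0, 0), (padding, padding), (padding, padding)),
                   constant_values=-np.inf)
    view = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    return np.ascontiguousarray(view[:, ::stride, ::stride].max(axis=(3, 4)))


def avgpool2d(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    view = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    return np.ascontiguousarray(view[:, ::stride, ::stride].mean(axis=(3, 4)))


def global_avg_pool(x: np.ndarray) -> np.ndarray:
    """Spatial mean per channel, flattened row-major -> 1-D feature vector."""
    return x.mean(axis=(1, 2))


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def batchnorm(x: np.ndarray, gamma, beta, mean, var, eps: float = 1e-5):
    """Inference-mode batch normalization with stored statistics."""
    scale = gamma / np.sqrt(var + eps)
    shift = beta - mean * scale
    return x * scale[:, None, None] + shift[:, None, None]


def linear(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Fully connected layer; ``w`` is ``(out, in)``."""
    return w @ x + b


def he_conv(rng: np.random.Generator, c_out: int, c_in: int, k: int,
            bias: bool = False):
    """He-normal conv weights (fan-in scaling for ReLU stacks)."""
    fan_in = c_in * k * k
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                   size=(c_out, c_in, k, k)).astype(np.float32)
    b = np.zeros(c_out, dtype=np.float32) if bias else None
    return w, b


def he_fc(rng: np.random.Generator, n_out: int, n_in: int):
    w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in)).astype(np.float32)
    return w, np.zeros(n_out, dtype=np.float32)
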