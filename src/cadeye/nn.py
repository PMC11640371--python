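"""Minimal NumPy neural-network primitives (NHWC layout).

Only what the frozen feature extractors and the trainable heads need: 2-D and
depthwise convolution via strided patch views, the usual activations, and a
seeded He initializer. Convolutions use "same" padding semantics (output size
= ceil(input / stride)).
"""

from __future__ import annotations

import numpy as np

from .errors import ShapeError

__all__ = ["conv2d", "depthwise_conv2d", "relu", "relu6", "swish", "sigmoid",
           "softmax", "he_init"]


def relu(x):
    return np.maximum(x, 0.0)


def relu6(x):
    return np.clip(x, 0.0, 6.0)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def swish(x):
    return x * sigmoid(x)


def softmax(z, axis=-1):
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / max(fan_in, 1))).astype(np.float32)


def _pad_same(x: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    _, h, w, _ = x.shape
    out_h = -(-h // sh)
    out_w = -(-w // sw)
    ph = max((out_h - 1) * sh + kh - h, 0)
    pw = max((out_w - 1) * sw + kw - w, 0)
    if ph == 0 and pw == 0:
        return x
    return np.pad(x, ((0, 0), (ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2), (0, 0)))


def _patches(x: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """Strided view of shape (N, Ho, Wo, C, kh, kw) over a padded input."""
    v = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    return v[:, ::sh, ::sw]


def conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None,
           stride: int = 1) -> np.ndarray:
    """Same-padded 2-D convolution. ``x``: (N,H,W,Cin); ``w``: (kh,kw,Cin,Cout)."""
    if x.ndim != 4:
        raise ShapeError(f"conv2d expects a 4-axis NHWC batch, got {x.shape}")
    kh, kw, cin, cout = w.shape
    if x.shape[3] != cin:
        raise ShapeError(f"input has {x.shape[3]} channels, kernel expects {cin}")
    x = np.ascontiguousarray(x, dtype=np.float32)
    if kh == kw == 1:  # pointwise: a plain matmul, no patch extraction
        out = x[:, ::stride, ::stride, :] @ w[0, 0]
        if b is not None:
            out = out + b
        return out.astype(np.float32)
    xp = _pad_same(x, kh, kw, stride, stride)
    v = _patches(xp, kh, kw, stride, stride)       # (N,Ho,Wo,Cin,kh,kw)
    n, ho, wo = v.shape[:3]
    cols = v.transpose(0, 1, 2, 4, 5, 3).reshape(n * ho * wo, kh * kw * cin)
    wmat = w.transpose(0, 1, 2, 3).reshape(kh * kw * cin, cout)
    out = cols @ wmat
    out = out.reshape(n, ho, wo, cout)
    if b is not None:
        out = out + b
    return out.astype(np.float32)


def depthwise_conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None,
                     stride: int = 1) -> np.ndarray:
    """Same-padded depthwise convolution. ``w``: (kh,kw,C) — one kernel per channel."""
    if x.ndim != 4:
        raise ShapeError(f"depthwise_conv2d expects a 4-axis NHWC batch, got {x.shape}")
    kh, kw, c = w.shape
    if x.shape[3] != c:
        raise ShapeError(f"input has {x.shape[3]} channels, kernel expects {c}")
    xp = _pad_same(np.ascontiguousarray(x, dtype=np.float32), kh, kw, stride, stride)
    h, wd = xp.shape[1:3]
    ho = (h - kh) // stride + 1
    wo = (wd - kw) // stride + 1
    out = np.zeros((x.shape[0], ho, wo, c), dtype=np.float32)
    # shift-and-add over kernel taps keeps every operand contiguous
    wf = w.astype(np.float32)
    for i in range(kh):
        for j in range(kw):
            out += xp[:, i:i + ho * stride:stride, j:j + wo * stride:stride, :] * wf[i, j]
    if b is not None:
        out = out + b
    return out


def identity_depthwise_kernel(channels: int, k: int = 3) -> np.ndarray:
    """Depthwise kernel that reproduces its input exactly (center tap = 1)."""
    w = np.zeros((k, k, channels), dtype=np.float32)
    w[k // 2, k // 2, :] = 1.0
    return w
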