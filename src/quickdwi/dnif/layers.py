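"""Minimal NumPy layer primitives with exact analytic backward passes.

All tensors are NCHW.  Convolutions use zero padding to preserve spatial
size ("same"); the backward pass of a same-padded correlation is itself a
same-padded correlation with spatially flipped, channel-transposed
weights, so a single im2col kernel serves both directions.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv2d",
    "conv2d_backward",
    "conv_transpose2x2",
    "conv_transpose2x2_backward",
    "maxpool2x2",
    "maxpool2x2_backward",
    "relu",
    "relu_backward",
]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H*W, C*k*k) patch matrix with zero 'same' padding."""
    n, c, h, w = x.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)


def conv2d(x: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Same-padded 2D correlation.

    weight: (out_ch, in_ch, k, k); bias: (out_ch,).
    Returns (output, cached patch matrix for the weight gradient).
    """
    n, c, h, w = x.shape
    o, ci, k, _ = weight.shape
    assert ci == c, (ci, c)
    cols = _im2col(x, k)  # (N, HW, Ckk)
    y = cols @ weight.reshape(o, c * k * k).T + bias
    return y.transpose(0, 2, 1).reshape(n, o, h, w), cols


def conv2d_backward(
    dy: np.ndarray, cols: np.ndarray, weight: np.ndarray, x_shape: tuple[int, ...]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dweight, dbias) of :func:`conv2d`."""
    n, c, h, w = x_shape
    o, _, k, _ = weight.shape
    dy_mat = dy.reshape(n, o, h * w).transpose(0, 2, 1)  # (N, HW, O)
    dweight = np.einsum("npo,npk->ok", dy_mat, cols).reshape(weight.shape)
    dbias = dy.sum(axis=(0, 2, 3))
    # dx = same-correlation of dy with flipped, channel-transposed weights
    w_flip = weight[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (in, out, k, k)
    dx, _ = conv2d(dy, np.ascontiguousarray(w_flip), np.zeros(c))
    return dx, dweight, dbias


def conv_transpose2x2(x: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """2x2 stride-2 transposed convolution (learned upsampling).

    weight: (in_ch, out_ch, 2, 2).  Output spatial dims are doubled.
    """
    n, c, h, w = x.shape
    _, o, _, _ = weight.shape
    y = np.einsum("nchw,coab->nohawb", x, weight).reshape(n, o, 2 * h, 2 * w)
    return y + bias[None, :, None, None]


def conv_transpose2x2_backward(
    dy: np.ndarray, x: np.ndarray, weight: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, c, h, w = x.shape
    o = weight.shape[1]
    dy6 = dy.reshape(n, o, h, 2, w, 2)
    dx = np.einsum("nohawb,coab->nchw", dy6, weight)
    dweight = np.einsum("nchw,nohawb->coab", x, dy6)
    dbias = dy.sum(axis=(0, 2, 3))
    return dx, dweight, dbias


def maxpool2x2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2 max pooling; returns (pooled, argmax indices for backward)."""
    n, c, h, w = x.shape
    assert h % 2 == 0 and w % 2 == 0, "maxpool2x2 needs even spatial dims"
    patches = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = patches.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0], idx


def maxpool2x2_backward(dy: np.ndarray, idx: np.ndarray, x_shape: tuple[int, ...]) -> np.ndarray:
    n, c, h, w = x_shape
    dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
    np.put_along_axis(dflat, idx[..., None], dy[..., None], axis=-1)
    return (
        dflat.reshape(n, c, h // 2, w // 2, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h, w)
    )


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_backward(dy: np.ndarray, x: np.ndarray) -> np.ndarray:
    return dy * (x > 0)
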