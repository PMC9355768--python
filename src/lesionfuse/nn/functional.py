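"""Convolutional primitives with hand-written backward passes.

These are the only ops whose gradients are not composed from elementwise
pieces: 2-D convolution (im2col + einsum), transposed convolution, and
2x2 max pooling.  Layouts follow the NCHW convention.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, as_tensor

__all__ = ["conv2d", "conv_transpose2d", "max_pool2d"]


def _windows(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """Strided view (N, C, Ho, Wo, kh, kw) over a padded input."""
    w = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return w[:, :, ::stride, ::stride]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """Cross-correlation of ``x`` (N,C,H,W) with ``weight`` (O,C,kh,kw)."""
    x, weight = as_tensor(x), as_tensor(weight)
    n, c, h, w = x.shape
    o, ci, kh, kw = weight.shape
    if ci != c:
        raise ValueError(f"weight expects {ci} input channels, got {c}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = _windows(xp, kh, kw, stride)
    out = np.einsum("nchwij,ocij->nohw", win, weight.data, optimize=True)
    if bias is not None:
        out = out + bias.data[None, :, None, None]
    ho, wo = out.shape[2], out.shape[3]
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if weight.requires_grad:
            weight._accumulate(
                np.einsum("nchwij,nohw->ocij", win, g, optimize=True)
            )
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                        np.einsum("nohw,oc->nchw", g, weight.data[:, :, i, j],
                                  optimize=True)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    return Tensor._from_op(out, parents, backward)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None,
                     stride: int = 2) -> Tensor:
    """Transposed convolution; ``weight`` is (C_in, C_out, kh, kw).

    Output spatial size is ``(H-1)*stride + kh`` (no padding), which for the
    2x2/stride-2 decoders used here exactly doubles the resolution.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    n, c, h, w = x.shape
    ci, o, kh, kw = weight.shape
    if ci != c:
        raise ValueError(f"weight expects {ci} input channels, got {c}")
    ho, wo = (h - 1) * stride + kh, (w - 1) * stride + kw
    out = np.zeros((n, o, ho, wo))
    for i in range(kh):
        for j in range(kw):
            out[:, :, i:i + stride * (h - 1) + 1:stride,
                j:j + stride * (w - 1) + 1:stride] += \
                np.einsum("nchw,co->nohw", x.data, weight.data[:, :, i, j],
                          optimize=True)
    if bias is not None:
        out += bias.data[None, :, None, None]
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        dx = np.zeros_like(x.data) if x.requires_grad else None
        dw = np.empty_like(weight.data) if weight.requires_grad else None
        for i in range(kh):
            for j in range(kw):
                gs = g[:, :, i:i + stride * (h - 1) + 1:stride,
                       j:j + stride * (w - 1) + 1:stride]
                if dx is not None:
                    dx += np.einsum("nohw,co->nchw", gs, weight.data[:, :, i, j],
                                    optimize=True)
                if dw is not None:
                    dw[:, :, i, j] = np.einsum("nchw,nohw->co", x.data, gs,
                                               optimize=True)
        if dw is not None:
            weight._accumulate(dw)
        if dx is not None:
            x._accumulate(dx)

    return Tensor._from_op(out, parents, backward)


def max_pool2d(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping max pooling with window ``size`` x ``size``."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    if h % size or w % size:
        raise ValueError(f"spatial dims ({h},{w}) not divisible by pool size {size}")
    hs, ws = h // size, w // size
    tiles = (
        x.data.reshape(n, c, hs, size, ws, size)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, hs, ws, size * size)
    )
    idx = tiles.argmax(axis=-1)
    out = np.take_along_axis(tiles, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        dtiles = np.zeros_like(tiles)
        np.put_along_axis(dtiles, idx[..., None], g[..., None], axis=-1)
        dx = (
            dtiles.reshape(n, c, hs, ws, size, size)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        x._accumulate(dx)

    return Tensor._from_op(out, (x,), backward)
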