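"""Convolution and pooling primitives with hand-written adjoints.

All EEG-side convolutions in this package are separable along either the
time axis (kernels of shape ``(1, k)``) or the electrode axis (kernels of
shape ``(C, 1)``), so instead of a general conv2d the engine provides the
two specialised operations plus strided average / variance pooling.  The
1-D denoiser reuses the time convolution with a singleton electrode axis.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = [
    "conv_time",
    "depthwise_conv_time",
    "depthwise_spatial_conv",
    "avg_pool_time",
    "var_pool_time",
    "upsample_time",
]


def conv_time(x: Tensor, w: Tensor, b: Tensor | None = None, same: bool = True) -> Tensor:
    """Convolve along the trailing (time) axis.

    Parameters
    ----------
    x : Tensor, shape (N, Cin, C, V)
    w : Tensor, shape (Cout, Cin, k)
    b : Tensor or None, shape (Cout,)
    same : pad the time axis so the output length equals the input length
        (asymmetric for even k: ``k//2 - (1 - k%2)`` left, ``k//2`` right).
    """
    k = w.shape[-1]
    if same:
        left = k // 2 - (1 - k % 2)
        right = k // 2
        xp = np.pad(x.data, [(0, 0), (0, 0), (0, 0), (left, right)])
    else:
        left = right = 0
        xp = x.data
    if xp.shape[-1] < k:
        raise ValueError(f"time axis ({x.shape[-1]}) shorter than kernel ({k})")
    n, cin, c, _ = xp.shape
    vout = xp.shape[-1] - k + 1
    cout = w.shape[0]
    # im2col: (N, C, Vout, Cin*k) laid out for a single BLAS gemm
    win = sliding_window_view(xp, k, axis=-1)  # (N, Cin, C, Vout, k) strided view
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4)).reshape(-1, cin * k)
    wmat = w.data.reshape(cout, cin * k)
    out = cols @ wmat.T  # (N*C*Vout, Cout)
    out_data = np.ascontiguousarray(
        out.reshape(n, c, vout, cout).transpose(0, 3, 1, 2))
    if b is not None:
        out_data += b.data[None, :, None, None]

    children = [t for t in (x, w, b) if t is not None]

    def bwd(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, cout)
        if w.requires_grad:
            w._accumulate((gmat.T @ cols).reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = gmat @ wmat  # (N*C*Vout, Cin*k)
            gxp = np.zeros_like(xp)
            gcols = gcols.reshape(n, c, vout, cin, k).transpose(0, 3, 1, 2, 4)
            # scatter the overlapping windows back onto the time axis
            for j in range(k):
                gxp[..., j : j + vout] += gcols[..., j]
            gx = gxp[..., left : left + x.shape[-1]] if same else gxp
            x._accumulate(gx)

    return Tensor._make(out_data, children, bwd)


def depthwise_conv_time(x: Tensor, w: Tensor, same: bool = True) -> Tensor:
    """Per-channel convolution along the trailing axis.

    x : Tensor, shape (N, C, L); w : Tensor, shape (C, k) — one filter per
    channel, no channel mixing.
    """
    k = w.shape[-1]
    if same:
        left = k // 2 - (1 - k % 2)
        right = k // 2
        xp = np.pad(x.data, [(0, 0), (0, 0), (left, right)])
    else:
        left = 0
        xp = x.data
    win = sliding_window_view(xp, k, axis=-1)  # (N, C, L', k)
    out_data = np.einsum("nclk,ck->ncl", win, w.data, optimize=True)

    def bwd(g):
        if w.requires_grad:
            w._accumulate(np.einsum("ncl,nclk->ck", g, win, optimize=True))
        if x.requires_grad:
            gp = np.pad(g, [(0, 0), (0, 0), (k - 1, k - 1)])
            gwin = sliding_window_view(gp, k, axis=-1)
            gx_full = np.einsum("nclk,ck->ncl", gwin, w.data[:, ::-1], optimize=True)
            gx = gx_full[..., left : left + x.shape[-1]] if same else gx_full
            x._accumulate(gx)

    return Tensor._make(out_data, (x, w), bwd)


def depthwise_spatial_conv(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Depthwise convolution collapsing the electrode axis.

    Parameters
    ----------
    x : Tensor, shape (N, G, C, V) — G feature maps over C electrodes
    w : Tensor, shape (G, M, C) — M spatial filters per input map
    b : Tensor or None, shape (G*M,)

    Returns shape (N, G*M, 1, V); output map ``g*M + m`` is the spatial
    projection of input map ``g`` by filter ``m``.
    """
    n, gmaps, c, v = x.shape
    m = w.shape[1]
    out = np.einsum("ngcv,gmc->ngmv", x.data, w.data, optimize=True)
    out_data = out.reshape(n, gmaps * m, 1, v)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    children = [t for t in (x, w, b) if t is not None]

    def bwd(g):
        gr = g.reshape(n, gmaps, m, v)
        if w.requires_grad:
            w._accumulate(np.einsum("ngmv,ngcv->gmc", gr, x.data, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accumulate(np.einsum("ngmv,gmc->ngcv", gr, w.data, optimize=True))

    return Tensor._make(out_data, children, bwd)


def _pool_positions(v: int, kernel: int, stride: int) -> np.ndarray:
    if v < kernel:
        raise ValueError(f"time axis ({v}) shorter than pooling kernel ({kernel})")
    return np.arange(0, v - kernel + 1, stride)


def _pool_windows(x: Tensor, kernel: int, stride: int):
    pos = _pool_positions(x.shape[-1], kernel, stride)
    idx = pos[:, None] + np.arange(kernel)[None, :]  # (T', k)
    win = x.data[..., idx]  # (..., T', k)
    return win, idx


def avg_pool_time(x: Tensor, kernel: int, stride: int) -> Tensor:
    win, idx = _pool_windows(x, kernel, stride)
    out_data = win.mean(axis=-1)

    def bwd(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, (..., idx), g[..., None] / kernel)
        x._accumulate(gx)

    return Tensor._make(out_data, (x,), bwd)


def var_pool_time(x: Tensor, kernel: int, stride: int) -> Tensor:
    """Strided population-variance pooling along time."""
    if kernel < 1:
        raise ValueError("pooling kernel must be >= 1")
    win, idx = _pool_windows(x, kernel, stride)
    mu = win.mean(axis=-1, keepdims=True)
    out_data = ((win - mu) ** 2).mean(axis=-1)

    def bwd(g):
        # d var / d x_j = 2 (x_j - mu) / k
        gwin = g[..., None] * 2.0 * (win - mu) / kernel
        gx = np.zeros_like(x.data)
        np.add.at(gx, (..., idx), gwin)
        x._accumulate(gx)

    return Tensor._make(out_data, (x,), bwd)


def upsample_time(x: Tensor, factor: int) -> Tensor:
    """Nearest-neighbour upsampling along the trailing axis."""
    out_data = np.repeat(x.data, factor, axis=-1)

    def bwd(g):
        shp = g.shape[:-1] + (x.shape[-1], factor)
        x._accumulate(g.reshape(shp).sum(axis=-1))

    return Tensor._make(out_data, (x,), bwd)
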