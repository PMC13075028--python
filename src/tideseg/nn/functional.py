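"""Convolution, resize and loss primitives with hand-written adjoints.

2-D convolution is computed as a loop over kernel taps, each tap a BLAS
``tensordot`` — memory-light compared with im2col and fast at the tile sizes
this package trains on. Bilinear resize follows the half-pixel-center
(``align_corners=False``) convention used everywhere in the project.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp_special

from .tensor import Tensor

__all__ = [
    "conv2d",
    "depthwise_conv2d",
    "conv1d_channels",
    "bilinear_resize",
    "cross_entropy",
    "bce_with_logits",
]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW input, OIHW weights."""
    n, c, h, wid = x.shape
    o, ci, kh, kw = w.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {ci}")
    s = stride
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    hp, wp = xp.shape[2], xp.shape[3]
    ho, wo = (hp - kh) // s + 1, (wp - kw) // s + 1
    acc = np.zeros((n, ho, wo, o), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i:i + s * ho:s, j:j + s * wo:s]
            # (N,C,Ho,Wo) x (O,C) -> (N,Ho,Wo,O)
            acc += np.tensordot(xs, w.data[:, :, i, j], axes=([1], [1]))
    out_data = np.ascontiguousarray(acc.transpose(0, 3, 1, 2))
    if b is not None:
        out_data += b.data.reshape(1, o, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        need_x = x.requires_grad
        need_w = w.requires_grad
        if not (need_x or need_w):
            return
        dxp = np.zeros_like(xp) if need_x else None
        dw = np.zeros_like(w.data) if need_w else None
        for i in range(kh):
            for j in range(kw):
                xs_sl = (slice(None), slice(None),
                         slice(i, i + s * ho, s), slice(j, j + s * wo, s))
                if need_w:
                    # (N,O,Ho,Wo) x (N,C,Ho,Wo) -> (O,C)
                    dw[:, :, i, j] = np.tensordot(g, xp[xs_sl], axes=([0, 2, 3], [0, 2, 3]))
                if need_x:
                    # (N,O,Ho,Wo) x (O,C) -> (N,C,Ho,Wo)
                    dxp[xs_sl] += np.tensordot(g, w.data[:, :, i, j],
                                               axes=([1], [0])).transpose(0, 3, 1, 2)
        if need_w:
            w._accum(dw)
        if need_x:
            if padding:
                x._accum(dxp[:, :, padding:hp - padding, padding:wp - padding])
            else:
                x._accum(dxp)

    return Tensor._make(out_data, parents, backward)


def depthwise_conv2d(x: Tensor, w: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """Per-channel 2-D convolution; weights shaped (C, kh, kw)."""
    n, c, h, wid = x.shape
    cw, kh, kw = w.shape
    if cw != c:
        raise ValueError("depthwise channel mismatch")
    s = stride
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    hp, wp = xp.shape[2], xp.shape[3]
    ho, wo = (hp - kh) // s + 1, (wp - kw) // s + 1
    out_data = np.zeros((n, c, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            out_data += xp[:, :, i:i + s * ho:s, j:j + s * wo:s] * w.data[None, :, i, j, None, None]

    def backward(g):
        need_x = x.requires_grad
        need_w = w.requires_grad
        dxp = np.zeros_like(xp) if need_x else None
        dw = np.zeros_like(w.data) if need_w else None
        for i in range(kh):
            for j in range(kw):
                sl = (slice(None), slice(None), slice(i, i + s * ho, s), slice(j, j + s * wo, s))
                if need_w:
                    dw[:, i, j] = (g * xp[sl]).sum(axis=(0, 2, 3))
                if need_x:
                    dxp[sl] += g * w.data[None, :, i, j, None, None]
        if need_w:
            w._accum(dw)
        if need_x:
            if padding:
                x._accum(dxp[:, :, padding:hp - padding, padding:wp - padding])
            else:
                x._accum(dxp)

    return Tensor._make(out_data, (x, w), backward)


def conv1d_channels(z: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """1-D convolution sliding over the channel axis of (N, C) descriptors.

    Zero padding of (k-1)/2 keeps the output length at C — the ECA
    cross-channel interaction. Kernel length must be odd.
    """
    k = w.shape[0]
    if k % 2 == 0:
        raise ValueError("conv1d_channels requires an odd kernel size")
    pad = (k - 1) // 2
    n, c = z.shape
    zp = np.pad(z.data, ((0, 0), (pad, pad)))
    out_data = np.zeros((n, c), dtype=z.dtype)
    for t in range(k):
        out_data += w.data[t] * zp[:, t:t + c]
    if b is not None:
        out_data += b.data
    parents = (z, w) if b is None else (z, w, b)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accum(np.array([g.sum()]))
        if w.requires_grad:
            dw = np.array([(g * zp[:, t:t + c]).sum() for t in range(k)])
            w._accum(dw)
        if z.requires_grad:
            dzp = np.zeros_like(zp)
            for t in range(k):
                dzp[:, t:t + c] += w.data[t] * g
            z._accum(dzp[:, pad:pad + c])

    return Tensor._make(out_data, parents, backward)


def _resize_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Row-stochastic (n_out, n_in) interpolation matrix, half-pixel centers."""
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.minimum(np.floor(src).astype(np.intp), n_in - 1)
    i1 = np.minimum(i0 + 1, n_in - 1)
    frac = src - i0
    mat = np.zeros((n_out, n_in), dtype=dtype)
    rows = np.arange(n_out)
    np.add.at(mat, (rows, i0), 1.0 - frac)
    np.add.at(mat, (rows, i1), frac)
    return mat


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize of the trailing two axes of an NCHW tensor.

    Separable: out = R_h x R_w^T applied per (n, c) slice, where R_h and R_w
    are the 1-D interpolation matrices. The adjoint is the transpose pair.
    """
    n, c, h, w = x.shape
    if (out_h, out_w) == (h, w):
        return x
    ry = _resize_matrix(h, out_h, x.dtype)
    rx = _resize_matrix(w, out_w, x.dtype)
    flat = x.data.reshape(n * c, h, w)
    out_data = (ry @ flat @ rx.T).reshape(n, c, out_h, out_w)

    def backward(g):
        if not x.requires_grad:
            return
        gf = g.reshape(n * c, out_h, out_w)
        x._accum((ry.T @ gf @ rx).reshape(n, c, h, w))

    return Tensor._make(out_data, (x,), backward)


def cross_entropy(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean pixel-wise multi-class cross-entropy.

    ``logits``: (N, K, H, W); ``target``: integer labels (N, H, W).
    """
    n, k, h, w = logits.shape
    t = np.asarray(target)
    if t.shape != (n, h, w):
        raise ValueError(f"target shape {t.shape} does not match logits {logits.shape}")
    d = logits.data
    m = d.max(axis=1, keepdims=True)
    e = np.exp(d - m)
    se = e.sum(axis=1, keepdims=True)
    log_p = d - m - np.log(se)
    picked = np.take_along_axis(log_p, t[:, None], axis=1)[:, 0]
    npix = n * h * w
    out_data = np.array(-picked.sum() / npix)

    def backward(g):
        if not logits.requires_grad:
            return
        p = e / se
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, t[:, None], 1.0, axis=1)
        logits._accum((p - onehot) * (float(g) / npix))

    return Tensor._make(out_data, (logits,), backward)


def bce_with_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed in logit space (numerically stable)."""
    t = np.asarray(target, dtype=logits.dtype)
    if t.shape != logits.shape:
        raise ValueError(f"target shape {t.shape} does not match logits {logits.shape}")
    d = logits.data
    loss = np.maximum(d, 0.0) - d * t + np.log1p(np.exp(-np.abs(d)))
    size = d.size
    out_data = np.array(loss.sum() / size)

    def backward(g):
        if not logits.requires_grad:
            return
        logits._accum((_sp_special.expit(d) - t) * (float(g) / size))

    return Tensor._make(out_data, (logits,), backward)
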