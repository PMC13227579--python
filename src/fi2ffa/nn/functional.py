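"""Convolution, pooling and normalization primitives with autodiff hooks.

Convolutions use an im2col lowering to a single BLAS matmul; the transposed
convolution is implemented as the exact adjoint of the forward convolution,
so the pair shares the same numpy kernels. The im2col buffer computed in a
convolution forward pass is cached on the tape and reused for the weight
gradient; the non-overlapping case (kernel == stride, no padding), which is
what the 2x2 stride-2 up/down-sampling layers hit, is a pure reshape.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = ["conv2d", "conv_transpose2d", "max_pool2d", "instance_norm"]


def _pad(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, padding: int) -> np.ndarray:
    """(N,C,H,W) -> (N*Ho*Wo, C*kh*kw) patch matrix."""
    xp = _pad(x, padding)
    n, c, hp, wp = xp.shape
    if kh == kw == stride and padding == 0:
        ho, wo = hp // kh, wp // kw
        v = xp.reshape(n, c, ho, kh, wo, kw).transpose(0, 2, 4, 1, 3, 5)
        return np.ascontiguousarray(v).reshape(n * ho * wo, c * kh * kw)
    v = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, ho, wo = v.shape[:4]
    return np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(n * ho * wo, c * kh * kw)


def _out_hw(hw: tuple[int, int], k: int, stride: int, padding: int) -> tuple[int, int]:
    return tuple((d + 2 * padding - k) // stride + 1 for d in hw)


def _conv_fwd(x: np.ndarray, w: np.ndarray, stride: int, padding: int,
              return_cols: bool = False):
    """Cross-correlation. x:(N,I,H,W), w:(O,I,kh,kw) -> (N,O,Ho,Wo)."""
    o, i, kh, kw = w.shape
    n = x.shape[0]
    ho, wo = _out_hw(x.shape[2:], kh, stride, padding)
    cols = _im2col(x, kh, kw, stride, padding)
    y = (cols @ w.reshape(o, -1).T).reshape(n, ho, wo, o).transpose(0, 3, 1, 2)
    if return_cols:
        return np.ascontiguousarray(y), cols
    return np.ascontiguousarray(y)


def _conv_dx(gy: np.ndarray, w: np.ndarray, x_hw: tuple[int, int], stride: int, padding: int) -> np.ndarray:
    """Gradient of _conv_fwd w.r.t. its input (= transposed-conv forward)."""
    o, i, kh, kw = w.shape
    n, _, ho, wo = gy.shape
    h, wd = x_hw
    gcols = gy.transpose(0, 2, 3, 1).reshape(-1, o) @ w.reshape(o, -1)
    gcols = gcols.reshape(n, ho, wo, i, kh, kw)
    if kh == kw == stride and padding == 0 and ho * stride == h and wo * stride == wd:
        return np.ascontiguousarray(gcols.transpose(0, 3, 1, 4, 2, 5)).reshape(n, i, h, wd)
    gc = np.ascontiguousarray(gcols.transpose(0, 3, 4, 5, 1, 2))  # (N,I,kh,kw,Ho,Wo)
    dxp = np.zeros((n, i, h + 2 * padding, wd + 2 * padding), dtype=gy.dtype)
    for a in range(kh):
        for b in range(kw):
            dxp[:, :, a : a + ho * stride : stride, b : b + wo * stride : stride] += gc[:, :, a, b]
    if padding:
        return dxp[:, :, padding:-padding, padding:-padding]
    return dxp


def _dw_from_cols(cols: np.ndarray, gy: np.ndarray, w_shape: tuple[int, ...]) -> np.ndarray:
    o = w_shape[0]
    gy_r = gy.transpose(0, 2, 3, 1).reshape(-1, o)
    return (gy_r.T @ cols).reshape(w_shape)


def _conv_dw(x: np.ndarray, gy: np.ndarray, w_shape: tuple[int, ...], stride: int, padding: int) -> np.ndarray:
    o, i, kh, kw = w_shape
    return _dw_from_cols(_im2col(x, kh, kw, stride, padding), gy, w_shape)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    o, i, kh, kw = w.shape
    n, ci, h, wd = x.shape
    if ci != i:
        raise ValueError(f"conv2d: input has {ci} channels, weight expects {i}")
    need_grad = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    y, cols = _conv_fwd(x.data, w.data, stride, padding, return_cols=True)
    if b is not None:
        y += b.data[None, :, None, None]
    out = Tensor(y)
    if not need_grad:
        return out

    def backward(g):
        gx = _conv_dx(g, w.data, (h, wd), stride, padding) if x.requires_grad else None
        gw = _dw_from_cols(cols, g, w.shape) if w.requires_grad else None
        gb = g.sum(axis=(0, 2, 3)) if (b is not None and b.requires_grad) else None
        return (gx, gw, gb) if b is not None else (gx, gw)

    out.requires_grad = True
    out._prev = (x, w, b) if b is not None else (x, w)
    out._backward = backward
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 2, padding: int = 0) -> Tensor:
    """Transposed convolution; weight layout (C_in, C_out, kh, kw)."""
    ci, co, kh, kw = w.shape
    n, xc, h, wd = x.shape
    if xc != ci:
        raise ValueError(f"conv_transpose2d: input has {xc} channels, weight expects {ci}")
    ho = (h - 1) * stride + kh - 2 * padding
    wo = (wd - 1) * stride + kw - 2 * padding
    y = _conv_dx(x.data, w.data, (ho, wo), stride, padding)
    if b is not None:
        y += b.data[None, :, None, None]

    def backward(g):
        gx = _conv_fwd(g, w.data, stride, padding) if x.requires_grad else None
        gw = _conv_dw(g, x.data, w.shape, stride, padding) if w.requires_grad else None
        gb = g.sum(axis=(0, 2, 3)) if (b is not None and b.requires_grad) else None
        return (gx, gw, gb) if b is not None else (gx, gw)

    parents = (x, w, b) if b is not None else (x, w)
    out = Tensor(y)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._prev = parents
        out._backward = backward
    return out


def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError("max_pool2d: spatial size must be divisible by the window")
    win = np.ascontiguousarray(
        x.data.reshape(n, c, h // k, k, w // k, k).transpose(0, 1, 2, 4, 3, 5)
    ).reshape(n, c, h // k, w // k, k * k)
    idx = win.argmax(axis=-1)
    y = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gw = np.zeros((n, c, h // k, w // k, k * k), dtype=g.dtype)
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        gx = gw.reshape(n, c, h // k, w // k, k, k).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        return (np.ascontiguousarray(gx),)

    out = Tensor(y)
    if x.requires_grad:
        out.requires_grad = True
        out._prev = (x,)
        out._backward = backward
    return out


def instance_norm(x: Tensor, gamma: Tensor | None = None, beta: Tensor | None = None,
                  eps: float = 1e-5) -> Tensor:
    """Per-(sample, channel) normalization over the spatial axes."""
    n, c, h, w = x.shape
    m = h * w
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    xc = x.data - mu
    var = (xc**2).mean(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    y = xhat
    if gamma is not None:
        y = y * gamma.data[None, :, None, None]
    if beta is not None:
        y = y + beta.data[None, :, None, None]

    def backward(g):
        gh = g * gamma.data[None, :, None, None] if gamma is not None else g
        # standard normalization backward over the spatial axes
        gx = (inv / m) * (
            m * gh - gh.sum(axis=(2, 3), keepdims=True) - xhat * (gh * xhat).sum(axis=(2, 3), keepdims=True)
        )
        grads = [gx.astype(np.float32)]
        if gamma is not None:
            grads.append((g * xhat).sum(axis=(0, 2, 3)) if gamma.requires_grad else None)
        if beta is not None:
            grads.append(g.sum(axis=(0, 2, 3)) if beta.requires_grad else None)
        return tuple(grads)

    parents = [x]
    if gamma is not None:
        parents.append(gamma)
    if beta is not None:
        parents.append(beta)
    out = Tensor(y)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._prev = tuple(parents)
        out._backward = backward
    return out
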