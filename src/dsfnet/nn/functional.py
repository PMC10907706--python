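"""Fused NCHW spatial operations with hand-written backward passes.

Convolutions use im2col + BLAS matmul; the column buffer is kept alive in the
backward closure, trading memory for speed (fine at the feature-map sizes a
single-CPU run uses).
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["conv2d", "conv_transpose2d_2x2", "max_pool2d", "bilinear_resize"]


def _im2col(xp: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(B,C,Hp,Wp) -> (B, C*kh*kw, Ho*Wo) patch matrix."""
    B, C, Hp, Wp = xp.shape
    Ho, Wo = Hp - kh + 1, Wp - kw + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # (B, C, Ho, Wo, kh, kw) -> (B, C, kh, kw, Ho, Wo)
    cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3))
    return cols.reshape(B, C * kh * kw, Ho * Wo)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, padding: int = 0) -> Tensor:
    """2-D cross-correlation, stride 1, symmetric zero padding.

    ``w`` has shape (O, C, kh, kw); output is (B, O, Ho, Wo).
    """
    B, C, H, W = x.data.shape
    O, Cw, kh, kw = w.data.shape
    if Cw != C:
        raise ValueError(f"conv2d: input has {C} channels, weight expects {Cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Ho, Wo = H + 2 * padding - kh + 1, W + 2 * padding - kw + 1
    cols = _im2col(xp, kh, kw)  # (B, C*kh*kw, Ho*Wo)
    w2 = w.data.reshape(O, C * kh * kw)
    out = np.matmul(w2, cols).reshape(B, O, Ho, Wo)
    if b is not None:
        out = out + b.data.reshape(1, O, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g2 = g.reshape(B, O, Ho * Wo)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.tensordot(g2, cols, axes=([0, 2], [0, 2]))
            w._accum(gw.reshape(O, C, kh, kw))
        if x.requires_grad:
            gcols = np.matmul(w2.T, g2)  # (B, C*kh*kw, Ho*Wo)
            gcols = gcols.reshape(B, C, kh, kw, Ho, Wo)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + Ho, j : j + Wo] += gcols[:, :, i, j]
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accum(gxp)

    return Tensor._make(out, parents, backward)


def conv_transpose2d_2x2(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Transposed convolution with kernel 2, stride 2 (exact x2 upsampling).

    ``w`` has shape (C_in, C_out, 2, 2); output is (B, C_out, 2H, 2W).
    """
    B, C, H, W = x.data.shape
    Cin, O, kh, kw = w.data.shape
    if Cin != C:
        raise ValueError(f"conv_transpose2d: input has {C} channels, weight expects {Cin}")
    out6 = np.einsum("bchw,coij->bohiwj", x.data, w.data, optimize=True)
    out = out6.reshape(B, O, 2 * H, 2 * W)
    if b is not None:
        out = out + b.data.reshape(1, O, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g6 = g.reshape(B, O, H, 2, W, 2)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w._accum(np.einsum("bchw,bohiwj->coij", x.data, g6, optimize=True))
        if x.requires_grad:
            x._accum(np.einsum("bohiwj,coij->bchw", g6, w.data, optimize=True))

    return Tensor._make(out, parents, backward)


def max_pool2d(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2. Spatial dims must be even."""
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"max_pool2d: spatial size ({H},{W}) must be even")
    Hh, Wh = H // 2, W // 2
    x4 = x.data.reshape(B, C, Hh, 2, Wh, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        B, C, Hh, Wh, 4
    )
    idx = x4.argmax(axis=-1)
    out = np.take_along_axis(x4, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        g4 = np.zeros((B, C, Hh, Wh, 4), dtype=g.dtype)
        np.put_along_axis(g4, idx[..., None], g[..., None], axis=-1)
        gx = g4.reshape(B, C, Hh, Wh, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            B, C, H, W
        )
        x._accum(gx)

    return Tensor._make(out, (x,), backward)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Bilinear interpolation matrix (n_out, n_in), half-pixel-center convention."""
    A = np.zeros((n_out, n_in), dtype=np.float32)
    if n_in == 1:
        A[:, 0] = 1.0
        return A
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    f = (src - i0).astype(np.float32)
    A[np.arange(n_out), i0] += 1.0 - f
    A[np.arange(n_out), i1] += f
    return A


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Resize (B,C,H,W) to (B,C,Ho,Wo) by separable bilinear interpolation."""
    B, C, H, W = x.data.shape
    Ho, Wo = out_hw
    if (Ho, Wo) == (H, W):
        return x
    Ah = _interp_matrix(Ho, H)
    Aw = _interp_matrix(Wo, W)

    def apply(arr, Mh, Mw):
        t = np.einsum("oh,bchw->bcow", Mh, arr, optimize=True)
        return np.einsum("pw,bcow->bcop", Mw, t, optimize=True)

    out = apply(x.data, Ah, Aw)

    def backward(g):
        x._accum(apply(g, Ah.T, Aw.T))

    return Tensor._make(out, (x,), backward)
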