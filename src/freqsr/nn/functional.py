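"""Structured operations on (B, C, H, W) tensors: convolutions, pooling,
pixel shuffle and bilinear upsampling, with hand-written adjoints where a
composite of primitives would be wasteful.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided
from scipy.signal import fftconvolve

from .tensor import Tensor

__all__ = [
    "conv2d",
    "dwconv3x3",
    "dwconv_fft",
    "avg_pool3",
    "max_pool3",
    "global_avg_pool",
    "channel_max",
    "spatial_max",
    "pixel_shuffle2",
    "bilinear_up2",
]

_F32 = np.float32


# ---------------------------------------------------------------------------
# dense convolution via im2col + GEMM
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, ph: int, pw: int):
    """(B,C,H,W) -> (C*kh*kw, B*Ho*Wo) patch matrix (one copy, one GEMM later).

    The batch axis is folded into the columns so the convolution is a single
    large matrix product rather than a loop of small batched ones.
    """
    b, c, h, w = x.shape
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    hp, wp = x.shape[2], x.shape[3]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    sb, sc, sh, sw = x.strides
    view = as_strided(
        x,
        shape=(c, kh, kw, b, ho, wo),
        strides=(sc, sh, sw, sb, sh * stride, sw * stride),
        writeable=False,
    )
    return np.ascontiguousarray(view).reshape(c * kh * kw, b * ho * wo), ho, wo


def _col2im(cols: np.ndarray, xshape, kh, kw, stride, ph, pw) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back onto the image."""
    b, c, h, w = xshape
    hp, wp = h + 2 * ph, w + 2 * pw
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    gx = np.zeros((c, b, hp, wp), dtype=_F32)
    cols = cols.reshape(c, kh, kw, b, ho, wo)
    for i in range(kh):
        he = i + stride * ho
        for j in range(kw):
            we = j + stride * wo
            gx[:, :, i:he:stride, j:we:stride] += cols[:, i, j]
    gx = gx.transpose(1, 0, 2, 3)
    if ph or pw:
        gx = gx[:, :, ph : hp - ph, pw : wp - pw]
    return np.ascontiguousarray(gx)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, stride: int = 1,
           padding: int | None = None) -> Tensor:
    """2-D cross-correlation, weight (Cout, Cin, kh, kw); default 'same' padding
    for stride 1 and odd kernels.  1x1 kernels take a pure-GEMM fast path."""
    cout, cin, kh, kw = weight.shape
    if x.shape[1] != cin:
        raise ValueError(f"conv2d channel mismatch: input {x.shape[1]}, weight expects {cin}")
    if padding is None:
        padding = (kh - 1) // 2
    b = x.shape[0]
    if kh == 1 and kw == 1 and stride == 1 and padding == 0:
        h, w = x.shape[2], x.shape[3]
        wmat = weight.data.reshape(cout, cin)
        xmat = x.data.reshape(b, cin, h * w)
        out = np.matmul(wmat, xmat).reshape(b, cout, h, w)
        if bias is not None:
            out = out + bias.data.reshape(1, cout, 1, 1)

        parents = (x, weight) if bias is None else (x, weight, bias)

        def bwd1(g):
            gmat = g.reshape(b, cout, h * w)
            if weight.requires_grad:
                gw = np.matmul(gmat, xmat.transpose(0, 2, 1)).sum(axis=0)
                weight._accum(gw.reshape(weight.shape))
            if bias is not None and bias.requires_grad:
                bias._accum(gmat.sum(axis=(0, 2)))
            if x.requires_grad:
                x._accum(np.matmul(wmat.T, gmat).reshape(x.shape))

        return Tensor._make(out, parents, bwd1)

    cols, ho, wo = _im2col(x.data, kh, kw, stride, padding, padding)
    wmat = weight.data.reshape(cout, cin * kh * kw)
    out = np.matmul(wmat, cols)  # (Cout, B*Ho*Wo)
    out = np.ascontiguousarray(out.reshape(cout, b, ho, wo).transpose(1, 0, 2, 3))
    if bias is not None:
        out += bias.data.reshape(1, cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        gmat = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(cout, b * ho * wo)
        if weight.requires_grad:
            gw = np.matmul(gmat, cols.T)
            weight._accum(gw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(gmat.sum(axis=1))
        if x.requires_grad:
            gcols = np.matmul(wmat.T, gmat)  # (Cin*kh*kw, B*Ho*Wo)
            x._accum(_col2im(gcols, x.shape, kh, kw, stride, padding, padding))

    return Tensor._make(out, parents, bwd)


# ---------------------------------------------------------------------------
# depthwise convolutions
# ---------------------------------------------------------------------------

def dwconv3x3(x: Tensor, weight: Tensor, bias: Tensor | None = None, dilation: int = 1) -> Tensor:
    """Depthwise 3x3 cross-correlation with dilation, 'same' zero padding
    (a single fused op: nine shifted multiply-adds with a matching adjoint)."""
    b, c, h, w = x.shape
    if weight.shape != (c, 3, 3):
        raise ValueError(f"dwconv3x3 weight must be ({c},3,3), got {weight.shape}")
    p = dilation
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    out = np.zeros((b, c, h, w), dtype=_F32)
    wd = weight.data
    for u in range(3):
        r0 = u * dilation
        for v in range(3):
            c0 = v * dilation
            out += wd[:, u, v].reshape(1, c, 1, 1) * xp[:, :, r0 : r0 + h, c0 : c0 + w]
    if bias is not None:
        out += bias.data.reshape(1, c, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        if weight.requires_grad:
            gw = np.empty((c, 3, 3), dtype=_F32)
            for u in range(3):
                r0 = u * dilation
                for v in range(3):
                    c0 = v * dilation
                    gw[:, u, v] = (g * xp[:, :, r0 : r0 + h, c0 : c0 + w]).sum(axis=(0, 2, 3))
            weight._accum(gw)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=_F32)
            for u in range(3):
                r0 = u * dilation
                for v in range(3):
                    c0 = v * dilation
                    gxp[:, :, r0 : r0 + h, c0 : c0 + w] += wd[:, u, v].reshape(1, c, 1, 1) * g
            x._accum(gxp[:, :, p : p + h, p : p + w])

    return Tensor._make(out, parents, bwd)


def dwconv_fft(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Depthwise convolution with a large odd kernel (C,k,k) via FFT, 'same'
    zero padding.  Used for the 27x27 large-receptive-field branch, where 729
    shifted adds or an im2col would be wasteful."""
    b, c, h, w = x.shape
    kc, kh, kw = weight.shape
    if kc != c or kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("dwconv_fft expects per-channel odd kernels")
    kern = weight.data[None]  # (1,C,kh,kw) broadcast over batch
    out = fftconvolve(x.data, kern, mode="same", axes=(-2, -1)).astype(_F32)
    if bias is not None:
        out = out + bias.data.reshape(1, c, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        if x.requires_grad:
            gx = fftconvolve(g, kern[:, :, ::-1, ::-1], mode="same", axes=(-2, -1))
            x._accum(gx.astype(_F32))
        if weight.requires_grad:
            # dL/dk[u] = sum_i g[i] x[i + c0 - u]; extract from full correlation
            full = fftconvolve(x.data[:, :, ::-1, ::-1], g, mode="full", axes=(-2, -1))
            ch0 = h - 1 - (kh - 1) // 2
            cw0 = w - 1 - (kw - 1) // 2
            gw = full[:, :, ch0 : ch0 + kh, cw0 : cw0 + kw].sum(axis=0)
            weight._accum(gw.astype(_F32))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))

    return Tensor._make(out, parents, bwd)


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def avg_pool3(x: Tensor) -> Tensor:
    """3x3 stride-1 average pooling, zero padding (padded zeros count)."""
    c = x.shape[1]
    w = Tensor(np.full((c, 3, 3), 1.0 / 9.0, dtype=_F32))
    return dwconv3x3(x, w)


def max_pool3(x: Tensor) -> Tensor:
    """3x3 stride-1 max pooling ('same', -inf padding); first-match ties."""
    b, c, h, w = x.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)), constant_values=-np.inf)
    shifts = [(u, v) for u in range(3) for v in range(3)]
    out = np.full((b, c, h, w), -np.inf, dtype=_F32)
    for u, v in shifts:
        np.maximum(out, xp[:, :, u : u + h, v : v + w], out=out)

    def bwd(g):
        if not x.requires_grad:
            return
        gx = np.zeros((b, c, h + 2, w + 2), dtype=_F32)
        claimed = np.zeros((b, c, h, w), dtype=bool)
        for u, v in shifts:
            win = xp[:, :, u : u + h, v : v + w]
            hit = (win == out) & ~claimed
            claimed |= hit
            gx[:, :, u : u + h, v : v + w] += np.where(hit, g, 0.0)
        x._accum(gx[:, :, 1 : h + 1, 1 : w + 1])

    return Tensor._make(out, (x,), bwd)


def global_avg_pool(x: Tensor) -> Tensor:
    """(B,C,H,W) -> (B,C,1,1) spatial mean."""
    return x.mean(axis=(2, 3), keepdims=True)


def _max_reduce(x: Tensor, axes: tuple) -> Tensor:
    """Max over ``axes`` (keepdims); gradient flows to the first maximizer."""
    out = x.data.max(axis=axes, keepdims=True)
    hit = x.data == out
    # first-match tie break: keep only the first True along the reduced axes
    flat = np.moveaxis(hit, axes, tuple(range(-len(axes), 0)))
    lead = flat.shape[: flat.ndim - len(axes)]
    flat = flat.reshape(*lead, -1)
    first = np.zeros_like(flat)
    idx = flat.argmax(axis=-1)
    np.put_along_axis(first, idx[..., None], True, axis=-1)
    first &= flat
    mask = np.moveaxis(first.reshape(flat.shape[:-1] + tuple(np.array(x.data.shape)[list(axes)])),
                       tuple(range(-len(axes), 0)), axes)

    def bwd(g):
        x._accum(np.where(mask, g, 0.0).astype(_F32))

    return Tensor._make(out, (x,), bwd)


def channel_max(x: Tensor) -> Tensor:
    """(B,C,H,W) -> (B,1,H,W) max over channels."""
    return _max_reduce(x, (1,))


def spatial_max(x: Tensor) -> Tensor:
    """(B,C,H,W) -> (B,C,1,1) max over space."""
    return _max_reduce(x, (2, 3))


# ---------------------------------------------------------------------------
# upsampling
# ---------------------------------------------------------------------------

def pixel_shuffle2(x: Tensor) -> Tensor:
    """(B, 4C, H, W) -> (B, C, 2H, 2W) sub-pixel rearrangement.

    Channel block (c*4 + 2*dy + dx) lands on output pixel (2r+dy, 2c'+dx).
    """
    b, c4, h, w = x.shape
    if c4 % 4:
        raise ValueError("pixel_shuffle2 needs channels divisible by 4")
    c = c4 // 4
    return (
        x.reshape(b, c, 2, 2, h, w)
        .transpose(0, 1, 4, 2, 5, 3)  # b, c, h, dy, w, dx
        .reshape(b, c, 2 * h, 2 * w)
    )


def _up2_weights(n: int):
    """1-D x2 interpolation (align_corners=False): out[j] = a*x[lo] + (1-a)*x[hi]."""
    j = np.arange(2 * n)
    src = (j + 0.5) / 2.0 - 0.5
    lo = np.clip(np.floor(src).astype(int), 0, n - 1)
    hi = np.clip(lo + 1, 0, n - 1)
    frac = (src - np.floor(src)).astype(_F32)
    frac[src < 0] = 0.0
    return lo, hi, frac


def bilinear_up2(x: Tensor) -> Tensor:
    """Bilinear x2 upsampling of (B,C,H,W), half-pixel centres, edge clamp."""
    b, c, h, w = x.shape
    lo_h, hi_h, fh = _up2_weights(h)
    lo_w, hi_w, fw = _up2_weights(w)

    d = x.data
    rows = d[:, :, lo_h, :] * (1 - fh)[None, None, :, None] + d[:, :, hi_h, :] * fh[None, None, :, None]
    out = rows[:, :, :, lo_w] * (1 - fw)[None, None, None, :] + rows[:, :, :, hi_w] * fw[None, None, None, :]

    def bwd(g):
        if not x.requires_grad:
            return
        grows = np.zeros((b, c, 2 * h, w), dtype=_F32)
        np.add.at(grows.transpose(3, 0, 1, 2), lo_w, (g * (1 - fw)[None, None, None, :]).transpose(3, 0, 1, 2))
        np.add.at(grows.transpose(3, 0, 1, 2), hi_w, (g * fw[None, None, None, :]).transpose(3, 0, 1, 2))
        gx = np.zeros((b, c, h, w), dtype=_F32)
        np.add.at(gx.transpose(2, 0, 1, 3), lo_h, (grows * (1 - fh)[None, None, :, None]).transpose(2, 0, 1, 3))
        np.add.at(gx.transpose(2, 0, 1, 3), hi_h, (grows * fh[None, None, :, None]).transpose(2, 0, 1, 3))
        x._accum(gx)

    return Tensor._make(out.astype(_F32), (x,), bwd)
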