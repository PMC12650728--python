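"""Differentiable array primitives: convolutions, gathering, interpolation.

All convolutions are lowered to an im2col buffer followed by a BLAS matrix
product, which is the fastest route available on a plain CPU numpy stack.
Feature maps follow the (batch, channels, height, width) contract.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, as_tensor

__all__ = [
    "conv2d",
    "conv_transpose2d",
    "depthwise_conv2d",
    "gather_hw",
    "bilinear_sample",
    "snake_sample_contract",
    "group_norm",
    "silu",
    "gelu",
    "softplus",
]


def _pad_hw(x: np.ndarray, ph: int, pw: int, mode: str) -> np.ndarray:
    if ph == 0 and pw == 0:
        return x
    np_mode = "constant" if mode == "zeros" else "edge"
    return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)), mode=np_mode)


def _fold_pad_grad(gxp: np.ndarray, ph: int, pw: int, mode: str) -> np.ndarray:
    """Collapse the gradient of a padded array back onto the unpadded one."""
    if ph == 0 and pw == 0:
        return gxp
    if mode == "zeros":
        return gxp[:, :, ph : gxp.shape[2] - ph if ph else None, pw : gxp.shape[3] - pw if pw else None]
    # edge replication: padded rows/cols are copies, so their gradient is
    # summed into the border row/col they replicate.  Rows first (over the
    # full padded width) then columns handles the corners correctly.
    if ph:
        gxp[:, :, ph, :] += gxp[:, :, :ph, :].sum(axis=2)
        gxp[:, :, -ph - 1, :] += gxp[:, :, -ph:, :].sum(axis=2)
        gxp = gxp[:, :, ph:-ph, :]
    if pw:
        gxp[:, :, :, pw] += gxp[:, :, :, :pw].sum(axis=3)
        gxp[:, :, :, -pw - 1] += gxp[:, :, :, -pw:].sum(axis=3)
        gxp = gxp[:, :, :, pw:-pw]
    return gxp


def _conv1x1(x: Tensor, w: Tensor, bias: Tensor | None) -> Tensor:
    """Pointwise convolution as a batched matrix product (no im2col copy)."""
    N, C, H, W = x.shape
    O = w.shape[0]
    wmat = w.data.reshape(O, C)
    x2 = x.data.reshape(N, C, H * W)
    out_data = (wmat @ x2).reshape(N, O, H, W)
    if bias is not None:
        out_data += bias.data.reshape(1, O, 1, 1)
    parents = (x, w) if bias is None else (x, w, bias)
    out = Tensor(out_data, _parents=parents)

    def _bw(g):
        g2 = g.reshape(N, O, H * W)
        if w.requires_grad or w._parents:
            gw = np.einsum("nop,ncp->oc", g2, x2, optimize=True)
            w._accumulate(gw.reshape(w.shape))
        if bias is not None and (bias.requires_grad or bias._parents):
            bias._accumulate(g.sum(axis=(0, 2, 3)).reshape(bias.shape))
        if x.requires_grad or x._parents:
            x._accumulate((wmat.T @ g2).reshape(x.shape))

    out._backward = _bw if Tensor._needs_graph(x, w) or (bias is not None and Tensor._needs_graph(bias)) else None
    return out


def _conv_taps(x: Tensor, w: Tensor, bias: Tensor | None, ph: int, pw: int, pad_mode: str) -> Tensor:
    """Same-padding stride-1 convolution by per-tap matrix products.

    Avoids the im2col buffer: each kernel tap contributes
    ``w[:, :, i, j] @ x_shifted`` accumulated into the output.
    """
    N, C, H, W = x.shape
    O, _, kh, kw = w.shape
    xp = _pad_hw(x.data, ph, pw, pad_mode)
    Hp, Wp = xp.shape[2], xp.shape[3]
    xp2 = xp.reshape(N, C, Hp * Wp)
    out_data = np.zeros((N, O, H, W), dtype=x.data.dtype)
    o2 = out_data.reshape(N, O, H * W)
    for i in range(kh):
        for j in range(kw):
            sl = xp[:, :, i : i + H, j : j + W]
            o2 += (w.data[:, :, i, j] @ sl.reshape(N, C, -1)) if sl.flags.c_contiguous else (
                w.data[:, :, i, j] @ np.ascontiguousarray(sl).reshape(N, C, -1)
            )
    if bias is not None:
        out_data += bias.data.reshape(1, O, 1, 1)
    parents = (x, w) if bias is None else (x, w, bias)
    out = Tensor(out_data, _parents=parents)

    def _bw(g):
        g2 = np.ascontiguousarray(g).reshape(N, O, H * W)
        if bias is not None and (bias.requires_grad or bias._parents):
            bias._accumulate(g.sum(axis=(0, 2, 3)).reshape(bias.shape))
        need_x = x.requires_grad or x._parents
        need_w = w.requires_grad or w._parents
        gxp = np.zeros_like(xp) if need_x else None
        gw = np.zeros_like(w.data) if need_w else None
        gr = g2.reshape(N, O, H, W)
        for i in range(kh):
            for j in range(kw):
                sl = np.ascontiguousarray(xp[:, :, i : i + H, j : j + W]).reshape(N, C, -1)
                if need_w:
                    gw[:, :, i, j] = np.einsum("nop,ncp->oc", g2, sl, optimize=True)
                if need_x:
                    gxp[:, :, i : i + H, j : j + W] += (
                        np.swapaxes(w.data[:, :, i, j], 0, 1) @ g2
                    ).reshape(N, C, H, W)
        if need_w:
            w._accumulate(gw)
        if need_x:
            x._accumulate(_fold_pad_grad(gxp, ph, pw, pad_mode))

    out._backward = _bw if Tensor._needs_graph(x, w) or (bias is not None and Tensor._needs_graph(bias)) else None
    return out


def conv2d(
    x: Tensor,
    w: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int | str = 0,
    pad_mode: str = "zeros",
) -> Tensor:
    """2-D cross-correlation of ``x`` (N,C,H,W) with ``w`` (O,C,kh,kw)."""
    x, w = as_tensor(x), as_tensor(w)
    N, C, H, W = x.shape
    O, Cw, kh, kw = w.shape
    if C != Cw:
        raise ValueError(f"conv2d: input has {C} channels, weight expects {Cw}")
    if padding == "same":
        if stride != 1:
            raise ValueError("'same' padding requires stride 1")
        ph, pw = kh // 2, kw // 2
    else:
        ph = pw = int(padding)
    if kh == 1 and kw == 1 and stride == 1 and ph == 0 and pw == 0:
        return _conv1x1(x, w, bias)
    if stride == 1 and ph == kh // 2 and pw == kw // 2:
        return _conv_taps(x, w, bias, ph, pw, pad_mode)
    xp = _pad_hw(x.data, ph, pw, pad_mode)
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho, Wo = (Hp - kh) // stride + 1, (Wp - kw) // stride + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(N * Ho * Wo, C * kh * kw)
    wmat = w.data.reshape(O, C * kh * kw)
    out_data = (cols @ wmat.T).reshape(N, Ho, Wo, O).transpose(0, 3, 1, 2)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, O, 1, 1)
    parents = (x, w) if bias is None else (x, w, bias)
    out = Tensor(np.ascontiguousarray(out_data), _parents=parents)

    def _bw(g):
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * Ho * Wo, O)
        if w.requires_grad or w._parents:
            w._accumulate((gm.T @ cols).reshape(w.shape))
        if bias is not None and (bias.requires_grad or bias._parents):
            bias._accumulate(gm.sum(axis=0).reshape(bias.shape))
        if x.requires_grad or x._parents:
            gcols = (gm @ wmat).reshape(N, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride] += gcols[..., i, j]
            x._accumulate(_fold_pad_grad(gxp, ph, pw, pad_mode))

    out._backward = _bw if Tensor._needs_graph(x, w) or (bias is not None and Tensor._needs_graph(bias)) else None
    return out


def conv_transpose2d(x: Tensor, w: Tensor, stride: int = 2) -> Tensor:
    """Transposed convolution; ``w`` has shape (C_in, C_out, k, k).

    With ``k == stride`` (the default use here: 2x2 kernel, stride 2) the
    output is exactly ``stride`` times the input size with no overlap
    ambiguity.
    """
    x, w = as_tensor(x), as_tensor(w)
    N, C, H, W = x.shape
    Cw, O, kh, kw = w.shape
    if C != Cw:
        raise ValueError(f"conv_transpose2d: input has {C} channels, weight expects {Cw}")
    Ho, Wo = (H - 1) * stride + kh, (W - 1) * stride + kw
    xm = np.ascontiguousarray(x.data.transpose(0, 2, 3, 1)).reshape(N * H * W, C)
    out_data = np.zeros((N, O, Ho, Wo), dtype=x.data.dtype)
    # per-tap scatter: each kernel tap writes a strided grid
    ymat = xm @ w.data.reshape(C, O * kh * kw)  # (NHW, O*kh*kw)
    ymat = ymat.reshape(N, H, W, O, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            out_data[:, :, i : i + stride * H : stride, j : j + stride * W : stride] += ymat[..., i, j]
    out = Tensor(out_data, _parents=(x, w))

    def _bw(g):
        gwin = sliding_window_view(g, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
        gcols = np.ascontiguousarray(gwin.transpose(0, 2, 3, 1, 4, 5)).reshape(N * H * W, O * kh * kw)
        if x.requires_grad or x._parents:
            gx = (gcols @ w.data.reshape(C, O * kh * kw).T).reshape(N, H, W, C).transpose(0, 3, 1, 2)
            x._accumulate(np.ascontiguousarray(gx))
        if w.requires_grad or w._parents:
            w._accumulate((xm.T @ gcols).reshape(w.shape))

    out._backward = _bw if Tensor._needs_graph(x, w) else None
    return out


def depthwise_conv2d(x: Tensor, w: Tensor, pad_mode: str = "edge") -> Tensor:
    """Per-channel (depthwise) convolution; ``w`` has shape (C, k, k)."""
    x, w = as_tensor(x), as_tensor(w)
    N, C, H, W = x.shape
    Cw, kh, kw = w.shape
    if C != Cw:
        raise ValueError(f"depthwise_conv2d: input has {C} channels, weight expects {Cw}")
    ph, pw = kh // 2, kw // 2
    xp = _pad_hw(x.data, ph, pw, pad_mode)
    # per-tap accumulation: cheaper than materializing the window view
    out_data = np.zeros_like(x.data)
    for i in range(kh):
        for j in range(kw):
            out_data += xp[:, :, i : i + H, j : j + W] * w.data[None, :, i, j, None, None]
    out = Tensor(out_data, _parents=(x, w))

    def _bw(g):
        if w.requires_grad or w._parents:
            gw = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    gw[:, i, j] = np.einsum("nchw,nchw->c", g, xp[:, :, i : i + H, j : j + W])
            w._accumulate(gw)
        if x.requires_grad or x._parents:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + H, j : j + W] += g * w.data[None, :, i, j, None, None]
            x._accumulate(_fold_pad_grad(gxp, ph, pw, pad_mode))

    out._backward = _bw if Tensor._needs_graph(x, w) else None
    return out


def gather_hw(x: Tensor, rows: np.ndarray, cols: np.ndarray) -> Tensor:
    """Gather ``x[n, :, rows[n, ...], cols[n, ...]]`` -> (N, C, *rows.shape[1:]).

    ``rows``/``cols`` are integer index arrays shared across channels.
    """
    x = as_tensor(x)
    N, C, H, W = x.shape
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    tail = rows.shape[1:]
    idx = (rows.astype(np.intp) * W + cols.astype(np.intp)).reshape(N, 1, -1)
    flat = x.data.reshape(N, C, H * W)
    out = Tensor(np.take_along_axis(flat, idx, axis=2).reshape(N, C, *tail), _parents=(x,))

    def _bw(g):
        gflat = np.zeros((N, C, H * W), dtype=x.data.dtype)
        np.add.at(
            gflat,
            (np.arange(N)[:, None, None], np.arange(C)[None, :, None], idx),
            g.reshape(N, C, -1),
        )
        x._accumulate(gflat.reshape(x.shape))

    out._backward = _bw if Tensor._needs_graph(x) else None
    return out


def bilinear_sample(x: Tensor, rows, cols) -> Tensor:
    """Bilinear interpolation of ``x`` (N,C,H,W) at fractional coordinates.

    ``rows`` and ``cols`` have shape (N, *S) (Tensor or array, gradients
    flow into Tensor coordinates); the result has shape (N, C, *S).
    Pixel centers sit at integer (row, col) coordinates with the origin at
    the top-left; coordinates outside the image are clamped to the border.
    """
    x = as_tensor(x)
    rows = as_tensor(rows, dtype=x.dtype)
    cols = as_tensor(cols, dtype=x.dtype)
    if not (np.all(np.isfinite(rows.data)) and np.all(np.isfinite(cols.data))):
        raise ValueError("bilinear_sample: coordinates must be finite")
    N, C, H, W = x.shape
    r = rows.clip(0.0, float(H - 1))
    c = cols.clip(0.0, float(W - 1))
    r0 = np.minimum(np.floor(r.data), max(H - 2, 0)).astype(np.intp)
    c0 = np.minimum(np.floor(c.data), max(W - 2, 0)).astype(np.intp)
    r1 = np.minimum(r0 + 1, H - 1)
    c1 = np.minimum(c0 + 1, W - 1)
    fr = (r - r0.astype(x.dtype)).reshape((N, 1) + r.shape[1:])
    fc = (c - c0.astype(x.dtype)).reshape((N, 1) + c.shape[1:])
    v00 = gather_hw(x, r0, c0)
    v01 = gather_hw(x, r0, c1)
    v10 = gather_hw(x, r1, c0)
    v11 = gather_hw(x, r1, c1)
    top = v00 + (v01 - v00) * fc
    bot = v10 + (v11 - v10) * fc
    return top + (bot - top) * fr


def snake_sample_contract(x: Tensor, offsets: Tensor, weights: Tensor, axis: str) -> Tensor:
    """Fused snake-convolution kernel: deformable sampling + tap contraction.

    For every output position, gathers ``K`` linearly interpolated samples
    along the tap path (taps spread along ``axis``, offsets displace the
    perpendicular coordinate) and contracts them with ``weights``
    (out_channels, in_channels, K).  Mathematically identical to
    ``bilinear_sample`` + a 1x1 convolution over the stacked taps, but a
    single primitive: it avoids materializing the interpolation graph,
    which dominates both time and memory at training scale.
    """
    x, offsets, weights = as_tensor(x), as_tensor(offsets), as_tensor(weights)
    N, C, H, W = x.shape
    O, Cw, K = weights.shape
    taps = np.arange(K, dtype=np.intp) - K // 2
    frac_extent = H if axis == "x" else W
    step = W if axis == "x" else 1
    if axis == "x":
        base = np.arange(H, dtype=np.float32).reshape(1, 1, H, 1)
    else:
        base = np.arange(W, dtype=np.float32).reshape(1, 1, 1, W)
    coord = offsets.data + base  # (N, K, H, W)
    inside = ((coord > 0.0) & (coord < frac_extent - 1)).astype(x.dtype)
    np.clip(coord, 0.0, frac_extent - 1, out=coord)
    lo = np.minimum(np.floor(coord), max(frac_extent - 2, 0))
    f = coord - lo
    lo = lo.astype(np.int32)
    # flat pixel index of the low sample, per tap
    if axis == "x":
        grid = np.arange(W, dtype=np.int32).reshape(1, 1, 1, W)
        idx0 = lo * W + np.clip(grid + taps.reshape(1, K, 1, 1).astype(np.int32), 0, W - 1)
    else:
        grid = np.arange(H, dtype=np.int32).reshape(1, 1, H, 1) * W
        idx0 = lo + np.clip(
            grid + taps.reshape(1, K, 1, 1).astype(np.int32) * W, 0, (H - 1) * W
        )
    flat = np.ascontiguousarray(x.data).reshape(N, C, H * W)
    wmat = weights.data.reshape(O, C, K)
    out_data = np.zeros((N, O, H * W), dtype=x.data.dtype)
    v_taps: list[np.ndarray] = []
    d_taps: list[np.ndarray] = []
    for k in range(K):
        i0 = idx0[:, k].reshape(N, 1, H * W)
        a = np.take_along_axis(flat, i0, axis=2)
        b = np.take_along_axis(flat, i0 + step, axis=2) if frac_extent > 1 else a.copy()
        b -= a
        d_taps.append(b.copy())
        b *= f[:, None, k].reshape(N, 1, H * W)
        b += a
        v_taps.append(b)  # (N, C, HW)
        out_data += wmat[:, :, k] @ b
    out = Tensor(out_data.reshape(N, O, H, W), _parents=(x, offsets, weights))

    def _bw(g):
        g2 = g.reshape(N, O, H * W)
        need_x = x.requires_grad or x._parents
        need_off = offsets.requires_grad or offsets._parents
        need_w = weights.requires_grad or weights._parents
        gw = np.zeros_like(wmat) if need_w else None
        goff = np.zeros((N, K, H * W), dtype=x.data.dtype) if need_off else None
        gflat = np.zeros((N, C, H * W), dtype=x.data.dtype) if need_x else None
        nidx = np.arange(N)[:, None, None]
        cidx = np.arange(C)[None, :, None]
        for k in range(K):
            if need_w:
                gw[:, :, k] = np.einsum("nop,ncp->oc", g2, v_taps[k], optimize=True)
            if need_x or need_off:
                gv = np.swapaxes(wmat[:, :, k], 0, 1) @ g2  # (N, C, HW)
                if need_off:
                    goff[:, k] = (gv * d_taps[k]).sum(axis=1)
                if need_x:
                    i0 = idx0[:, k].reshape(N, 1, H * W)
                    fk = f[:, None, k].reshape(N, 1, H * W)
                    gb = gv * fk
                    if frac_extent > 1:
                        np.add.at(gflat, (nidx, cidx, i0 + step), gb)
                    np.add.at(gflat, (nidx, cidx, i0), gv - gb)
        if need_w:
            weights._accumulate(gw.reshape(weights.shape))
        if need_off:
            offsets._accumulate(goff.reshape(N, K, H, W) * inside)
        if need_x:
            x._accumulate(gflat.reshape(x.shape))

    out._backward = _bw if Tensor._needs_graph(x, offsets, weights) else None
    return out


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int, eps: float = 1e-5) -> Tensor:
    """Fused group normalization with affine parameters (gamma, beta per channel)."""
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    N, C, H, W = x.shape
    xg = x.data.reshape(N, groups, -1)
    mu = xg.mean(axis=2, keepdims=True)
    var = xg.var(axis=2, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mu) * inv).reshape(N, C, H, W)
    gma = gamma.data.reshape(1, C, 1, 1)
    out = Tensor(xhat * gma + beta.data.reshape(1, C, 1, 1), _parents=(x, gamma, beta))

    def _bw(g):
        if gamma.requires_grad or gamma._parents:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad or beta._parents:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            gxh = (g * gma).reshape(N, groups, -1)
            xh = xhat.reshape(N, groups, -1)
            m1 = gxh.mean(axis=2, keepdims=True)
            m2 = (gxh * xh).mean(axis=2, keepdims=True)
            gx = (gxh - m1 - xh * m2) * inv
            x._accumulate(gx.reshape(x.shape))

    out._backward = _bw if Tensor._needs_graph(x, gamma, beta) else None
    return out


# ------------------------------------------------------------------ activations
def silu(x: Tensor) -> Tensor:
    """SiLU (swish): x * sigmoid(x), fused."""
    x = as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    out = Tensor(x.data * s, _parents=(x,))

    def _bw(g):
        x._accumulate(g * (s + x.data * s * (1.0 - s)))

    out._backward = _bw if Tensor._needs_graph(x) else None
    return out


def gelu(x: Tensor) -> Tensor:
    """Exact GELU via the Gauss error function, fused."""
    from scipy import special as _special

    x = as_tensor(x)
    cdf = 0.5 * (1.0 + _special.erf(x.data * np.float32(1.0 / np.sqrt(2.0))))
    out = Tensor(x.data * cdf.astype(x.dtype), _parents=(x,))

    def _bw(g):
        pdf = np.exp(-0.5 * x.data**2) * np.float32(1.0 / np.sqrt(2.0 * np.pi))
        x._accumulate(g * (cdf + x.data * pdf))

    out._backward = _bw if Tensor._needs_graph(x) else None
    return out


def softplus(x: Tensor) -> Tensor:
    return (x.exp() + 1.0).log()
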