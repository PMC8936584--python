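"""A small reverse-mode automatic-differentiation engine on numpy arrays.

The engine provides exactly the operations the segmentation network needs:
elementwise arithmetic, matmul, fused 2-D convolutions (dense and depthwise),
batch normalization, bilinear upsampling, differentiable bilinear grid
sampling, global pooling, and the loss primitives.  Heavy operations are
implemented as *fused* nodes with hand-written backward passes (verified by
finite differences in the test suite) so a training step builds a graph of a
few hundred nodes rather than tens of thousands.

Convolutions are evaluated as k*k batched GEMMs (one per kernel offset),
which keeps all the arithmetic inside BLAS.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "add", "mul", "matmul", "relu", "sigmoid", "clip", "concat",
    "reshape", "transpose", "tsum", "tmean", "global_avg_pool",
    "narrow", "affine_grid",
    "conv2d", "depthwise_conv2d", "batch_norm", "upsample_bilinear",
    "grid_sample", "softmax_cross_entropy", "smooth_l1_loss", "linear",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference / frozen forward passes)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operators -----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 or isinstance(shape[0], int) else shape[0])

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    # -- autodiff ------------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()
        # closures reference their output node (a cycle); break the graph so
        # intermediate activations free without waiting for the gc.  Leaf
        # tensors (parameters) keep their accumulated gradient.
        for node in topo:
            if node._backward is not None and node is not self:
                node.grad = None
            node._backward = None
            node._parents = ()

    def zero_grad(self):
        self.grad = None


# -- graph-construction helpers ---------------------------------------------

def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _acc(t: Tensor, g: np.ndarray):
    if t.requires_grad:
        t.grad = g if t.grad is None else t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# -- elementwise and shape ops ----------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward():
        _acc(a, _unbroadcast(out.grad, a.shape))
        _acc(b, _unbroadcast(out.grad, b.shape))

    out = _make(out_data, (a, b), backward)
    return out


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward():
        _acc(a, _unbroadcast(out.grad * b.data, a.shape))
        _acc(b, _unbroadcast(out.grad * a.data, b.shape))

    out = _make(out_data, (a, b), backward)
    return out


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def backward():
        ga = out.grad @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ out.grad
        _acc(a, _unbroadcast(ga, a.shape))
        _acc(b, _unbroadcast(gb, b.shape))

    out = _make(out_data, (a, b), backward)
    return out


def relu(x: Tensor) -> Tensor:
    x = _wrap(x)
    out_data = np.maximum(x.data, 0)

    def backward():
        _acc(x, out.grad * (out.data > 0))

    out = _make(out_data, (x,), backward)
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = _wrap(x)
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def backward():
        _acc(x, out.grad * out.data * (1.0 - out.data))

    out = _make(out_data, (x,), backward)
    return out


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes through strictly inside (lo, hi)."""
    x = _wrap(x)
    out_data = np.clip(x.data, lo, hi)

    def backward():
        inside = (x.data > lo) & (x.data < hi)
        _acc(x, out.grad * inside)

    out = _make(out_data, (x,), backward)
    return out


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]

    def backward():
        pieces = np.split(out.grad, np.cumsum(sizes)[:-1], axis=axis)
        for t, g in zip(ts, pieces):
            _acc(t, g)

    out = _make(out_data, ts, backward)
    return out


def reshape(x: Tensor, shape) -> Tensor:
    x = _wrap(x)
    out_data = x.data.reshape(shape)

    def backward():
        _acc(x, out.grad.reshape(x.shape))

    out = _make(out_data, (x,), backward)
    return out


def transpose(x: Tensor, axes) -> Tensor:
    x = _wrap(x)
    out_data = x.data.transpose(axes)
    inv = np.argsort(axes)

    def backward():
        _acc(x, out.grad.transpose(inv))

    out = _make(out_data, (x,), backward)
    return out


def tsum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    x = _wrap(x)
    out_data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward():
        g = out.grad
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        _acc(x, np.broadcast_to(g, x.shape).copy())

    out = _make(out_data, (x,), backward)
    return out


def tmean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    x = _wrap(x)
    n = x.size if axis is None else np.prod([x.shape[a] for a in np.atleast_1d(axis)])
    return mul(tsum(x, axis=axis, keepdims=keepdims), 1.0 / float(n))


def global_avg_pool(x: Tensor) -> Tensor:
    """(B, C, H, W) -> (B, C, 1, 1) spatial mean."""
    x = _wrap(x)
    B, C, H, W = x.shape
    out_data = x.data.mean(axis=(2, 3), keepdims=True)

    def backward():
        _acc(x, np.broadcast_to(out.grad / (H * W), x.shape).copy())

    out = _make(out_data, (x,), backward)
    return out


def narrow(x: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Slice ``length`` entries from ``start`` along ``axis``."""
    x = _wrap(x)
    idx = [slice(None)] * x.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)
    out_data = x.data[idx]

    def backward():
        g = np.zeros_like(x.data)
        g[idx] = out.grad
        _acc(x, g)

    out = _make(out_data, (x,), backward)
    return out


def affine_grid(theta4: Tensor, H: int, W: int) -> Tensor:
    """Sampling grid for a shear-free affine transform.

    ``theta4``: (B, 4) rows of (s_x, s_y, t_x, t_y).  Returns (B, H, W, 2)
    normalized source coordinates x_s = s_x * x_t + t_x, y_s = s_y * y_t + t_y
    over the canonical align-corners target grid.
    """
    theta4 = _wrap(theta4)
    B = theta4.shape[0]
    xt = np.linspace(-1.0, 1.0, W, dtype=theta4.dtype) if W > 1 else np.zeros(1, theta4.dtype)
    yt = np.linspace(-1.0, 1.0, H, dtype=theta4.dtype) if H > 1 else np.zeros(1, theta4.dtype)
    XT, YT = np.meshgrid(xt, yt)
    sx = theta4.data[:, 0][:, None, None]
    sy = theta4.data[:, 1][:, None, None]
    tx = theta4.data[:, 2][:, None, None]
    ty = theta4.data[:, 3][:, None, None]
    out_data = np.stack([sx * XT[None] + tx, sy * YT[None] + ty], axis=-1)

    def backward():
        g = out.grad
        gt = np.stack([
            (g[..., 0] * XT[None]).sum(axis=(1, 2)),
            (g[..., 1] * YT[None]).sum(axis=(1, 2)),
            g[..., 0].sum(axis=(1, 2)),
            g[..., 1].sum(axis=(1, 2)),
        ], axis=1)
        _acc(theta4, gt)

    out = _make(out_data, (theta4,), backward)
    return out


# -- fused convolution ops ---------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation: x (B,Cin,H,W), w (Cout,Cin,k,k) -> (B,Cout,Ho,Wo)."""
    x, w = _wrap(x), _wrap(w)
    B, Cin, H, W = x.shape
    Cout, Cin_w, kh, kw = w.shape
    if Cin != Cin_w:
        raise ValueError(f"conv2d channel mismatch: input {Cin}, weight {Cin_w}")
    s, p = stride, padding
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    out_data = np.zeros((B, Cout, Ho * Wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i:i + s * Ho:s, j:j + s * Wo:s]
            out_data += np.matmul(w.data[:, :, i, j], xs.reshape(B, Cin, Ho * Wo))
    out_data = out_data.reshape(B, Cout, Ho, Wo)
    if b is not None:
        out_data = out_data + b.data.reshape(1, Cout, 1, 1)

    def backward():
        gy = out.grad.reshape(B, Cout, Ho * Wo)
        if b is not None:
            _acc(b, out.grad.sum(axis=(0, 2, 3)))
        need_x = x.requires_grad
        gxp = np.zeros_like(xp) if need_x else None
        gw = np.zeros_like(w.data) if w.requires_grad else None
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, :, i:i + s * Ho:s, j:j + s * Wo:s]
                if gw is not None:
                    gw[:, :, i, j] = np.matmul(
                        gy, xs.reshape(B, Cin, Ho * Wo).transpose(0, 2, 1)).sum(axis=0)
                if need_x:
                    gxs = np.matmul(w.data[:, :, i, j].T, gy).reshape(B, Cin, Ho, Wo)
                    gxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += gxs
        if gw is not None:
            _acc(w, gw)
        if need_x:
            _acc(x, gxp[:, :, p:p + H, p:p + W] if p else gxp)

    parents = (x, w) if b is None else (x, w, b)
    out = _make(out_data, parents, backward)
    return out


def depthwise_conv2d(x: Tensor, w: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """Per-channel conv: x (B,C,H,W), w (C,k,k) -> (B,C,Ho,Wo)."""
    x, w = _wrap(x), _wrap(w)
    B, C, H, W = x.shape
    Cw, kh, kw = w.shape
    if C != Cw:
        raise ValueError(f"depthwise channel mismatch: input {C}, weight {Cw}")
    s, p = stride, padding
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    out_data = np.zeros((B, C, Ho, Wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i:i + s * Ho:s, j:j + s * Wo:s]
            out_data += w.data[None, :, i, j, None, None] * xs

    def backward():
        gy = out.grad
        need_x = x.requires_grad
        gxp = np.zeros_like(xp) if need_x else None
        gw = np.zeros_like(w.data) if w.requires_grad else None
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, :, i:i + s * Ho:s, j:j + s * Wo:s]
                if gw is not None:
                    gw[:, i, j] = (gy * xs).sum(axis=(0, 2, 3))
                if need_x:
                    gxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += \
                        w.data[None, :, i, j, None, None] * gy
        if gw is not None:
            _acc(w, gw)
        if need_x:
            _acc(x, gxp[:, :, p:p + H, p:p + W] if p else gxp)

    out = _make(out_data, (x, w), backward)
    return out


# -- batch normalization -----------------------------------------------------

def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Channel batch-norm over (B, C, H, W); updates running stats in place."""
    x, gamma, beta = _wrap(x), _wrap(gamma), _wrap(beta)
    B, C, H, W = x.shape
    if training:
        mean = x.data.mean(axis=(0, 2, 3), dtype=np.float64)
        var = x.data.var(axis=(0, 2, 3), dtype=np.float64)
        running_mean *= (1 - momentum)
        running_mean += momentum * mean
        running_var *= (1 - momentum)
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    # do the normalization in the input dtype so float32 nets stay float32
    mean = mean.astype(x.dtype, copy=False)
    invstd = (1.0 / np.sqrt(var + eps)).astype(x.dtype, copy=False)
    xhat = (x.data - mean[None, :, None, None]) * invstd[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward():
        gy = out.grad
        dgamma = (gy * xhat).sum(axis=(0, 2, 3))
        dbeta = gy.sum(axis=(0, 2, 3))
        _acc(gamma, dgamma)
        _acc(beta, dbeta)
        if not x.requires_grad:
            return
        gscale = (gamma.data * invstd)[None, :, None, None]
        if training:
            M = B * H * W
            gx = gscale / M * (M * gy
                               - dbeta[None, :, None, None]
                               - xhat * dgamma[None, :, None, None])
        else:
            gx = gscale * gy
        _acc(x, gx)

    out = _make(out_data, (x, gamma, beta), backward)
    return out


# -- resampling --------------------------------------------------------------

def _interp_matrix(n_out: int, n_in: int, dtype, align_corners: bool) -> np.ndarray:
    """Row-stochastic 1-D bilinear interpolation matrix.

    Half-pixel sampling (``align_corners=False``) keeps the scale uniform,
    so upsampling commutes with shifts by whole stride multiples — the FCN
    and head upsampling layers rely on that; align-corners matches the
    sampler's grid convention.
    """
    A = np.zeros((n_out, n_in), dtype=dtype)
    if n_out == 1 or n_in == 1:
        A[:, 0] = 1.0
        return A
    if align_corners:
        pos = np.linspace(0.0, n_in - 1.0, n_out)
    else:
        pos = np.clip((np.arange(n_out) + 0.5) * n_in / n_out - 0.5,
                      0.0, n_in - 1.0)
    i0 = np.minimum(np.floor(pos).astype(int), n_in - 2)
    frac = pos - i0
    for r in range(n_out):
        A[r, i0[r]] += 1.0 - frac[r]
        A[r, i0[r] + 1] += frac[r]
    return A


def upsample_bilinear(x: Tensor, out_h: int, out_w: int,
                      align_corners: bool = False) -> Tensor:
    """Bilinear resize of (B, C, H, W) maps; exactly linear."""
    x = _wrap(x)
    B, C, H, W = x.shape
    if (out_h, out_w) == (H, W):
        return x
    Ah = _interp_matrix(out_h, H, x.dtype, align_corners)
    Aw = _interp_matrix(out_w, W, x.dtype, align_corners)
    out_data = np.matmul(np.matmul(Ah, x.data), Aw.T)

    def backward():
        _acc(x, np.matmul(np.matmul(Ah.T, out.grad), Aw))

    out = _make(out_data, (x,), backward)
    return out


def grid_sample(x: Tensor, grid) -> Tensor:
    """Differentiable bilinear sampling with zero padding outside the image.

    ``x``: (B, C, H, W); ``grid``: (B, Ho, Wo, 2) normalized (x, y) source
    coordinates in the align-corners convention ((-1,-1) = top-left pixel
    centre).  Each output pixel is the truncated-kernel weighted sum
    sum_{n,m} x[n,m] * max(0, 1-|xs-m|) * max(0, 1-|ys-n|), which makes the
    op differentiable in both the image and the sampling grid.
    """
    x = _wrap(x)
    grid = grid if isinstance(grid, Tensor) else Tensor(np.asarray(grid))
    B, C, H, W = x.shape
    Bg, Ho, Wo, two = grid.shape
    if Bg != B or two != 2:
        raise ValueError(f"grid shape {grid.shape} incompatible with input {x.shape}")
    px = (grid.data[..., 0] + 1.0) * 0.5 * (W - 1)
    py = (grid.data[..., 1] + 1.0) * 0.5 * (H - 1)
    # snap coordinates that are integers up to rounding error, so the
    # identity transform is an exact identity resampling
    for p in (px, py):
        r = np.rint(p)
        near = np.abs(p - r) < 1e-9
        p[near] = r[near]
    x0 = np.floor(px).astype(np.int64)
    y0 = np.floor(py).astype(np.int64)
    wx = px - x0
    wy = py - y0
    bidx = np.arange(B)[:, None, None]

    def corner(xi, yi):
        valid = (xi >= 0) & (xi < W) & (yi >= 0) & (yi < H)
        xc = np.clip(xi, 0, W - 1)
        yc = np.clip(yi, 0, H - 1)
        vals = x.data[bidx, :, yc, xc]          # (B, Ho, Wo, C)
        return vals * valid[..., None], valid, xc, yc

    v00, m00, x00, y00 = corner(x0, y0)
    v01, m01, x01, y01 = corner(x0 + 1, y0)
    v10, m10, x10, y10 = corner(x0, y0 + 1)
    v11, m11, x11, y11 = corner(x0 + 1, y0 + 1)
    wxe = wx[..., None]
    wye = wy[..., None]
    out_data = ((1 - wye) * ((1 - wxe) * v00 + wxe * v01)
                + wye * ((1 - wxe) * v10 + wxe * v11))
    out_data = np.ascontiguousarray(out_data.transpose(0, 3, 1, 2))

    def backward():
        gy = out.grad.transpose(0, 2, 3, 1)      # (B, Ho, Wo, C)
        if x.requires_grad:
            gx = np.zeros_like(x.data.transpose(0, 2, 3, 1))  # (B, H, W, C)
            for (xc, yc, m, wgt) in (
                (x00, y00, m00, (1 - wx) * (1 - wy)),
                (x01, y01, m01, wx * (1 - wy)),
                (x10, y10, m10, (1 - wx) * wy),
                (x11, y11, m11, wx * wy),
            ):
                np.add.at(gx, (bidx, yc, xc), gy * (wgt * m)[..., None])
            _acc(x, np.ascontiguousarray(gx.transpose(0, 3, 1, 2)))
        if grid.requires_grad:
            dpx = (gy * ((1 - wye) * (v01 - v00) + wye * (v11 - v10))).sum(axis=-1)
            dpy = (gy * ((1 - wxe) * (v10 - v00) + wxe * (v11 - v01))).sum(axis=-1)
            g = np.stack([dpx * 0.5 * (W - 1), dpy * 0.5 * (H - 1)], axis=-1)
            _acc(grid, g)

    out = _make(out_data, (x, grid), backward)
    return out


# -- loss primitives ---------------------------------------------------------

def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean per-pixel softmax cross-entropy.

    ``logits``: (B, K) or (B, K, H, W); ``labels``: integer array (B,) or
    (B, H, W) with values in [0, K).
    """
    logits = _wrap(logits)
    labels = np.asarray(labels)
    if logits.ndim == 2:
        lg = logits.data[:, :, None, None]
        lb = labels[:, None, None]
    else:
        lg, lb = logits.data, labels
    B, K = lg.shape[0], lg.shape[1]
    if lb.min() < 0 or lb.max() >= K:
        raise ValueError(f"labels must lie in [0, {K})")
    m = lg.max(axis=1, keepdims=True)
    ex = np.exp(lg - m)
    Z = ex.sum(axis=1, keepdims=True)
    logp = lg - m - np.log(Z)
    bi = np.arange(B)[:, None, None]
    hi = np.arange(lg.shape[2])[None, :, None]
    wi = np.arange(lg.shape[3])[None, None, :]
    picked = logp[bi, lb, hi, wi]
    M = picked.size
    out_data = np.asarray(-picked.sum() / M)

    def backward():
        soft = ex / Z
        soft[bi, lb, hi, wi] -= 1.0
        g = soft * (out.grad / M)
        _acc(logits, g.reshape(logits.shape))

    out = _make(out_data, (logits,), backward)
    return out


def smooth_l1_loss(pred: Tensor, target) -> Tensor:
    """Mean elementwise smooth-L1: 0.5 r^2 for |r| < 1, |r| - 0.5 otherwise."""
    pred = _wrap(pred)
    t = target.data if isinstance(target, Tensor) else np.asarray(target)
    r = pred.data - t
    absr = np.abs(r)
    vals = np.where(absr < 1.0, 0.5 * r * r, absr - 0.5)
    M = vals.size
    out_data = np.asarray(vals.sum() / M)

    def backward():
        g = np.clip(r, -1.0, 1.0) * (out.grad / M)
        _acc(pred, g)

    out = _make(out_data, (pred,), backward)
    return out


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Affine map: x (B, F) @ w (F, O) + b (O,)."""
    out = matmul(x, w)
    if b is not None:
        out = add(out, b)
    return out
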