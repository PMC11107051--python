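"""Handwritten adjoints for the structured 3D operators.

Each function takes and returns :class:`~hcadan.nn.autograd.Tensor` and wires
an explicit backward closure.  Conventions used throughout the package:

* volumes are laid out ``(N, C, D, H, W)`` with ``D`` the through-plane axis;
* all convolutions are stride 1 with "same" zero padding and odd kernels, so
  the gradient w.r.t. the input is the correlation with the flipped kernel;
* resolution changes happen only in dedicated pooling / transpose-conv /
  interpolation ops, which keeps every adjoint short and exactly testable
  against finite differences.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .autograd import Tensor


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _corr3d(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Stride-1 'same' correlation of (N,C,D,H,W) with (O,C,kz,ky,kx)."""
    kz, ky, kx = w.shape[2:]
    if (kz, ky, kx) == (1, 1, 1):
        return np.einsum("oc,ncdhw->nodhw", w[:, :, 0, 0, 0], x)
    xp = np.pad(x, ((0, 0), (0, 0), (kz // 2,) * 2, (ky // 2,) * 2, (kx // 2,) * 2))
    win = sliding_window_view(xp, (kz, ky, kx), axis=(2, 3, 4))  # N,C,D,H,W,kz,ky,kx
    n, c, d, h, ww = x.shape
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7))
    cols = cols.reshape(n * d * h * ww, c * kz * ky * kx)
    y = cols @ w.reshape(w.shape[0], -1).T
    return y.reshape(n, d, h, ww, w.shape[0]).transpose(0, 4, 1, 2, 3)


def _corr3d_wgrad(x: np.ndarray, gy: np.ndarray, kshape) -> np.ndarray:
    """Gradient of _corr3d w.r.t. the kernel, shape (O,C,kz,ky,kx)."""
    kz, ky, kx = kshape
    if (kz, ky, kx) == (1, 1, 1):
        return np.einsum("nodhw,ncdhw->oc", gy, x)[:, :, None, None, None]
    xp = np.pad(x, ((0, 0), (0, 0), (kz // 2,) * 2, (ky // 2,) * 2, (kx // 2,) * 2))
    win = sliding_window_view(xp, (kz, ky, kx), axis=(2, 3, 4))
    return np.einsum("ncdhwijk,nodhw->ocijk", win, gy, optimize=True)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """3D correlation, stride 1, same padding, odd kernel sizes."""
    y = _corr3d(x.data, w.data)
    if b is not None:
        y = y + b.data[None, :, None, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if x.requires_grad:
            wf = w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            x._accumulate(_corr3d(g, np.ascontiguousarray(wf)))
        if w.requires_grad:
            w._accumulate(_corr3d_wgrad(x.data, g, w.data.shape[2:]))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))

    return Tensor._make(y, parents, backward)


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None, stride) -> Tensor:
    """Transpose convolution with kernel == stride (non-overlapping tiles).

    ``w`` has shape (C_in, C_out, sz, sy, sx); output spatial dims are the
    input dims multiplied by the stride.
    """
    sz, sy, sx = stride
    n, c, d, h, ww = x.data.shape
    o = w.data.shape[1]
    y = np.tensordot(x.data, w.data, axes=([1], [0]))  # n,d,h,w,o,sz,sy,sx
    y = y.transpose(0, 4, 1, 5, 2, 6, 3, 7).reshape(n, o, d * sz, h * sy, ww * sx)
    if b is not None:
        y = y + b.data[None, :, None, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gb = g.reshape(n, o, d, sz, h, sy, ww, sx).transpose(0, 2, 4, 6, 1, 3, 5, 7)
        if x.requires_grad:
            x._accumulate(np.tensordot(gb, w.data, axes=([4, 5, 6, 7], [1, 2, 3, 4])
                                       ).transpose(0, 4, 1, 2, 3))
        if w.requires_grad:
            w._accumulate(np.tensordot(x.data, gb, axes=([0, 2, 3, 4], [0, 1, 2, 3])))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))

    return Tensor._make(y, parents, backward)


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def avg_pool_down(x: Tensor, factor) -> Tensor:
    """Average pooling with kernel == stride; dims must be divisible."""
    fz, fy, fx = factor
    n, c, d, h, w = x.data.shape
    if d % fz or h % fy or w % fx:
        raise ValueError(f"shape {(d, h, w)} not divisible by pooling factor {factor}")
    xr = x.data.reshape(n, c, d // fz, fz, h // fy, fy, w // fx, fx)
    y = xr.mean(axis=(3, 5, 7))
    scale = 1.0 / (fz * fy * fx)

    def backward(g):
        gg = np.broadcast_to(g[:, :, :, None, :, None, :, None],
                             (n, c, d // fz, fz, h // fy, fy, w // fx, fx))
        x._accumulate((gg * scale).reshape(n, c, d, h, w).astype(x.dtype, copy=False))

    return Tensor._make(y, (x,), backward)


_COUNT_CACHE: dict = {}


def _box_sum(a: np.ndarray, k) -> np.ndarray:
    size = (1, 1) + tuple(k)
    return ndimage.uniform_filter(a, size=size, mode="constant") * float(np.prod(k))


def box_mean_same(x: Tensor, k) -> Tensor:
    """Stride-1 average pooling over a (kz,ky,kx) window, averaged over the
    in-bounds voxels only (a constant field is therefore reproduced exactly,
    including at the borders)."""
    key = (x.data.shape[2:], tuple(k))
    if key not in _COUNT_CACHE:
        ones = np.ones((1, 1) + x.data.shape[2:])
        _COUNT_CACHE[key] = np.maximum(_box_sum(ones, k), 1.0)
    count = _COUNT_CACHE[key].astype(x.dtype, copy=False)
    y = _box_sum(x.data, k) / count

    def backward(g):
        x._accumulate(_box_sum(g / count, k).astype(x.dtype, copy=False))

    return Tensor._make(y, (x,), backward)


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------

def linear_resize_matrix(n_in: int, n_out: int, dtype=np.float64) -> np.ndarray:
    """Dense 1D linear-interpolation matrix with half-pixel sample centers.

    Rows sum to one, so constants are preserved exactly.
    """
    m = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.minimum(src.astype(int), n_in - 2)
    t = src - lo
    m[np.arange(n_out), lo] = 1.0 - t
    m[np.arange(n_out), lo + 1] = t
    return m


def apply_axis_matrix(x: Tensor, m: np.ndarray, axis: int) -> Tensor:
    """y = m @ x along `axis` (the building block of trilinear resizing)."""
    md = m.astype(x.dtype, copy=False)

    def fwd(a, mat):
        moved = np.moveaxis(a, axis, 0)
        out = np.tensordot(mat, moved, axes=([1], [0]))
        return np.moveaxis(out, 0, axis)

    y = fwd(x.data, md)

    def backward(g):
        x._accumulate(fwd(g, md.T))

    return Tensor._make(y, (x,), backward)


def resize_trilinear(x: Tensor, out_shape) -> Tensor:
    """Trilinear resize of (N,C,D,H,W) to spatial `out_shape`."""
    for axis, n_out in zip((2, 3, 4), out_shape):
        n_in = x.data.shape[axis]
        if n_in != n_out:
            x = apply_axis_matrix(x, linear_resize_matrix(n_in, n_out), axis)
    return x


# ---------------------------------------------------------------------------
# point sampling (deformable attention)
# ---------------------------------------------------------------------------

def sample_trilinear(value: Tensor, coords: Tensor) -> Tensor:
    """Sample a feature grid at fractional points.

    value:  (B, C, D, H, W) feature grid.
    coords: (B, Q, 3) normalized coordinates in [0, 1] per axis (z, y, x);
            0 maps to the first voxel center, 1 to the last (node-centered).
    returns (B, Q, C); gradients flow to both the grid and the coordinates.
    """
    bsz, c, d, h, w = value.data.shape
    dims = np.array([d, h, w], dtype=value.dtype)
    pix = coords.data * (dims - 1.0)  # B,Q,3 voxel coords
    inside = (pix > 0.0) & (pix < dims - 1.0)  # clamped points get no coord grad
    pix = np.clip(pix, 0.0, dims - 1.0)
    lo = np.minimum(pix.astype(int), np.maximum(dims.astype(int) - 2, 0))
    t = pix - lo  # B,Q,3 in [0,1]

    q = coords.data.shape[1]
    p = d * h * w
    vflat = value.data.reshape(bsz, c, p).transpose(0, 2, 1).reshape(bsz * p, c)

    # the 8 corners, vectorized: S = 8, arrays (S, B, Q)
    dz = np.array([0, 0, 0, 0, 1, 1, 1, 1])[:, None, None]
    dy = np.array([0, 0, 1, 1, 0, 0, 1, 1])[:, None, None]
    dx = np.array([0, 1, 0, 1, 0, 1, 0, 1])[:, None, None]
    iz = np.minimum(lo[None, ..., 0] + dz, d - 1)
    iy = np.minimum(lo[None, ..., 1] + dy, h - 1)
    ix = np.minimum(lo[None, ..., 2] + dx, w - 1)
    boff = (np.arange(bsz) * p)[None, :, None]
    flat = (iz * h + iy) * w + ix + boff                      # S,B,Q
    one = np.array(1.0, dtype=value.dtype)
    wz = np.where(dz, t[None, ..., 0], one - t[None, ..., 0])  # S,B,Q
    wy = np.where(dy, t[None, ..., 1], one - t[None, ..., 1])
    wx = np.where(dx, t[None, ..., 2], one - t[None, ..., 2])
    wgt = wz * wy * wx
    v = vflat[flat]                                           # S,B,Q,C
    out = np.einsum("sbq,sbqc->bqc", wgt, v)

    def backward(g):  # g: B,Q,C
        if value.requires_grad:
            # scatter-add via a sparse matrix: much faster than np.add.at
            from scipy import sparse
            data = (g[None] * wgt[..., None]).reshape(-1, c)
            row = flat.ravel()
            nnz = row.size
            scatter = sparse.csr_matrix(
                (np.ones(nnz, dtype=data.dtype), (row, np.arange(nnz))),
                shape=(bsz * p, nnz))
            gv = scatter @ data  # (B*P, C)
            gv = gv.reshape(bsz, p, c).transpose(0, 2, 1)
            value._accumulate(gv.reshape(value.data.shape).astype(value.dtype,
                                                                  copy=False))
        if coords.requires_grad:
            gdotv = np.einsum("bqc,sbqc->sbq", g, v)
            sz = np.where(dz, one, -one)
            sy = np.where(dy, one, -one)
            sx = np.where(dx, one, -one)
            gc = np.stack([
                (gdotv * sz * wy * wx).sum(axis=0),
                (gdotv * wz * sy * wx).sum(axis=0),
                (gdotv * wz * wy * sx).sum(axis=0)], axis=-1)
            coords._accumulate(gc * inside * (dims - 1.0))

    return Tensor._make(out, (value, coords), backward)
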