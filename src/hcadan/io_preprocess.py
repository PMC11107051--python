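"""Volume I/O and the preprocessing pipeline for anisotropic CT.

Grids are stored ``(z, y, x)`` with 0-based voxel indices and node-centered
coordinates; ``spacing`` is ``(sz, sy, sx)`` in mm.  Typical abdominal CT in
this setting has in-plane spacing around 0.5-1.0 mm but slice spacing of
5-8 mm, so preprocessing treats the through-plane axis separately wherever
the distinction matters (patching, augmentation, resampling targets).

Pipeline steps:

* intensity clipping to the [0.5, 99.5] percentile range of the foreground
  voxels followed by a z-score using the clamped foreground statistics;
* voxel-spacing resampling with third-order spline interpolation for images
  and nearest neighbor for masks;
* tumor-centered patch extraction with seeded jitter;
* online augmentation (flips, in-plane 90-degree rotations, small integer
  translations) applied identically to image and mask.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume3D", "SegMask", "PreprocessConfig",
    "read_volume", "write_volume", "write_mask",
    "clip_normalize", "resample", "extract_patch", "augment",
]


@dataclass
class Volume3D:
    """A scalar grid indexed (z, y, x) with per-axis spacing in mm."""

    data: np.ndarray
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.data.ndim}")
        if any(not np.isfinite(s) or s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be finite and positive, got {self.spacing}")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class SegMask:
    """Binary mask on the same lattice as its paired volume."""

    data: np.ndarray
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.data.ndim}")
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be 0/1 (binarize on read)")
        self.data = self.data.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self):
        return self.data.shape

    def volume_fraction(self) -> float:
        return float(self.data.mean())


@dataclass
class PreprocessConfig:
    clip_low_pct: float = 0.5
    clip_high_pct: float = 99.5
    target_spacing: tuple = (5.0, 0.741, 0.741)
    patch_shape: tuple = (28, 256, 256)
    jitter_frac: float = 0.25
    flip_prob: float = 0.5
    rot90_prob: float = 0.25
    translate_prob: float = 0.5
    max_translate: int = 5
    interpolation_order_image: int = 3
    interpolation_order_mask: int = 0

    def __post_init__(self):
        if not (0 <= self.clip_low_pct < self.clip_high_pct <= 100):
            raise ValueError("require 0 <= clip_low_pct < clip_high_pct <= 100")
        if any(p < 8 for p in self.patch_shape):
            raise ValueError("patch_shape components must be >= 8")


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine_for(spacing, origin) -> np.ndarray:
    # grid order is (z,y,x); NIfTI stores (x,y,z)
    sx, sy, sz = spacing[2], spacing[1], spacing[0]
    aff = np.diag([sx, sy, sz, 1.0])
    aff[:3, 3] = (origin[2], origin[1], origin[0])
    return aff


def write_volume(vol: Volume3D, path: str):
    img = nib.Nifti1Image(np.asarray(vol.data.T, dtype=np.float32),
                          _affine_for(vol.spacing, vol.origin))
    nib.save(img, path)


def write_mask(mask: SegMask, path: str):
    img = nib.Nifti1Image(np.asarray(mask.data.T, dtype=np.uint8),
                          _affine_for(mask.spacing, mask.origin))
    nib.save(img, path)


def read_volume(path: str, mask_path: str | None = None):
    """Read a NIfTI image (and optional mask) into (z,y,x) grid order.

    Masks are binarized on read (any value > 0 becomes 1) and must share the
    image lattice.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]  # (sx, sy, sz)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    tr = img.affine[:3, 3]
    origin = (float(tr[2]), float(tr[1]), float(tr[0]))
    vol = Volume3D(np.ascontiguousarray(data.T.astype(np.float32)), spacing, origin)
    if mask_path is None:
        return vol, None
    if not os.path.exists(mask_path):
        raise FileNotFoundError(mask_path)
    mimg = nib.load(mask_path)
    mdata = np.asanyarray(mimg.dataobj)
    if mdata.ndim != 3:
        raise ValueError(f"expected a 3D mask, got ndim={mdata.ndim}")
    mdata = np.ascontiguousarray(mdata.T)
    if mdata.shape != vol.data.shape:
        raise ValueError(f"mask shape {mdata.shape} != image shape {vol.data.shape}")
    return vol, SegMask((mdata > 0).astype(np.uint8), spacing, origin)


# ---------------------------------------------------------------------------
# intensity normalization
# ---------------------------------------------------------------------------

def clip_normalize(vol: Volume3D, fg: SegMask) -> Volume3D:
    """Clip to the foreground [0.5, 99.5] percentile band, then z-score.

    Percentiles, mean and SD are all computed over the foreground voxels
    (the annotated region), following the usual CT fingerprinting scheme;
    a zero-variance foreground yields an all-zero volume.
    """
    if fg.data.shape != vol.data.shape:
        raise ValueError("foreground mask must match the volume shape")
    fg_vals = vol.data[fg.data > 0]
    if fg_vals.size == 0:
        raise ValueError("empty foreground mask")
    lo, hi = np.percentile(fg_vals, [0.5, 99.5])
    clipped = np.clip(vol.data, lo, hi)
    cf = np.clip(fg_vals, lo, hi)
    mu, sd = float(cf.mean()), float(cf.std())
    if sd == 0.0:
        out = np.zeros_like(clipped, dtype=np.float32)
    else:
        out = ((clipped - mu) / sd).astype(np.float32)
    return Volume3D(out, vol.spacing, vol.origin)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample(vol, target_spacing, order: int | None = None):
    """Resample to `target_spacing`; third-order spline for images by default.

    Output shape per axis is round(n_in * s_in / s_target); node-centered
    convention: output node j sits at physical coordinate j * s_target, and is
    interpolated at input voxel coordinate j * s_target / s_in.
    """
    is_mask = isinstance(vol, SegMask)
    if order is None:
        order = 0 if is_mask else 3
    if order not in (0, 1, 3):
        raise ValueError(f"order must be 0, 1 or 3; got {order}")
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    if target_spacing == tuple(vol.spacing):
        cls = SegMask if is_mask else Volume3D
        return cls(vol.data.copy(), vol.spacing, vol.origin)
    in_shape = vol.data.shape
    out_shape = tuple(max(1, int(round(n * s_in / s_t)))
                      for n, s_in, s_t in zip(in_shape, vol.spacing, target_spacing))
    axes = [np.arange(n_out) * s_t / s_in
            for n_out, s_t, s_in in zip(out_shape, target_spacing, vol.spacing)]
    grid = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([g.ravel() for g in grid])
    src = vol.data.astype(np.float64)
    if order == 3:
        # odd-reflection padding extends the volume linearly, so the cubic
        # spline reproduces linear trends up to the original boundary
        pad = 12  # the cubic prefilter's IIR tail decays ~0.27^k
        widths = [(pad, pad) if n > 1 else (0, 0) for n in src.shape]
        src = np.pad(src, widths, mode="reflect", reflect_type="odd")
        coords = coords + np.array([w[0] for w in widths])[:, None]
    data = ndimage.map_coordinates(src, coords, order=order,
                                   mode="nearest").reshape(out_shape)
    if is_mask:
        return SegMask((data > 0.5).astype(np.uint8), target_spacing, vol.origin)
    return Volume3D(data.astype(np.float32), target_spacing, vol.origin)


# ---------------------------------------------------------------------------
# patch extraction
# ---------------------------------------------------------------------------

def extract_patch(vol: Volume3D, mask: SegMask, cfg: PreprocessConfig,
                  seed: int | None = None, jitter: bool = True):
    """Fixed-shape patch centered on the tumor centroid plus seeded jitter.

    The tumor typically occupies a small fraction of the scan, so sampling is
    centered on it; jitter of up to ``jitter_frac`` of the patch extent per
    axis decorrelates successive draws.  Out-of-bounds regions are zero-padded.
    """
    if mask.data.sum() == 0:
        raise ValueError("empty mask: cannot center a patch")
    rng = np.random.default_rng(seed)
    centroid = np.array(ndimage.center_of_mass(mask.data))
    center = np.round(centroid).astype(int)
    patch = np.array(cfg.patch_shape, dtype=int)
    if jitter and cfg.jitter_frac > 0:
        max_j = np.floor(cfg.jitter_frac * patch).astype(int)
        center = center + rng.integers(-max_j, max_j + 1)
    start = center - patch // 2
    stop = start + patch

    shape = np.array(vol.data.shape)
    src_lo = np.clip(start, 0, shape)
    src_hi = np.clip(stop, 0, shape)
    dst_lo = src_lo - start
    dst_hi = dst_lo + (src_hi - src_lo)

    out_img = np.zeros(tuple(patch), dtype=vol.data.dtype)
    out_msk = np.zeros(tuple(patch), dtype=np.uint8)
    src = tuple(slice(a, b) for a, b in zip(src_lo, src_hi))
    dst = tuple(slice(a, b) for a, b in zip(dst_lo, dst_hi))
    out_img[dst] = vol.data[src]
    out_msk[dst] = mask.data[src]
    origin = tuple(o + s * lo for o, s, lo in zip(vol.origin, vol.spacing, start))
    return (Volume3D(out_img, vol.spacing, origin),
            SegMask(out_msk, vol.spacing, origin))


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _shift_zero_fill(a: np.ndarray, shifts) -> np.ndarray:
    out = np.zeros_like(a)
    src, dst = [], []
    for n, s in zip(a.shape, shifts):
        if abs(s) >= n:
            return out
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    out[tuple(dst)] = a[tuple(src)]
    return out


def augment(img: Volume3D, mask: SegMask, cfg: PreprocessConfig, seed: int):
    """Seeded spatial augmentation applied identically to image and mask.

    Per-axis flips (p = ``flip_prob``), in-plane rotations by a multiple of
    90 degrees (p = ``rot90_prob``), and integer in-plane translations of up
    to ``max_translate`` voxels (p = ``translate_prob``).  Deterministic per
    seed; masks stay binary because every transform is a permutation of (a
    subset of) voxels.
    """
    if img.data.shape != mask.data.shape:
        raise ValueError("image/mask shapes differ")
    rng = np.random.default_rng(seed)
    a, m = img.data, mask.data
    for axis in range(3):
        if rng.random() < cfg.flip_prob:
            a = np.flip(a, axis)
            m = np.flip(m, axis)
    if rng.random() < cfg.rot90_prob and a.shape[1] == a.shape[2]:
        k = int(rng.integers(1, 4))
        a = np.rot90(a, k, axes=(1, 2))
        m = np.rot90(m, k, axes=(1, 2))
    if rng.random() < cfg.translate_prob:
        t = cfg.max_translate
        shifts = (0, int(rng.integers(-t, t + 1)), int(rng.integers(-t, t + 1)))
        a = _shift_zero_fill(np.ascontiguousarray(a), shifts)
        m = _shift_zero_fill(np.ascontiguousarray(m), shifts)
    return (Volume3D(np.ascontiguousarray(a), img.spacing, img.origin),
            SegMask(np.ascontiguousarray(m), mask.spacing, mask.origin))
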