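"""Synthetic anisotropic CT-like phantoms with ellipsoidal tumors.

Multi-center abdominal CT is rarely shareable, so every other module in this
package is exercised on phantoms: a textured background, an ellipsoidal
"tumor" with a soft one-voxel partial-volume rim, Gaussian noise, and
controllable inter-domain shifts (intensity offset, contrast scale, noise
ratio, slice spacing) that emulate the heterogeneity between scanners and
sites.  Intensities are on an arbitrary HU-like scale; no CT physics is
modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io_preprocess import SegMask, Volume3D

__all__ = [
    "PhantomSpec", "DomainShiftSpec",
    "generate_phantom", "generate_set", "generate_domain_pair", "shifted_spec",
]


@dataclass
class PhantomSpec:
    """Parameters of one synthetic volume.

    Defaults emulate a desk-scale patch of contrast CT: soft-tissue
    background around 40 (HU-like), texture and noise amplitudes of 10 and
    8, slice spacing 5 mm vs 0.741 mm in-plane, and a deliberately low
    tumor contrast (+30, about 2-3 background SDs) matching the poor
    tumor/background separability that makes gastric-tumor segmentation hard.
    Semi-axes are in voxels, ordered (z, y, x).
    """

    shape: tuple = (16, 64, 64)
    spacing: tuple = (5.0, 0.741, 0.741)
    semi_axes: tuple = (3.0, 10.0, 10.0)
    delta_t: float = 30.0
    mu_bg: float = 40.0
    texture_amp: float = 10.0
    noise_sd: float = 8.0
    rim_voxels: float = 1.0   # soft partial-volume rim width; 0 = hard edge
    domain: str = "A"

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be positive")
        if any(2 * a + 2 > n for a, n in zip(self.semi_axes, self.shape)):
            raise ValueError(
                f"ellipsoid with semi-axes {self.semi_axes} does not fit "
                f"strictly inside grid {self.shape}")


@dataclass
class DomainShiftSpec:
    """Inter-center shift applied to the target domain."""

    intensity_shift: float = 0.0   # additive background offset
    contrast_scale: float = 1.0    # multiplies tumor contrast and texture
    noise_ratio: float = 1.0       # multiplies noise SD
    spacing_pair: tuple = (5.0, 5.0)  # (source, target) slice spacing in mm

    def __post_init__(self):
        if self.contrast_scale <= 0:
            raise ValueError("contrast scale must be > 0")


def _texture_field(shape, amp: float, rng: np.random.Generator) -> np.ndarray:
    """Sum of 3 low-frequency cosine fields (a cheap 'complex background')."""
    if amp == 0:
        return np.zeros(shape)
    zz, yy, xx = [np.arange(n) / n for n in shape]
    grids = np.meshgrid(zz, yy, xx, indexing="ij")
    field = np.zeros(shape)
    for _ in range(3):
        freq = rng.integers(1, 4, size=3)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        wave = np.ones(shape)
        for g, f, p in zip(grids, freq, phase):
            wave = wave * np.cos(2 * np.pi * f * g + p)
        field += wave
    return amp / 3.0 * field


def generate_phantom(spec: PhantomSpec, seed: int):
    """One phantom: returns (Volume3D, SegMask), deterministic per seed.

    The tumor center is drawn uniformly so the ellipsoid stays strictly
    inside the grid, with a random in-plane orientation (through-plane
    rotation would be unrealistic at 5-8 mm slices).  The image adds the
    tumor contrast through a soft ~1-voxel partial-volume rim; the mask is
    the hard ellipsoid (normalized radius <= 1).
    """
    rng = np.random.default_rng(seed)
    shape = np.array(spec.shape)
    axes = np.array(spec.semi_axes, dtype=float)

    margin = axes + 1.0
    lo, hi = margin, shape - 1 - margin
    if np.any(lo > hi):
        raise ValueError("ellipsoid does not fit strictly inside the grid")
    center = rng.uniform(lo, hi)
    theta = rng.uniform(0, 2 * np.pi)

    zz, yy, xx = np.meshgrid(*[np.arange(n, dtype=float) for n in shape],
                             indexing="ij")
    dz = zz - center[0]
    dy = yy - center[1]
    dx = xx - center[2]
    # in-plane rotation of the offset vector into the ellipsoid frame
    ry = np.cos(theta) * dy + np.sin(theta) * dx
    rx = -np.sin(theta) * dy + np.cos(theta) * dx
    rho = np.sqrt((dz / axes[0]) ** 2 + (ry / axes[1]) ** 2 + (rx / axes[2]) ** 2)

    mask = (rho <= 1.0).astype(np.uint8)
    if spec.rim_voxels > 0:
        # soft rim: full contrast inside the mask, tapering to 0 over
        # ~rim_voxels just outside (makes boundary refinement measurable)
        rim = np.clip((1.0 - rho) * float(axes.min()) / spec.rim_voxels + 1.0,
                      0.0, 1.0)
    else:
        rim = (rho <= 1.0).astype(float)

    img = (spec.mu_bg
           + _texture_field(spec.shape, spec.texture_amp, rng)
           + spec.delta_t * rim)
    if spec.noise_sd > 0:
        img = img + spec.noise_sd * rng.standard_normal(spec.shape)
    return (Volume3D(img.astype(np.float32), spec.spacing),
            SegMask(mask, spec.spacing))


def generate_set(spec: PhantomSpec, n: int, seed: int,
                 scale_range: tuple = (0.7, 1.4)):
    """A set of n phantoms with stratified tumor sizes.

    Semi-axes are scaled by stratified-uniform draws over ``scale_range``, so
    tumor volumes across a set span roughly ``(smax/smin)**3`` (= 8x at the
    default range) — the size diversity that motivates multi-scale alignment.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    smin, smax = scale_range
    out = []
    for i in range(n):
        u = rng.uniform()
        s = smin + (smax - smin) * (i + u) / n
        axes = tuple(a * s for a in spec.semi_axes)
        out.append(generate_phantom(replace(spec, semi_axes=axes),
                                    int(child_seeds[i])))
    return out


def shifted_spec(spec: PhantomSpec, shift: DomainShiftSpec) -> PhantomSpec:
    """Apply a domain shift to a phantom spec (target-domain parameters)."""
    s_src, s_tgt = shift.spacing_pair
    z_mm = spec.shape[0] * spec.spacing[0]
    new_shape = (max(1, int(round(z_mm / s_tgt))),) + tuple(spec.shape[1:])
    z_scale = spec.spacing[0] / s_tgt  # preserve physical tumor size
    new_axes = (spec.semi_axes[0] * z_scale,) + tuple(spec.semi_axes[1:])
    return replace(
        spec,
        shape=new_shape,
        spacing=(float(s_tgt),) + tuple(spec.spacing[1:]),
        semi_axes=new_axes,
        mu_bg=spec.mu_bg + shift.intensity_shift,
        delta_t=spec.delta_t * shift.contrast_scale,
        texture_amp=spec.texture_amp * shift.contrast_scale,
        noise_sd=spec.noise_sd * shift.noise_ratio,
        domain="B",
    )


def generate_domain_pair(spec_a: PhantomSpec, spec_b: PhantomSpec,
                         shift: DomainShiftSpec, n: int, seed: int):
    """Labeled source set and shifted target set (n phantoms each).

    Target masks are returned for *evaluation only*; adaptation training must
    never read them (the trainer enforces this through its unlabeled view).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    seed_a, seed_b = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2)]
    src_spec = replace(spec_a, spacing=(float(shift.spacing_pair[0]),)
                       + tuple(spec_a.spacing[1:]), domain="A")
    tgt_spec = shifted_spec(spec_b, shift)
    return (generate_set(src_spec, n, seed_a), generate_set(tgt_spec, n, seed_b))
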