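"""Hierarchical class-aware domain alignment (HCADA).

One independent U-Net domain discriminator per pyramid level: the post-PBA
feature map is upsampled by trilinear interpolation to patch resolution, the
discriminator emits an unbounded per-voxel domain score (positive = looks
like source), and the score map is gated element-wise by the tumor-class
attention map so alignment focuses on voxels with class evidence.

Ablation arms:

* ``hcada`` — all four levels, class-aware gating (the full method);
* ``m1``   — only the last CADA block (level 4, highest resolution);
* ``m2``   — class-agnostic: the attention map is replaced by ones;
* ``off``  — no alignment (plain supervised training of the backbone).
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import ops
from .astr import NetworkConfig

__all__ = ["ALIGN_MODES", "class_attention", "UNetDiscriminator", "HCADA",
           "cada_map", "levels_for_mode", "attention_for_mode"]

ALIGN_MODES = ("hcada", "m1", "m2", "off")


def class_attention(logits):
    """Per-voxel class softmax of the segmentor logits (channel axis 1).

    Returns a map with the same shape whose channels sum to 1 at every voxel.
    """
    if isinstance(logits, nn.Tensor):
        shift = nn.Tensor(logits.data.max(axis=1, keepdims=True))
        e = (logits - shift).exp()
        return e / e.sum(axis=1, keepdims=True)
    x = np.asarray(logits, dtype=float)
    e = np.exp(x - x.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def cada_map(dmap, att):
    """Element-wise product of the domain score map with the tumor-class
    attention (class-aware domain probability map).

    ``att`` may be the full 2-channel attention map (channel 1, the tumor
    class, is used) or an already-extracted per-voxel weight with the same
    shape as ``dmap``.  The attention factor is gradient-blocked.
    """
    datt = att.data if isinstance(att, nn.Tensor) else np.asarray(att)
    dd = dmap.data if isinstance(dmap, nn.Tensor) else np.asarray(dmap)
    if datt.ndim == dd.ndim and dd.ndim >= 2 and datt.shape[1] == 2 \
            and dd.shape[1] == 1 and datt.shape[2:] == dd.shape[2:]:
        att = att[:, 1:2]
        datt = datt[:, 1:2]
    if datt.shape != dd.shape:
        raise ValueError(f"shape mismatch: dmap {dd.shape} vs att {datt.shape}")
    if isinstance(dmap, nn.Tensor):
        weight = att.detach() if isinstance(att, nn.Tensor) else nn.Tensor(datt)
        return dmap * weight
    return dd * datt


def levels_for_mode(mode: str) -> tuple:
    if mode not in ALIGN_MODES:
        raise ValueError(f"unknown align mode {mode!r}")
    if mode == "off":
        return ()
    return (4,) if mode == "m1" else (1, 2, 3, 4)


def attention_for_mode(att, mode: str):
    """m2 replaces the attention map by ones (class-agnostic alignment)."""
    if mode == "m2":
        shape = att.shape if isinstance(att, nn.Tensor) else np.asarray(att).shape
        return nn.Tensor(np.ones(shape, dtype=np.float32)) \
            if isinstance(att, nn.Tensor) else np.ones(shape)
    return att


class UNetDiscriminator(nn.Module):
    """3-level U-Net with leaky-ReLU and a linear 1-channel head.

    The head is linear (no sigmoid) because the least-squares adversarial
    targets are +/-1 and need an unbounded output range.
    """

    def __init__(self, c_in, rng, base=(16, 32, 64), groups=8):
        super().__init__()
        b1, b2, b3 = base
        self.act = nn.LeakyReLU(0.2)
        self.enc1 = nn.Conv3d(c_in, b1, (3, 3, 3), rng)
        self.enc2 = nn.Conv3d(b1, b2, (3, 3, 3), rng)
        self.bott = nn.Conv3d(b2, b3, (3, 3, 3), rng)
        self.up2 = nn.ConvTranspose3d(b3, b2, (2, 2, 2), rng)
        self.dec2 = nn.Conv3d(2 * b2, b2, (3, 3, 3), rng)
        self.up1 = nn.ConvTranspose3d(b2, b1, (2, 2, 2), rng)
        self.dec1 = nn.Conv3d(2 * b1, b1, (3, 3, 3), rng)
        self.head = nn.Conv3d(b1, 1, (1, 1, 1), rng)

    def forward(self, x):
        e1 = self.act(self.enc1(x))
        e2 = self.act(self.enc2(ops.avg_pool_down(e1, (2, 2, 2))))
        b = self.act(self.bott(ops.avg_pool_down(e2, (2, 2, 2))))
        d2 = self.act(self.dec2(nn.cat([self.up2(b), e2], axis=1)))
        d1 = self.act(self.dec1(nn.cat([self.up1(d2), e1], axis=1)))
        return self.head(d1)


class HCADA(nn.Module):
    """Four independent per-level discriminators over upsampled PBA features."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0,
                 disc_base=(16, 32, 64)):
        super().__init__()
        rng = np.random.default_rng(seed)
        c1, c2, c3, c4 = cfg.channels
        self.ch_per_level = {1: c4, 2: c3, 3: c2, 4: c1}
        self.discriminators = nn.ModuleList([
            UNetDiscriminator(self.ch_per_level[l], rng, disc_base)
            for l in (1, 2, 3, 4)])

    def discriminator(self, level: int) -> UNetDiscriminator:
        if level not in (1, 2, 3, 4):
            raise ValueError(f"unknown pyramid level {level}")
        return self.discriminators[level - 1]

    def discriminate(self, level: int, feat, patch_shape):
        """Upsample a level's feature map to patch resolution and score it.

        Returns a (N,1,*patch_shape) unbounded domain score map.
        """
        if not isinstance(feat, nn.Tensor):
            feat = nn.Tensor(np.asarray(feat, dtype=np.float32))
        up = ops.resize_trilinear(feat, tuple(patch_shape))
        return self.discriminator(level)(up)
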