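"""AsTr: anisotropic CNN-transformer segmentation network.

The backbone couples three parts:

* an anisotropic convolutional encoder whose AsBlocks process the x-y plane
  (1x3x3) and the z direction (3x1x1) in parallel branches, so 5-8 mm slice
  spacing does not contaminate in-plane features, followed by
  squeeze-and-excitation residual (SE-Res) stages at the coarser scales;
* a deformable transformer (DeTrans) over the flattened 4-level feature
  pyramid: each query attends to a small set of learned sampling points per
  level (multi-scale deformable self-attention) instead of all positions,
  which keeps long-range context affordable in 3D;
* a mirrored decoder with transpose-conv upsampling, element-wise addition
  of the transformer features, and one pyramid boundary-aware (PBA) block
  per level.  A PBA block subtracts multi-kernel average-pooled fields from
  the feature map, gates the feature with the sigmoid of the difference, and
  projects the concatenated branches back — a soft edge detector at several
  granularities.

``forward`` returns full-resolution 2-class logits plus the four post-PBA
feature maps that the domain-alignment module consumes.

The first two resolution reductions are in-plane only (1x2x2 average
pooling); the last two are isotropic (2x2x2), so input patches must have
in-plane dims divisible by 16 and depth divisible by 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import ops

__all__ = ["NetworkConfig", "FeaturePyramid", "AsBlock", "SEResBlock",
           "PBABlock", "DeTransEncoder", "AsTr", "summary"]


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``base_channels`` are the encoder stage widths from the highest-resolution
    stage to the lowest; ``width_mult`` scales all of them.  DeTrans sizes
    default to the usual deformable-transformer settings (4 layers, 6 heads,
    4 sampling points).  ``pba_kernels`` are per level l=1..4 (lowest to
    highest resolution): 3/5 for the first two blocks, 5/7 for the last two.
    """

    base_channels: tuple = (16, 32, 64, 128)
    width_mult: float = 1.0
    as_blocks: tuple = (2, 3)
    se_blocks: tuple = (3, 2)
    se_reduction: int = 4
    detrans_layers: int = 4
    detrans_heads: int = 6
    detrans_points: int = 4
    detrans_embed: int = 128
    pba_kernels: tuple = ((3, 5), (3, 5), (5, 7), (5, 7))
    num_classes: int = 2
    gn_groups: int = 8
    down_factors: tuple = ((1, 2, 2), (1, 2, 2), (2, 2, 2), (2, 2, 2))
    use_pba: bool = True
    in_channels: int = 1

    @property
    def channels(self) -> tuple:
        return tuple(max(2, int(round(c * self.width_mult)))
                     for c in self.base_channels)

    @classmethod
    def desk(cls, **overrides) -> "NetworkConfig":
        """CPU-sized profile used throughout the test suite."""
        base = dict(width_mult=0.25, detrans_layers=2, detrans_heads=2,
                    detrans_points=2, detrans_embed=32)
        base.update(overrides)
        return cls(**base)

    def validate_input_shape(self, shape):
        total = np.prod(np.array(self.down_factors), axis=0)
        if any(s % f for s, f in zip(shape, total)):
            raise ValueError(
                f"input shape {tuple(shape)} not divisible by cumulative "
                f"downsampling factors {tuple(total)}")


@dataclass
class FeaturePyramid:
    """Levels l=1..4 from lowest to highest spatial resolution."""

    levels: dict = field(default_factory=dict)

    def __getitem__(self, l: int):
        return self.levels[l]

    def __setitem__(self, l: int, v):
        self.levels[l] = v

    def shapes(self) -> dict:
        return {l: t.shape for l, t in self.levels.items()}


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

class AsBlock(nn.Module):
    """Anisotropic convolution block.

    Parallel 1x3x3 (in-plane) and 3x1x1 (through-plane) convolutions, each
    followed by GN+PReLU, concatenated with a 1x1x1 projection of the input,
    then projected back to ``c_out`` channels by a final 1x1x1 convolution.
    Four convolution layers in total; spatial dims preserved.
    """

    def __init__(self, c_in, c_out, rng, groups=8):
        super().__init__()
        self.conv_inplane = nn.Conv3d(c_in, c_out, (1, 3, 3), rng)
        self.conv_through = nn.Conv3d(c_in, c_out, (3, 1, 1), rng)
        self.proj_in = nn.Conv3d(c_in, c_out, (1, 1, 1), rng)
        self.proj_out = nn.Conv3d(3 * c_out, c_out, (1, 1, 1), rng)
        self.norm_inplane = nn.GroupNorm(c_out, groups)
        self.norm_through = nn.GroupNorm(c_out, groups)
        self.act_inplane = nn.PReLU(c_out)
        self.act_through = nn.PReLU(c_out)
        self.norm_out = nn.GroupNorm(c_out, groups)
        self.act_out = nn.PReLU(c_out)

    @property
    def conv_layers(self):
        return (self.conv_inplane, self.conv_through, self.proj_in, self.proj_out)

    def forward(self, x):
        xy = self.act_inplane(self.norm_inplane(self.conv_inplane(x)))
        z = self.act_through(self.norm_through(self.conv_through(x)))
        merged = nn.cat([xy, z, self.proj_in(x)], axis=1)
        return self.act_out(self.norm_out(self.proj_out(merged)))


class SEResBlock(nn.Module):
    """Residual block with squeeze-and-excitation channel gating.

    y = x + gate(branch(x)) * branch(x); no post-activation, so a zeroed
    branch reduces to the identity.
    """

    def __init__(self, channels, rng, reduction=4, groups=8):
        super().__init__()
        self.conv1 = nn.ConvGNPReLU(channels, channels, (3, 3, 3), rng, groups)
        self.conv2 = nn.Conv3d(channels, channels, (3, 3, 3), rng)
        self.norm2 = nn.GroupNorm(channels, groups)
        self.se = nn.SqueezeExcite(channels, reduction, rng)

    def forward(self, x):
        branch = self.norm2(self.conv2(self.conv1(x)))
        return x + self.se(branch)


class PBABlock(nn.Module):
    """Pyramid boundary-aware block.

    For each kernel k: pool the feature with a stride-1 average over a
    k^3 window, gate the feature by sigmoid(F - pooled), concatenate the
    branches over channels and project back to C with a 1x1x1 convolution.
    """

    def __init__(self, channels, kernels, rng):
        super().__init__()
        for k in kernels:
            if k < 3 or k % 2 == 0:
                raise ValueError("PBA kernels must be odd and >= 3")
        self.kernels = tuple(kernels)
        self.proj = nn.Conv3d(len(kernels) * channels, channels, (1, 1, 1), rng)

    def branches(self, x):
        out = []
        for k in self.kernels:
            pooled = ops.box_mean_same(x, (k, k, k))
            out.append((x - pooled).sigmoid() * x)
        return out

    def forward(self, x):
        return self.proj(nn.cat(self.branches(x), axis=1))


# ---------------------------------------------------------------------------
# deformable transformer
# ---------------------------------------------------------------------------

def sinusoidal_position_encoding(shapes: dict, d_model: int,
                                 dtype=np.float32) -> np.ndarray:
    """3D sinusoidal positional encoding for the concatenated token sequence.

    d_model is split across the three axes; each axis gets sin/cos pairs at
    geometrically spaced frequencies of its normalized coordinate.
    """
    per_axis = d_model // 3
    chunks = []
    for l in sorted(shapes):
        d, h, w = shapes[l]
        coords = np.meshgrid(
            *[np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
              for n in (d, h, w)], indexing="ij")
        parts = []
        for axis, c in enumerate(coords):
            n_pairs = max((per_axis if axis < 2 else d_model - 2 * per_axis) // 2, 1)
            freqs = 10000.0 ** (-np.arange(n_pairs) / n_pairs)
            ang = c.ravel()[:, None] * freqs[None, :] * 2 * np.pi
            parts.append(np.sin(ang))
            parts.append(np.cos(ang))
        enc = np.concatenate(parts, axis=1)[:, :d_model]
        if enc.shape[1] < d_model:
            enc = np.pad(enc, ((0, 0), (0, d_model - enc.shape[1])))
        chunks.append(enc)
    return np.concatenate(chunks, axis=0).astype(dtype)


class MSDMSA(nn.Module):
    """Multi-scale deformable self-attention.

    Every query token attends to ``n_points`` learned sampling locations per
    pyramid level and head; attention weights are a softmax over all
    (level, point) pairs.  Sampling offsets start at zero so the initial
    attention looks at the reference point itself.
    """

    def __init__(self, d_model, n_heads, n_points, n_levels, rng):
        super().__init__()
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_model, self.n_heads = d_model, n_heads
        self.n_points, self.n_levels = n_points, n_levels
        self.value_proj = nn.Linear(d_model, d_model, rng)
        self.offset_proj = nn.Linear(d_model, n_heads * n_levels * n_points * 3, rng)
        self.offset_proj.weight.data[:] = 0.0  # start sampling at the reference
        self.weight_proj = nn.Linear(d_model, n_heads * n_levels * n_points, rng)
        self.out_proj = nn.Linear(d_model, d_model, rng)

    def attention_weights(self, x):
        """Softmax over (level, point) pairs per head; (N,T,H,L*K)."""
        n, t, _ = x.shape
        logits = self.weight_proj(x).reshape(
            n, t, self.n_heads, self.n_levels * self.n_points)
        shift = nn.Tensor(logits.data.max(axis=-1, keepdims=True))
        e = (logits - shift).exp()
        return e / e.sum(axis=-1, keepdims=True)

    def forward(self, x, shapes: dict, ref_points: np.ndarray):
        """x: (N,T,d); ref_points: (T,3) normalized [0,1] per-token centers."""
        n, t, d = x.shape
        hh, kk, ll = self.n_heads, self.n_points, self.n_levels
        dh = d // hh
        levels = sorted(shapes)
        sizes = [int(np.prod(shapes[l])) for l in levels]
        offsets = np.cumsum([0] + sizes)

        value = self.value_proj(x)  # N,T,d
        attn = self.attention_weights(x).reshape(n, t, hh, ll, kk)
        raw_off = self.offset_proj(x).reshape(n, t, hh, ll, kk, 3)

        out = None
        for li, l in enumerate(levels):
            dlev = np.array(shapes[l], dtype=value.dtype)
            # value grid for this level, heads folded into the batch
            vl = value[:, offsets[li]:offsets[li + 1], :]
            grid = vl.reshape(n, sizes[li], hh, dh).transpose((0, 2, 3, 1))
            grid = grid.reshape((n * hh, dh) + tuple(shapes[l]))
            # sampling coords: reference + offset scaled by the level size
            ref = nn.Tensor(np.broadcast_to(
                ref_points[None, :, None, None, :], (n, t, hh, kk, 3)).copy())
            coords = ref + raw_off[:, :, :, li, :, :] * (1.0 / dlev)
            coords = coords.transpose((0, 2, 1, 3, 4)).reshape(n * hh, t * kk, 3)
            sampled = ops.sample_trilinear(grid, coords)  # N*H, T*K, dh
            sampled = sampled.reshape(n, hh, t, kk, dh)
            w = attn[:, :, :, li, :].transpose((0, 2, 1, 3))  # N,H,T,K
            contrib = (sampled * w.reshape(n, hh, t, kk, 1)).sum(axis=3)
            out = contrib if out is None else out + contrib
        out = out.transpose((0, 2, 1, 3)).reshape(n, t, d)
        return self.out_proj(out)


class DeTransLayer(nn.Module):
    def __init__(self, d_model, n_heads, n_points, n_levels, ffn_mult, rng):
        super().__init__()
        self.attn = MSDMSA(d_model, n_heads, n_points, n_levels, rng)
        self.ln1 = nn.LayerNorm(d_model)
        self.ffn1 = nn.Linear(d_model, ffn_mult * d_model, rng)
        self.ffn2 = nn.Linear(ffn_mult * d_model, d_model, rng)
        self.ln2 = nn.LayerNorm(d_model)

    def ffn_only(self, x):
        """Residual + norm path with the attention output forced to zero."""
        y = self.ln1(x)
        return self.ln2(y + self.ffn2(self.ffn1(y).relu()))

    def forward(self, x, shapes, ref_points):
        x = self.ln1(x + self.attn(x, shapes, ref_points))
        return self.ln2(x + self.ffn2(self.ffn1(x).relu()))


class DeTransEncoder(nn.Module):
    """Deformable transformer over the flattened 4-level pyramid.

    Input/output are feature pyramids with identical shapes: levels are
    projected to the embedding dim, tagged with 3D sinusoidal positional
    encodings plus a learned level embedding, passed through the DeTrans
    layers, then projected back to each level's channel count and reshaped.
    """

    def __init__(self, cfg: NetworkConfig, rng):
        super().__init__()
        d = cfg.detrans_embed
        ch = cfg.channels  # stage widths, highest->lowest resolution
        self.d_model = d
        # level l=1 (lowest res) has the deepest stage width ch[3]
        self.ch_per_level = {1: ch[3], 2: ch[2], 3: ch[1], 4: ch[0]}
        self.in_proj = {l: nn.Conv3d(c, d, (1, 1, 1), rng)
                        for l, c in self.ch_per_level.items()}
        self.out_proj = {l: nn.Conv3d(d, c, (1, 1, 1), rng)
                         for l, c in self.ch_per_level.items()}
        self.in_projs = nn.ModuleList([self.in_proj[l] for l in (1, 2, 3, 4)])
        self.out_projs = nn.ModuleList([self.out_proj[l] for l in (1, 2, 3, 4)])
        self.level_embed = nn.Parameter(
            0.02 * rng.standard_normal((4, d)).astype(np.float32))
        self.layers = nn.ModuleList([
            DeTransLayer(d, cfg.detrans_heads, cfg.detrans_points, 4, 2, rng)
            for _ in range(cfg.detrans_layers)])
        self._pe_cache = {}

    @staticmethod
    def reference_points(shapes: dict) -> np.ndarray:
        """Normalized (z,y,x) centers of every token, concatenated l=1..4."""
        refs = []
        for l in sorted(shapes):
            axes = [np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
                    for n in shapes[l]]
            grid = np.meshgrid(*axes, indexing="ij")
            refs.append(np.stack([g.ravel() for g in grid], axis=1))
        return np.concatenate(refs, axis=0).astype(np.float32)

    def forward(self, pyr: FeaturePyramid) -> FeaturePyramid:
        shapes = {l: t.shape[2:] for l, t in pyr.levels.items()}
        key = tuple(sorted(shapes.items()))
        if key not in self._pe_cache:
            self._pe_cache[key] = (
                sinusoidal_position_encoding(shapes, self.d_model),
                self.reference_points(shapes))
        pos, refs = self._pe_cache[key]

        toks, sizes = [], []
        for l in sorted(shapes):
            t = self.in_proj[l](pyr[l])  # N,d,D,H,W
            nb, d = t.shape[0], t.shape[1]
            sz = int(np.prod(shapes[l]))
            sizes.append(sz)
            tok = t.reshape(nb, d, sz).transpose((0, 2, 1))
            tok = tok + self.level_embed[l - 1].reshape(1, 1, d)
            toks.append(tok)
        x = nn.cat(toks, axis=1) + nn.Tensor(pos[None])

        for layer in self.layers:
            x = layer(x, shapes, refs)

        out = FeaturePyramid()
        offset = 0
        for l, sz in zip(sorted(shapes), sizes):
            tok = x[:, offset:offset + sz, :]
            offset += sz
            nb = tok.shape[0]
            t = tok.transpose((0, 2, 1)).reshape(
                (nb, self.d_model) + tuple(shapes[l]))
            out[l] = self.out_proj[l](t)
        return out


# ---------------------------------------------------------------------------
# encoder / decoder / full network
# ---------------------------------------------------------------------------

class AsEncoder(nn.Module):
    def __init__(self, cfg: NetworkConfig, rng):
        super().__init__()
        c1, c2, c3, c4 = cfg.channels
        g = cfg.gn_groups
        self.stem = nn.ConvGNPReLU(cfg.in_channels, c1, (3, 3, 3), rng, g)
        self.down_factors = cfg.down_factors
        self.as_stage1 = nn.ModuleList(
            [AsBlock(c1, c1, rng, g) for _ in range(cfg.as_blocks[0])])
        self.as_stage2 = nn.ModuleList(
            [AsBlock(c1 if i == 0 else c2, c2, rng, g)
             for i in range(cfg.as_blocks[1])])
        self.proj3 = nn.ConvGNPReLU(c2, c3, (1, 1, 1), rng, g)
        self.se_stage1 = nn.ModuleList(
            [SEResBlock(c3, rng, cfg.se_reduction, g)
             for _ in range(cfg.se_blocks[0])])
        self.proj4 = nn.ConvGNPReLU(c3, c4, (1, 1, 1), rng, g)
        self.se_stage2 = nn.ModuleList(
            [SEResBlock(c4, rng, cfg.se_reduction, g)
             for _ in range(cfg.se_blocks[1])])

    def forward(self, x) -> FeaturePyramid:
        pyr = FeaturePyramid()
        x = self.stem(x)
        x = ops.avg_pool_down(x, self.down_factors[0])
        for blk in self.as_stage1:
            x = blk(x)
        pyr[4] = x
        x = ops.avg_pool_down(x, self.down_factors[1])
        for blk in self.as_stage2:
            x = blk(x)
        pyr[3] = x
        x = self.proj3(ops.avg_pool_down(x, self.down_factors[2]))
        for blk in self.se_stage1:
            x = blk(x)
        pyr[2] = x
        x = self.proj4(ops.avg_pool_down(x, self.down_factors[3]))
        for blk in self.se_stage2:
            x = blk(x)
        pyr[1] = x
        return pyr


class AsDecoder(nn.Module):
    """Mirrors the encoder: SE-Res stages at the coarse levels, AsBlock
    stages at the fine levels, one PBA block per level, transpose-conv
    upsampling, transformer features added element-wise."""

    def __init__(self, cfg: NetworkConfig, rng):
        super().__init__()
        c1, c2, c3, c4 = cfg.channels
        g = cfg.gn_groups
        self.use_pba = cfg.use_pba
        self.stage1 = nn.ModuleList(
            [SEResBlock(c4, rng, cfg.se_reduction, g)
             for _ in range(cfg.se_blocks[1])])
        self.stage2 = nn.ModuleList(
            [SEResBlock(c3, rng, cfg.se_reduction, g)
             for _ in range(cfg.se_blocks[0])])
        self.stage3 = nn.ModuleList(
            [AsBlock(c2, c2, rng, g) for _ in range(cfg.as_blocks[1])])
        self.stage4 = nn.ModuleList(
            [AsBlock(c1, c1, rng, g) for _ in range(cfg.as_blocks[0])])
        self.pba = nn.ModuleList(
            [PBABlock(c, cfg.pba_kernels[i], rng)
             for i, c in enumerate((c4, c3, c2, c1))])
        f = cfg.down_factors
        self.up1 = nn.ConvTranspose3d(c4, c3, f[3], rng)
        self.up2 = nn.ConvTranspose3d(c3, c2, f[2], rng)
        self.up3 = nn.ConvTranspose3d(c2, c1, f[1], rng)
        self.up4 = nn.ConvTranspose3d(c1, c1, f[0], rng)
        self.final = nn.ConvGNPReLU(c1, c1, (3, 3, 3), rng, g)
        self.head = nn.Conv3d(c1, cfg.num_classes, (1, 1, 1), rng)

    def _level(self, x, stage, pba_block):
        for blk in stage:
            x = blk(x)
        if self.use_pba:
            x = pba_block(x)
        return x

    def forward(self, pyr: FeaturePyramid, skip: FeaturePyramid):
        pba_feats = {}
        x = skip[1] + pyr[1]
        x = self._level(x, self.stage1, self.pba[0])
        pba_feats[1] = x
        x = self.up1(x) + skip[2] + pyr[2]
        x = self._level(x, self.stage2, self.pba[1])
        pba_feats[2] = x
        x = self.up2(x) + skip[3] + pyr[3]
        x = self._level(x, self.stage3, self.pba[2])
        pba_feats[3] = x
        x = self.up3(x) + skip[4] + pyr[4]
        x = self._level(x, self.stage4, self.pba[3])
        pba_feats[4] = x
        x = self.final(self.up4(x))
        return self.head(x), pba_feats


class AsTr(nn.Module):
    """The full segmentation network: encode -> DeTrans -> decode."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.encoder = AsEncoder(cfg, rng)
        self.detrans = DeTransEncoder(cfg, rng)
        self.decoder = AsDecoder(cfg, rng)

    def forward(self, x):
        """x: (N, C, D, H, W) patch -> (logits (N,2,D,H,W), {l: pba feature})."""
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(np.asarray(x, dtype=np.float32))
        self.cfg.validate_input_shape(x.shape[2:])
        skip = self.encoder(x)
        pyr = self.detrans(skip)
        return self.decoder(pyr, skip)


def summary(net: nn.Module) -> str:
    """Per-layer parameter counts plus the total."""
    lines, total = [], 0
    for name, p in net.named_parameters():
        lines.append(f"{name:60s} {str(p.data.shape):24s} {p.data.size:>10d}")
        total += p.data.size
    lines.append(f"{'total':60s} {'':24s} {total:>10d}")
    return "\n".join(lines)
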