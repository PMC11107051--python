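# Methods

## Problem setting

Gastric tumors in abdominal CT are hard to segment automatically: the
in-plane resolution (~0.5–1.0 mm) is an order of magnitude finer than the
slice spacing (5–8 mm), the tumor/background contrast is low, and data
pooled from several centers carries systematic intensity and resolution
differences between scanners. The package implements a two-part answer: a
segmentation backbone built for anisotropic voxels (AsTr) and an
unsupervised adversarial alignment module (HCADA) that adapts the backbone
to an unlabeled target center.

## Preprocessing

Grids are (z, y, x), 0-based, node-centered; spacing is (sz, sy, sx) mm.

* **Intensity**: voxel values are clipped to the [0.5, 99.5] percentile
  band of the foreground (annotated-region) intensities and z-scored by the
  clamped foreground mean/SD — the standard CT fingerprinting scheme. A
  zero-variance foreground maps to an all-zero volume. The operation is
  idempotent up to an affine rescaling (clamping twice with the same band
  equals clamping once).
* **Resampling**: third-order spline for images, nearest neighbor for
  masks; the output shape is round(n·s_in/s_target) per axis. The volume is
  padded by odd reflection (linear-trend extension) before spline
  prefiltering so degree-1 intensity ramps are reproduced to ≤1e-6
  everywhere, including the border; scipy's built-in boundary modes flatten
  ramps near the edge.
* **Patching**: fixed-shape patches centered on the tumor centroid plus a
  seeded uniform jitter of up to 25 % of the patch extent per axis
  (tumors occupy a small fraction of the scan, so uniform patch sampling
  would mostly show background); out-of-bounds regions are zero-padded.
* **Augmentation**: per-axis flips (p=0.5), in-plane 90° rotations
  (p=0.25), integer in-plane translations up to 5 voxels (p=0.5), applied
  identically to image and mask, deterministic per seed.

## Network

The encoder is a Conv–GroupNorm–PReLU stem, two in-plane (1×2×2) average
poolings feeding two AsBlock stages (2 and 3 blocks), then two isotropic
(2×2×2) poolings feeding two SE-Res stages (3 and 2 blocks). An AsBlock
runs 1×3×3 and 3×1×1 convolutions in parallel, concatenates them with a
1×1×1 projection of its input and projects back — in-plane and
through-plane context are extracted independently, which is the right
prior when slices are 5–8 mm apart. Keeping the first two reductions
in-plane only preserves the few z samples as long as possible. Where a
stage changes width before an SE-Res chain, a 1×1×1 Conv–GN–PReLU
projection is inserted (the residual blocks themselves are
width-preserving).

The four pyramid levels are projected to a common embedding, flattened to
one token sequence with 3D sinusoidal positional encodings plus a learned
level embedding, and passed through deformable transformer layers: each
query attends to `n_points` sampled locations per level and head
(trilinear interpolation at reference + learned offset; offsets start at
zero), with attention weights softmaxed over (level, point) pairs.
Positional encoding is sinusoidal rather than learned for determinism.
Full self-attention over ~10⁴–10⁵ voxel tokens would be quadratic;
deformable attention keeps the cost linear in the token count.

The decoder mirrors the encoder, upsamples with kernel-=-stride transpose
convolutions, adds the reshaped transformer features element-wise at every
level, and applies one PBA block per level (average-pooling kernels 3/5 at
the two coarse levels, 5/7 at the two fine levels; stride-1 pooling
averages over in-bounds voxels only, so constants are preserved exactly at
borders). The PBA projection maps the n·C concatenated branch channels
back to C so the decoding path keeps its width. A final Conv–GN–PReLU and
1×1×1 head emit 2-class logits at patch resolution; the four post-PBA
feature maps are returned for alignment. With `use_pba=False` the
pre-PBA features take their place (the ablation arm).

Widths are (16, 32, 64, 128)·width_mult; the desk profile used throughout
the tests is width_mult 0.25, 2 transformer layers, 2 heads, 2 sampling
points, embedding 32. Group-norm uses 8 groups (clamped to the channel
count). Transformer sizes at full scale default to the usual
deformable-transformer settings (4 layers, 6 heads, 4 points, embedding
128).

## Domain alignment

Per level, the post-PBA feature map is trilinearly upsampled to patch
resolution and scored by an independent 3-level U-Net discriminator
(leaky-ReLU, linear 1-channel head — least-squares targets ±1 need an
unbounded range). The score map is gated element-wise by the tumor-class
channel of the class attention map (softmax of the segmentor logits). The
attention factor is gradient-blocked inside the adversarial loss;
otherwise the segmentor could satisfy alignment by collapsing its tumor
probability. Per-level losses combine as Σ_l λ^l·L^l with λ halving per
resolution halving, λ = (⅛, ¼, ½, 1) for levels 1..4 — coarse levels see
large tumors, fine levels small ones, and the weighting favors the
higher-resolution evidence. The reduction over voxels is the mean (so loss
scales are patch-size independent); binary cross-entropy is the standard
negative log form, voxel-averaged, with probabilities clamped to
[1e-7, 1−1e-7].

Training alternates, per iteration: (a) one discriminator step on
L_dis^h with the segmentor frozen; (b) one segmentor step on
L_seg + w_da·L_da^h with the discriminators frozen. w_da defaults to 0.01
so the supervised loss stays dominant (standard for least-squares
adversarial UDA); the discriminators use SGD at lr 1e-4 — a slow
discriminator stabilizes least-squares adversarial training. Ablation
arms: `m1` aligns only level 4 (the last, highest-resolution CADA block),
`m2` replaces the attention by ones (class-agnostic), `off` reduces
exactly to supervised training.

## Optimization

SGD with momentum 0.99; full-scale defaults are lr 1e-3, batch 2, 500
epochs × 250 iterations, patch 28×256×256. The desk profile is lr 5e-3,
batch 1, patch 8×32×32, 200 iterations: at width_mult 0.25 the larger
step is stable and converges within a CPU-scale budget. Non-finite inputs
or losses abort with a diagnostic. Inference is sliding-window with 50 %
overlap and logit averaging; volumes smaller than the patch are zero-
padded and cropped back, so a single window equals direct inference.

## Synthetic phantoms

Each phantom is a textured background (sum of three seeded low-frequency
cosine fields, amplitude 10), an ellipsoidal tumor with random center and
in-plane orientation, Gaussian noise (SD 8), and a soft ~1-voxel
partial-volume rim (`rim_voxels=0` gives a hard two-valued edge). The
default tumor contrast is +30 over a background of mean 40 and SD ≈ 9 —
deliberately low, matching the poor tumor/background separability of
gastric CT; with high contrast the task is trivially solvable and leaves
no headroom for studying adaptation. Tumor sizes in a generated set are
stratified over a 2× linear (≈8× volume) range, so multi-scale alignment
is actually exercised. Domain shifts compose an additive background
offset, a contrast scale, a noise ratio, and a slice-spacing change (the
target grid keeps the physical extent, so 8 mm slices mean fewer, thicker
slices and flatter tumors in voxel units).

What the phantoms do **not** model: organs and anatomic context, beam
hardening or any CT physics, Hounsfield calibration, annotation noise.
Passing the synthetic benchmark shows the machinery (losses, alignment,
protocols) behaves as designed under a controlled shift — not that the
method reaches any particular accuracy on clinical data.

## The reference cross-center experiment

`hcadan.uda_experiment` fixes the benchmark condition: source at 5 mm
slices, target shifted by +1.5 background SDs and resampled to 8 mm
slices. Desk-scale sizes: 6 cases per domain of 12×48×48 voxels, patch
8×32×32, a shared 80-iteration supervised warmup per seed, then 24
iterations per arm — supervised-only (which continues supervised
training, so arms are compute-matched), M1, M2 and full HCA-DAN — over 3
seeds; the report is the mean target-domain DSC per arm. Starting all
adaptation arms from the same warmup keeps the comparison paired and is
common practice in adversarial UDA.

## Numerical choices

* All layer math is float32; losses accept float64 arrays and are then
  computed in float64 (the closed-form tests run at 1e-9).
* Surface metrics use face-connectivity surfaces (a voxel with a
  face-adjacent background voxel; the array border counts as background),
  physical spacing-scaled distances via a k-d tree, percentiles by linear
  interpolation. Both-empty masks: DSC/JI = 100; distance metrics are
  undefined and the case is excluded and flagged.
* Dice loss of two empty grids is defined as 0; DSC = 200·JI/(100+JI)
  holds identically.
* Average pooling inside PBA averages over valid voxels only;
  downsampling pooling requires divisible shapes (inputs must be divisible
  by 4 in z and 16 in-plane).
* Sampling offsets in deformable attention are zero-initialized; clamped
  sampling points receive no coordinate gradient.

## Known limitations

* The desk-scale profile is far below the scale at which the method was
  designed to operate; the synthetic benchmark demonstrates ordering
  (adaptation ≥ source-only), not clinical effect sizes.
* The full-scale profile (28×256×256 patches, 125k iterations) is shipped
  but is not practical on CPU.
* The deformable-attention scatter/gather is the throughput bottleneck of
  the engine; training wall-clock is dominated by it and by im2col
  convolutions.
* Five-fold CV groups by case id; if a patient contributed both ordinary
  and enhanced CT volumes they must share a case id to stay group-disjoint.
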