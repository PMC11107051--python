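"""Training loops, cross-validation protocols and evaluation.

Two training modes:

* ``train_supervised`` minimizes Dice+BCE over augmented tumor-centered
  patches of the labeled set;
* ``train_hcada`` adds unsupervised domain adaptation: per iteration the
  per-level U-Net discriminators take one least-squares step (segmentor
  frozen) and the segmentor then minimizes the segmentation loss plus the
  class-aware adversarial alignment loss on target-domain patches
  (discriminators frozen).  Target masks are never read: the function only
  accepts an unlabeled view of the target cases.

Protocols: in-center five-fold group cross-validation (each case is a
group, so every case lands in exactly one test fold) and leave-one-center-
out, where the held-out center's images (not masks) participate as the
adaptation target.

Evaluation runs sliding-window full-volume inference with 50% overlap and
logit averaging, then reports DSC/JI/ASD/HD95 per case and mean +/- SD.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .astr import AsTr, NetworkConfig
from .hcada import (HCADA, ALIGN_MODES, attention_for_mode, class_attention,
                    levels_for_mode)
from .io_preprocess import PreprocessConfig, SegMask, Volume3D, augment, extract_patch
from .objectives_metrics import (DEFAULT_LAMBDAS, aggregate_metrics, bce_loss,
                                 da_loss_level, dice_loss, dis_loss_level,
                                 evaluate_masks)

__all__ = [
    "TrainConfig", "LabeledCase", "UnlabeledCase", "strip_labels", "Checkpoint",
    "train_supervised", "train_hcada", "evaluate", "sliding_window_predict",
    "SplitPlan", "make_five_fold", "make_loco", "run_protocol",
    "save_checkpoint", "load_checkpoint",
]


# ---------------------------------------------------------------------------
# configuration and data containers
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    network: NetworkConfig = field(default_factory=NetworkConfig)
    lr: float = 1e-3
    momentum: float = 0.99
    batch_size: int = 2
    epochs: int = 500
    iters_per_epoch: int = 250
    iterations: int | None = None      # overrides epochs * iters_per_epoch
    seed: int = 0
    align_mode: str = "hcada"
    lambdas: tuple = DEFAULT_LAMBDAS
    w_da: float = 0.01
    disc_lr: float = 1e-4
    disc_base: tuple = (16, 32, 64)
    patch_shape: tuple = (28, 256, 256)
    jitter_frac: float = 0.25
    augment_online: bool = True
    expected_spacing: tuple | None = None

    def __post_init__(self):
        if self.lr <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("lr, batch size and epochs must be positive")
        if self.align_mode not in ALIGN_MODES:
            raise ValueError(f"align_mode must be one of {ALIGN_MODES}")

    @property
    def total_iterations(self) -> int:
        if self.iterations is not None:
            return self.iterations
        return self.epochs * self.iters_per_epoch

    @property
    def preprocess(self) -> PreprocessConfig:
        return PreprocessConfig(patch_shape=self.patch_shape,
                                jitter_frac=self.jitter_frac)

    @classmethod
    def desk(cls, **overrides) -> "TrainConfig":
        """CPU-sized profile: small widths, small patches, short schedules."""
        base = dict(network=NetworkConfig.desk(), patch_shape=(8, 32, 32),
                    iterations=200, disc_base=(8, 16, 32), lr=5e-3,
                    batch_size=1)
        base.update(overrides)
        return cls(**base)


@dataclass
class LabeledCase:
    image: Volume3D
    mask: SegMask
    center: str = "C0"
    case_id: str = ""


@dataclass
class UnlabeledCase:
    """Target-domain view: carries no mask at all, by construction."""

    image: Volume3D
    center: str = "C0"
    case_id: str = ""


def strip_labels(cases) -> list:
    """Unlabeled view of a labeled set (the only door into adaptation)."""
    return [UnlabeledCase(c.image, c.center, c.case_id) for c in cases]


@dataclass
class Checkpoint:
    state: dict
    config: TrainConfig
    seed: int
    losses: list = field(default_factory=list)
    disc_state: dict | None = None


def save_checkpoint(ckpt: Checkpoint, path: str):
    if not path.endswith(".npz"):
        path += ".npz"  # np.savez appends it anyway; keep load symmetric
    np.savez(path,
             state=np.array([ckpt.state], dtype=object),
             disc_state=np.array([ckpt.disc_state], dtype=object),
             config=np.array([asdict(ckpt.config)], dtype=object),
             seed=ckpt.seed,
             losses=np.array([ckpt.losses], dtype=object))


def load_checkpoint(path: str) -> Checkpoint:
    if not path.endswith(".npz") and not os.path.exists(path):
        path += ".npz"
    with np.load(path, allow_pickle=True) as f:
        cfg_dict = f["config"][0]
        cfg_dict["network"] = NetworkConfig(**cfg_dict["network"])
        cfg = TrainConfig(**cfg_dict)
        return Checkpoint(state=f["state"][0], config=cfg, seed=int(f["seed"]),
                          losses=list(f["losses"][0]),
                          disc_state=f["disc_state"][0])


# ---------------------------------------------------------------------------
# batch sampling
# ---------------------------------------------------------------------------

def _sample_patch(case, cfg: TrainConfig, rng: np.random.Generator):
    pc = cfg.preprocess
    img, msk = extract_patch(case.image, case.mask, pc,
                             seed=int(rng.integers(2 ** 31)))
    if cfg.augment_online:
        img, msk = augment(img, msk, pc, seed=int(rng.integers(2 ** 31)))
    return img.data, msk.data


def sample_labeled_batch(cases, cfg: TrainConfig, rng: np.random.Generator):
    imgs, msks = [], []
    for _ in range(cfg.batch_size):
        case = cases[int(rng.integers(len(cases)))]
        a, m = _sample_patch(case, cfg, rng)
        imgs.append(a)
        msks.append(m)
    return (np.stack(imgs)[:, None].astype(np.float32),
            np.stack(msks).astype(np.float32))


def sample_unlabeled_batch(cases, cfg: TrainConfig, rng: np.random.Generator):
    """Image-only batches for the target domain.

    Without a mask there is no tumor centroid, so target patches are drawn
    uniformly at random from the volume (zero-padded at the borders).
    """
    pc = cfg.preprocess
    patch = np.array(cfg.patch_shape)
    imgs = []
    for _ in range(cfg.batch_size):
        case = cases[int(rng.integers(len(cases)))]
        if not isinstance(case, UnlabeledCase):
            raise TypeError(
                "target cases must be UnlabeledCase (use strip_labels); "
                "adaptation must not see target masks")
        shape = np.array(case.image.data.shape)
        center = rng.integers(patch // 4, np.maximum(shape - patch // 4,
                                                     patch // 4 + 1))
        fake_mask = np.zeros(case.image.data.shape, dtype=np.uint8)
        fake_mask[tuple(np.minimum(center, shape - 1))] = 1
        img, _ = extract_patch(case.image,
                               SegMask(fake_mask, case.image.spacing),
                               pc, seed=int(rng.integers(2 ** 31)),
                               jitter=False)
        if cfg.augment_online:
            img, _ = augment(img, SegMask(np.zeros(img.data.shape, np.uint8),
                                          img.spacing),
                             pc, seed=int(rng.integers(2 ** 31)))
        imgs.append(img.data)
    return np.stack(imgs)[:, None].astype(np.float32)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _seg_loss_tensor(logits, masks: np.ndarray):
    p = class_attention(logits)[:, 1]
    g = nn.Tensor(masks)
    return dice_loss(p, g) + bce_loss(p, g)


def _check_finite(value: float, it: int, name: str):
    if not np.isfinite(value):
        raise RuntimeError(f"non-finite {name} ({value}) at iteration {it}; "
                           "lower the learning rate or inspect the data")


def _check_batch(imgs: np.ndarray, it: int):
    if not np.isfinite(imgs).all():
        raise RuntimeError(f"non-finite voxels in the input batch at "
                           f"iteration {it}; inspect the data")


def train_supervised(cfg: TrainConfig, data, net: AsTr | None = None,
                     iterations: int | None = None) -> Checkpoint:
    """Minimize Dice+BCE over sampled augmented patches of the labeled set."""
    if len(data) < 1:
        raise ValueError("need at least one labeled case")
    rng = np.random.default_rng(cfg.seed)
    if net is None:
        net = AsTr(cfg.network, seed=int(rng.integers(2 ** 31)))
    net.train()
    opt = nn.SGD(net.parameters(), cfg.lr, cfg.momentum)
    n_iter = cfg.total_iterations if iterations is None else iterations
    losses = []
    for it in range(n_iter):
        imgs, msks = sample_labeled_batch(data, cfg, rng)
        _check_batch(imgs, it)
        logits, _ = net(imgs)
        loss = _seg_loss_tensor(logits, msks)
        _check_finite(loss.item(), it, "L_seg")
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append({"iter": it, "L_seg": float(loss.item())})
    return Checkpoint(state=net.state_dict(), config=cfg, seed=cfg.seed,
                      losses=losses)


def hierarchical_dis_loss(hcada_mod: HCADA, pba_s, pba_t, patch_shape,
                          mode: str, lambdas=DEFAULT_LAMBDAS):
    """L_dis^h over the levels active in `mode` (features held constant)."""
    terms = []
    for l in levels_for_mode(mode):
        d_s = hcada_mod.discriminate(l, pba_s[l], patch_shape)
        d_t = hcada_mod.discriminate(l, pba_t[l], patch_shape)
        terms.append(lambdas[l - 1] * dis_loss_level(d_s, d_t))
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total


def train_hcada(cfg: TrainConfig, source, target, net: AsTr | None = None,
                iterations: int | None = None,
                warmstart: Checkpoint | None = None) -> Checkpoint:
    """Adversarial domain-adaptive training.

    Per iteration: (a) the discriminators take one least-squares step with
    the segmentor frozen; (b) the segmentor minimizes
    L_seg + w_da * L_da^h with the discriminators frozen.  ``align_mode``
    gates the levels (hcada = all 4, m1 = level 4 only, m2 = class-agnostic
    attention); ``off`` reduces exactly to supervised training on the source.
    """
    if cfg.align_mode == "off":
        return train_supervised(cfg, source, net=net, iterations=iterations)
    for c in target:
        if not isinstance(c, UnlabeledCase):
            raise TypeError("target cases must be UnlabeledCase "
                            "(use strip_labels); adaptation must not see "
                            "target masks")
    rng = np.random.default_rng(cfg.seed)
    if net is None:
        net = AsTr(cfg.network, seed=int(rng.integers(2 ** 31)))
        if warmstart is not None:
            net.load_state_dict(dict(warmstart.state))
    net.train()
    disc = HCADA(cfg.network, seed=int(rng.integers(2 ** 31)),
                 disc_base=cfg.disc_base)
    seg_opt = nn.SGD(net.parameters(), cfg.lr, cfg.momentum)
    disc_opt = nn.SGD(disc.parameters(), cfg.disc_lr, cfg.momentum)
    n_iter = cfg.total_iterations if iterations is None else iterations
    patch_shape = cfg.patch_shape
    losses = []

    for it in range(n_iter):
        src_imgs, src_msks = sample_labeled_batch(source, cfg, rng)
        tgt_imgs = sample_unlabeled_batch(target, cfg, rng)
        _check_batch(src_imgs, it)
        _check_batch(tgt_imgs, it)

        # (a) discriminator step: segmentor frozen
        with nn.no_grad():
            _, pba_s = net(src_imgs)
            _, pba_t = net(tgt_imgs)
        pba_s = {l: nn.Tensor(f.data) for l, f in pba_s.items()}
        pba_t = {l: nn.Tensor(f.data) for l, f in pba_t.items()}
        l_dis = hierarchical_dis_loss(disc, pba_s, pba_t, patch_shape,
                                      cfg.align_mode, cfg.lambdas)
        _check_finite(l_dis.item(), it, "L_dis^h")
        disc_opt.zero_grad()
        l_dis.backward()
        disc_opt.step()

        # (b) segmentor step: discriminators frozen
        logits_s, _ = net(src_imgs)
        l_seg = _seg_loss_tensor(logits_s, src_msks)
        logits_t, pba_t = net(tgt_imgs)
        att_t = class_attention(logits_t).detach()
        da_terms = []
        for l in levels_for_mode(cfg.align_mode):
            d_t = disc.discriminate(l, pba_t[l], patch_shape)
            att_w = attention_for_mode(att_t[:, 1:2], cfg.align_mode)
            da_terms.append(cfg.lambdas[l - 1] * da_loss_level(d_t, att_w))
        l_da = da_terms[0]
        for t in da_terms[1:]:
            l_da = l_da + t
        total = l_seg + cfg.w_da * l_da
        _check_finite(total.item(), it, "L_seg + w_da*L_da^h")
        seg_opt.zero_grad()
        disc.zero_grad()  # grads flow through D's activations; discard them
        total.backward()
        seg_opt.step()
        losses.append({"iter": it, "L_seg": float(l_seg.item()),
                       "L_dis_h": float(l_dis.item()),
                       "L_da_h": float(l_da.item())})

    return Checkpoint(state=net.state_dict(), config=cfg, seed=cfg.seed,
                      losses=losses, disc_state=disc.state_dict())


# ---------------------------------------------------------------------------
# inference and evaluation
# ---------------------------------------------------------------------------

def _window_starts(n: int, w: int) -> list:
    if n <= w:
        return [0]
    stride = max(w // 2, 1)
    starts = list(range(0, n - w, stride))
    starts.append(n - w)
    return sorted(set(starts))


def sliding_window_predict(net, image: np.ndarray, patch_shape) -> np.ndarray:
    """Patch-wise full-volume logits with 50% overlap and averaging.

    Volumes smaller than the patch are zero-padded (and cropped back), so a
    single window reproduces direct inference exactly.
    """
    shape = np.array(image.shape)
    patch = np.array(patch_shape)
    pad = np.maximum(patch - shape, 0)
    padded = np.pad(image, [(0, int(p)) for p in pad])
    pshape = np.array(padded.shape)

    logits_sum = None
    counts = np.zeros(padded.shape, dtype=np.float32)
    with nn.no_grad():
        for z0 in _window_starts(pshape[0], patch[0]):
            for y0 in _window_starts(pshape[1], patch[1]):
                for x0 in _window_starts(pshape[2], patch[2]):
                    sl = (slice(z0, z0 + patch[0]), slice(y0, y0 + patch[1]),
                          slice(x0, x0 + patch[2]))
                    win = padded[sl][None, None].astype(np.float32)
                    logits, _ = net(win)
                    arr = logits.data[0]
                    if logits_sum is None:
                        logits_sum = np.zeros((arr.shape[0],) + padded.shape,
                                              dtype=np.float32)
                    logits_sum[(slice(None),) + sl] += arr
                    counts[sl] += 1.0
    logits_avg = logits_sum / counts[None]
    crop = (slice(None),) + tuple(slice(0, s) for s in shape)
    return logits_avg[crop]


def evaluate(ckpt: Checkpoint, cases, net: AsTr | None = None) -> tuple:
    """Sliding-window inference + metrics on labeled cases.

    Returns (aggregate dict, per-case list).  If the checkpoint pins an
    expected voxel spacing, mismatching cases raise.
    """
    cfg = ckpt.config
    if net is None:
        net = AsTr(cfg.network, seed=0)
        state = ckpt.state if isinstance(ckpt.state, dict) else dict(ckpt.state)
        net.load_state_dict(state)
    net.eval()
    per_case = []
    for case in cases:
        if cfg.expected_spacing is not None and \
                not np.allclose(case.image.spacing, cfg.expected_spacing):
            raise ValueError(
                f"case spacing {case.image.spacing} differs from the "
                f"checkpoint's preprocessing spacing {cfg.expected_spacing}")
        logits = sliding_window_predict(net, case.image.data, cfg.patch_shape)
        pred = (np.argmax(logits, axis=0) == 1).astype(np.uint8)
        rec = evaluate_masks(pred, case.mask.data, case.image.spacing)
        rec["case_id"] = case.case_id
        per_case.append(rec)
    return aggregate_metrics(per_case), per_case


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    protocol: str                      # "in_center_5fold" | "cross_center_loco"
    centers: dict                      # case_id -> center label
    folds: dict = field(default_factory=dict)  # case_id -> fold (5-fold only)


def make_five_fold(case_ids, seed: int = 0, n_folds: int = 5,
                   centers: dict | None = None) -> SplitPlan:
    """Group-disjoint assignment: every case in exactly one test fold."""
    rng = np.random.default_rng(seed)
    ids = list(case_ids)
    order = rng.permutation(len(ids))
    folds = {ids[j]: int(i % n_folds) for i, j in enumerate(order)}
    return SplitPlan("in_center_5fold",
                     centers or {c: "C0" for c in ids}, folds)


def make_loco(centers: dict) -> SplitPlan:
    """Leave-one-center-out: each center is the target exactly once."""
    if len(set(centers.values())) < 2:
        raise ValueError("leave-one-center-out needs at least 2 centers")
    return SplitPlan("cross_center_loco", dict(centers))


def run_protocol(plan: SplitPlan, cfg: TrainConfig, cases,
                 iterations: int | None = None) -> dict:
    """Execute a split plan: train per split, evaluate held-out cases.

    Five-fold trains supervised within one center's pool; leave-one-center-
    out trains HCA-DAN with the held-out center's images as the unlabeled
    target and evaluates on that center.
    """
    by_id = {c.case_id: c for c in cases}
    if set(by_id) != set(plan.centers):
        raise ValueError("plan and case list disagree on case ids")
    results = {}
    if plan.protocol == "in_center_5fold":
        for fold in sorted(set(plan.folds.values())):
            test = [by_id[i] for i, f in plan.folds.items() if f == fold]
            train = [by_id[i] for i, f in plan.folds.items() if f != fold]
            ckpt = train_supervised(cfg, train, iterations=iterations)
            results[f"fold{fold}"] = evaluate(ckpt, test)
    elif plan.protocol == "cross_center_loco":
        for center in sorted(set(plan.centers.values())):
            test = [c for c in cases if c.center == center]
            source = [c for c in cases if c.center != center]
            if not test or not source:
                raise ValueError(f"center {center} has no cases on one side")
            ckpt = train_hcada(cfg, source, strip_labels(test),
                               iterations=iterations)
            results[center] = evaluate(ckpt, test)
    else:
        raise ValueError(f"unknown protocol {plan.protocol}")
    return results
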