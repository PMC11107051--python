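"""Training objectives and evaluation metrics.

Losses
------
The segmentation loss is Dice + binary cross-entropy.  Domain alignment uses
the least-squares adversarial objective: discriminators are trained to emit
+1 on source-domain features and -1 on target-domain features; the segmentor
is trained to push target features toward the source label, weighted
per voxel by the tumor-class attention so alignment pressure concentrates on
class-evidence regions.  Per-level losses are combined hierarchically with
weights that halve at each resolution halving (lowest resolution gets the
smallest weight).

All reductions over probability/feature maps are voxel means, so loss values
are comparable across patch sizes.

Every loss accepts either numpy arrays or autograd Tensors and returns the
matching type, so the same code path is unit-testable against closed forms
and differentiable in training.

Metrics
-------
Dice similarity coefficient (DSC) and Jaccard index (JI) in percent; average
surface distance (ASD) and 95th-percentile Hausdorff distance (HD95) in mm,
computed between face-connectivity surface voxels with spacing-scaled
Euclidean distances.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .nn.autograd import Tensor

__all__ = [
    "DEFAULT_LAMBDAS", "UndefinedMetricError",
    "dice_loss", "bce_loss", "seg_loss",
    "dis_loss_level", "da_loss_level", "hierarchical_loss",
    "dsc", "jaccard", "asd", "hd95", "evaluate_masks", "aggregate_metrics",
]

#: per-level weights for l = 1..4 (lowest -> highest resolution)
DEFAULT_LAMBDAS = (0.125, 0.25, 0.5, 1.0)

_BCE_EPS = 1e-7


class UndefinedMetricError(ValueError):
    """Raised when a surface-distance metric is undefined (an empty mask)."""


def _is_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def dice_loss(p, g):
    """Soft Dice loss: 1 - 2*sum(p*g) / (sum(p^2) + sum(g^2)).

    Defined as 0 when both inputs are identically zero.
    """
    tensor_mode = _is_tensor(p, g)
    pd = p.data if isinstance(p, Tensor) else np.asarray(p, dtype=float)
    gd = g.data if isinstance(g, Tensor) else np.asarray(g, dtype=float)
    denom = float((pd * pd).sum() + (gd * gd).sum())
    if denom == 0.0:
        return Tensor(np.array(0.0)) if tensor_mode else 0.0
    if tensor_mode:
        p, g = _wrap(p), _wrap(g)
        return 1.0 - 2.0 * (p * g).sum() / ((p * p).sum() + (g * g).sum())
    return float(1.0 - 2.0 * (pd * gd).sum() / denom)


def bce_loss(p, g):
    """Voxel-averaged binary cross-entropy with probabilities clamped to
    [eps, 1-eps], eps = 1e-7."""
    if _is_tensor(p, g):
        p, g = _wrap(p), _wrap(g)
        pc = p.clip(_BCE_EPS, 1.0 - _BCE_EPS)
        return -(g * pc.log() + (1.0 - g) * (1.0 - pc).log()).mean()
    pd = np.clip(np.asarray(p, dtype=float), _BCE_EPS, 1.0 - _BCE_EPS)
    gd = np.asarray(g, dtype=float)
    return float(-(gd * np.log(pd) + (1.0 - gd) * np.log(1.0 - pd)).mean())


def seg_loss(p, g):
    """Segmentation loss: Dice + BCE."""
    return dice_loss(p, g) + bce_loss(p, g)


def dis_loss_level(d_src, d_tgt):
    """Least-squares discriminator loss at one level.

    mean((d_src - 1)^2) + mean((d_tgt + 1)^2): the discriminator labels
    source features +1 and target features -1.
    """
    if _is_tensor(d_src, d_tgt):
        d_src, d_tgt = _wrap(d_src), _wrap(d_tgt)
        return ((d_src - 1.0) ** 2).mean() + ((d_tgt + 1.0) ** 2).mean()
    a = np.asarray(d_src, dtype=float)
    b = np.asarray(d_tgt, dtype=float)
    return float(((a - 1.0) ** 2).mean() + ((b + 1.0) ** 2).mean())


def da_loss_level(d_tgt, att):
    """Class-weighted adversarial loss at one level.

    mean(att * (d_tgt - 1)^2): drives target-domain features toward the
    discriminator's source label (+1), with per-voxel weight given by the
    tumor-class attention.  The attention map is treated as a constant here
    (callers pass it detached), so the segmentor cannot satisfy the loss by
    collapsing its tumor probability.
    """
    if _is_tensor(d_tgt, att):
        d_tgt = _wrap(d_tgt)
        att = att.detach() if isinstance(att, Tensor) else Tensor(np.asarray(att, dtype=float))
        return (att * (d_tgt - 1.0) ** 2).mean()
    d = np.asarray(d_tgt, dtype=float)
    a = np.asarray(att, dtype=float)
    return float((a * (d - 1.0) ** 2).mean())


def hierarchical_loss(levels, lambdas=DEFAULT_LAMBDAS):
    """Weighted sum over levels l = 1..4: sum_l lambda_l * loss_l."""
    if len(levels) != len(lambdas):
        raise ValueError("need one weight per level")
    total = None
    for lam, term in zip(lambdas, levels):
        contrib = lam * term if isinstance(term, Tensor) else float(lam) * term
        total = contrib if total is None else total + contrib
    return total


# ---------------------------------------------------------------------------
# overlap metrics
# ---------------------------------------------------------------------------

def _as_bool(m) -> np.ndarray:
    d = m.data if hasattr(m, "data") and not isinstance(m, np.ndarray) else m
    return np.asarray(d) > 0


def dsc(pred, gt) -> float:
    """Dice similarity coefficient in percent; 100 when both masks are empty."""
    p, g = _as_bool(pred), _as_bool(gt)
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 100.0
    return float(200.0 * np.logical_and(p, g).sum() / denom)


def jaccard(pred, gt) -> float:
    """Jaccard index in percent; 100 when both masks are empty."""
    p, g = _as_bool(pred), _as_bool(gt)
    inter = int(np.logical_and(p, g).sum())
    union = int(np.logical_or(p, g).sum())
    if union == 0:
        return 100.0
    return float(100.0 * inter / union)


# ---------------------------------------------------------------------------
# surface-distance metrics
# ---------------------------------------------------------------------------

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


def _surface_points(mask: np.ndarray, spacing) -> np.ndarray:
    """Physical coordinates of voxels with a face-adjacent background voxel
    (voxels on the array border count as surface)."""
    interior = ndimage.binary_erosion(mask, structure=_FACE_STRUCT, border_value=0)
    surf = mask & ~interior
    idx = np.argwhere(surf)
    return idx * np.asarray(spacing, dtype=float)


def _directed_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    tree = cKDTree(b)
    d, _ = tree.query(a, k=1)
    return d


def asd(pred, gt, spacing) -> float:
    """Average surface distance in mm: the mean of the two directed mean
    nearest-surface distances."""
    p, g = _as_bool(pred), _as_bool(gt)
    if p.sum() == 0 or g.sum() == 0:
        raise UndefinedMetricError("surface distance undefined for empty mask")
    sp = _surface_points(p, spacing)
    sg = _surface_points(g, spacing)
    return float(0.5 * (_directed_distances(sp, sg).mean()
                        + _directed_distances(sg, sp).mean()))


def hd95(pred, gt, spacing) -> float:
    """95th-percentile Hausdorff distance in mm: the max of the two directed
    95th percentiles of nearest-surface distances (linear interpolation)."""
    p, g = _as_bool(pred), _as_bool(gt)
    if p.sum() == 0 or g.sum() == 0:
        raise UndefinedMetricError("surface distance undefined for empty mask")
    sp = _surface_points(p, spacing)
    sg = _surface_points(g, spacing)
    return float(max(np.percentile(_directed_distances(sp, sg), 95),
                     np.percentile(_directed_distances(sg, sp), 95)))


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def evaluate_masks(pred, gt, spacing) -> dict:
    """All four metrics for one case; distance metrics are NaN (and flagged)
    when either mask is empty."""
    out = {"DSC": dsc(pred, gt), "JI": jaccard(pred, gt)}
    try:
        out["ASD"] = asd(pred, gt, spacing)
        out["HD95"] = hd95(pred, gt, spacing)
        out["distance_defined"] = True
    except UndefinedMetricError:
        out["ASD"] = float("nan")
        out["HD95"] = float("nan")
        out["distance_defined"] = False
    return out


def aggregate_metrics(per_case: list) -> dict:
    """mean +/- SD over cases (distance metrics over defined cases only)."""
    keys = ("DSC", "JI", "ASD", "HD95")
    agg = {}
    for k in keys:
        vals = np.array([c[k] for c in per_case], dtype=float)
        vals = vals[np.isfinite(vals)]
        agg[k] = (float(vals.mean()), float(vals.std())) if vals.size else (float("nan"),) * 2
    agg["n_cases"] = len(per_case)
    agg["n_distance_excluded"] = sum(1 for c in per_case if not c["distance_defined"])
    return agg
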