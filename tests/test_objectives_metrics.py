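"""Losses against closed forms and metrics against brute-force oracles."""

import numpy as np
import pytest

from hcadan import nn
from hcadan.objectives_metrics import (DEFAULT_LAMBDAS, UndefinedMetricError,
                                       asd, bce_loss, da_loss_level, dice_loss,
                                       dis_loss_level, dsc, hd95,
                                       hierarchical_loss, jaccard, seg_loss)

rng = np.random.default_rng(2024)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def surface_voxels_oracle(mask):
    """Voxels with at least one face-adjacent background voxel (outside the
    array counts as background)."""
    m = np.pad(mask.astype(bool), 1)
    out = []
    for idx in np.argwhere(m):
        z, y, x = idx
        if not m[z, y, x]:
            continue
        for dz, dy, dx in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)]:
            if not m[z + dz, y + dy, x + dx]:
                out.append((z - 1, y - 1, x - 1))
                break
    return np.array(out, dtype=float)


def surface_distance_oracle(pred, gt, spacing):
    """All-pairs directed surface distances (physical mm)."""
    sp = surface_voxels_oracle(pred) * spacing
    sg = surface_voxels_oracle(gt) * spacing
    d = np.sqrt(((sp[:, None, :] - sg[None, :, :]) ** 2).sum(-1))
    return d.min(axis=1), d.min(axis=0)


def random_mask(shape, p, seed):
    r = np.random.default_rng(seed)
    m = (r.random(shape) < p).astype(np.uint8)
    if m.sum() == 0:
        m[tuple(r.integers(0, s) for s in shape)] = 1
    return m


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

class TestDiceLoss:
    def test_perfect_overlap_is_zero(self):
        g = random_mask((4, 5, 5), 0.3, 0).astype(float)
        assert dice_loss(g, g) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_is_one(self):
        p = np.array([1.0, 1, 0, 0])
        g = np.array([0.0, 0, 1, 1])
        assert dice_loss(p, g) == pytest.approx(1.0)

    def test_half_overlap_closed_form(self):
        p = np.array([1.0, 1, 0, 0])
        g = np.array([1.0, 0, 1, 0])
        assert dice_loss(p, g) == pytest.approx(0.5)

    def test_both_empty_defined_as_zero(self):
        z = np.zeros(8)
        assert dice_loss(z, z) == 0.0

    def test_consistent_with_dsc_on_binary(self):
        for seed in range(5):
            p = random_mask((6, 6, 6), 0.2, seed)
            g = random_mask((6, 6, 6), 0.2, seed + 50)
            assert dice_loss(p.astype(float), g.astype(float)) == \
                pytest.approx(1.0 - dsc(p, g) / 100.0, abs=1e-12)


class TestBceLoss:
    def test_perfect_prediction_near_zero(self):
        g = np.array([0.0, 1, 1, 0])
        assert bce_loss(g, g) <= 2 * 1e-7 * abs(np.log(1e-7))

    def test_maximum_entropy_is_ln2(self):
        g = random_mask((3, 4, 4), 0.4, 1).astype(float)
        p = np.full_like(g, 0.5)
        assert bce_loss(p, g) == pytest.approx(np.log(2), rel=1e-12)

    def test_matches_term_by_term_oracle(self):
        r = np.random.default_rng(9)
        p = r.uniform(0.01, 0.99, size=8)
        g = (r.random(8) < 0.5).astype(float)
        expect = -np.mean(g * np.log(p) + (1 - g) * np.log(1 - p))
        assert bce_loss(p, g) == pytest.approx(expect, abs=1e-9)

    def test_tensor_path_matches_numpy_path(self):
        r = np.random.default_rng(5)
        p = r.uniform(0, 1, size=(2, 3, 3))
        g = (r.random((2, 3, 3)) < 0.3).astype(float)
        t = bce_loss(nn.Tensor(p, requires_grad=True), nn.Tensor(g))
        assert t.item() == pytest.approx(bce_loss(p, g), abs=1e-12)


class TestSegLoss:
    def test_sum_of_components(self):
        r = np.random.default_rng(3)
        p = r.uniform(0.01, 0.99, size=27)
        g = (r.random(27) < 0.4).astype(float)
        assert seg_loss(p, g) == pytest.approx(dice_loss(p, g) + bce_loss(p, g))

    def test_closed_form_on_half_overlap_example(self):
        p = np.array([1.0, 1, 0, 0])
        g = np.array([1.0, 0, 1, 0])
        eps = 1e-7
        bce = -np.mean(g * np.log(np.clip(p, eps, 1 - eps))
                       + (1 - g) * np.log(np.clip(1 - p, eps, 1 - eps)))
        assert seg_loss(p, g) == pytest.approx(0.5 + bce, rel=1e-9)


class TestAdversarialLosses:
    def test_ideal_discriminator_zero(self):
        assert dis_loss_level(np.ones((2, 2)), -np.ones((2, 2))) == 0.0

    def test_uninformative_discriminator_two(self):
        assert dis_loss_level(np.zeros((2, 2)), np.zeros((2, 2))) == 2.0

    def test_matches_per_voxel_oracle(self):
        r = np.random.default_rng(8)
        ds, dt = r.normal(size=(2, 2)), r.normal(size=(2, 2))
        expect = ((ds - 1) ** 2).mean() + ((dt + 1) ** 2).mean()
        assert dis_loss_level(ds, dt) == pytest.approx(expect, abs=1e-9)

    def test_da_zero_when_target_source_like(self):
        att = np.full((1, 4), 0.7)
        assert da_loss_level(np.ones((1, 4)), att) == 0.0

    def test_da_zero_without_class_evidence(self):
        assert da_loss_level(np.zeros((1, 4)), np.zeros((1, 4))) == 0.0

    def test_da_hand_example(self):
        d = np.array([[0.0, 2.0]])
        att = np.array([[0.5, 1.0]])
        assert da_loss_level(d, att) == pytest.approx(0.75)

    def test_da_attention_is_gradient_blocked(self):
        d = nn.Tensor(np.zeros((2, 2)), requires_grad=True)
        att = nn.Tensor(np.full((2, 2), 0.5), requires_grad=True)
        da_loss_level(d, att).backward()
        assert att.grad is None and d.grad is not None


class TestHierarchicalLoss:
    def test_default_lambdas_sum(self):
        assert hierarchical_loss((1.0, 1.0, 1.0, 1.0)) == pytest.approx(1.875)
        assert DEFAULT_LAMBDAS == (0.125, 0.25, 0.5, 1.0)

    def test_single_level_linearity(self):
        for l in range(4):
            levels = [0.0] * 4
            levels[l] = 3.0
            assert hierarchical_loss(levels) == \
                pytest.approx(DEFAULT_LAMBDAS[l] * 3.0)

    def test_homogeneous_in_lambda(self):
        levels = (0.5, 1.5, 2.5, 3.5)
        lam = DEFAULT_LAMBDAS
        scaled = tuple(3.0 * w for w in lam)
        assert hierarchical_loss(levels, scaled) == \
            pytest.approx(3.0 * hierarchical_loss(levels, lam))


# ---------------------------------------------------------------------------
# overlap metrics
# ---------------------------------------------------------------------------

class TestOverlapMetrics:
    def test_identity_and_disjoint(self):
        m = random_mask((5, 6, 6), 0.3, 0)
        assert dsc(m, m) == 100.0 and jaccard(m, m) == 100.0
        a = np.zeros((2, 2, 2), np.uint8)
        b = np.zeros((2, 2, 2), np.uint8)
        a[0, 0, 0] = 1
        b[1, 1, 1] = 1
        assert dsc(a, b) == 0.0 and jaccard(a, b) == 0.0

    def test_counting_oracle_case(self):
        # |P| = |G| = 4, two shared voxels
        p = np.zeros((2, 2, 2), np.uint8).ravel()
        g = np.zeros(8, np.uint8)
        p[:4] = 1
        g[2:6] = 1
        p, g = p.reshape(2, 2, 2), g.reshape(2, 2, 2)
        assert dsc(p, g) == pytest.approx(50.0)
        assert jaccard(p, g) == pytest.approx(100.0 / 3.0)

    def test_dsc_jaccard_identity_on_random_masks(self):
        for seed in range(10):
            p = random_mask((6, 7, 7), 0.25, seed)
            g = random_mask((6, 7, 7), 0.25, seed + 99)
            ji = jaccard(p, g)
            assert dsc(p, g) == pytest.approx(200.0 * ji / (100.0 + ji), abs=1e-9)

    def test_both_empty_convention(self):
        z = np.zeros((3, 3, 3), np.uint8)
        assert dsc(z, z) == 100.0 and jaccard(z, z) == 100.0


class TestSurfaceMetrics:
    SPACING = (5.0, 0.741, 0.741)

    def test_identical_masks_zero(self):
        m = random_mask((6, 8, 8), 0.3, 4)
        assert asd(m, m, self.SPACING) == pytest.approx(0.0, abs=1e-12)
        assert hd95(m, m, self.SPACING) == pytest.approx(0.0, abs=1e-12)

    def test_single_voxel_pair_known_distance(self):
        a = np.zeros((4, 8, 8), np.uint8)
        b = np.zeros((4, 8, 8), np.uint8)
        a[2, 2, 3] = 1
        b[2, 5, 3] = 1  # 3 voxels apart along y
        expect = 3 * 0.741
        assert asd(a, b, self.SPACING) == pytest.approx(expect, abs=1e-9)
        assert hd95(a, b, self.SPACING) == pytest.approx(expect, abs=1e-9)

    def test_matches_exhaustive_oracle_on_random_masks(self):
        for seed in range(8):
            p = random_mask((7, 9, 9), 0.2, seed)
            g = random_mask((7, 9, 9), 0.2, seed + 1000)
            dp, dg = surface_distance_oracle(p, g, self.SPACING)
            np.testing.assert_allclose(
                asd(p, g, self.SPACING), 0.5 * (dp.mean() + dg.mean()),
                atol=1e-9)
            np.testing.assert_allclose(
                hd95(p, g, self.SPACING),
                max(np.percentile(dp, 95), np.percentile(dg, 95)), atol=1e-9)

    def test_hd95_bounded_by_exact_hausdorff(self):
        for seed in range(6):
            p = random_mask((6, 8, 8), 0.15, seed)
            g = random_mask((6, 8, 8), 0.15, seed + 77)
            dp, dg = surface_distance_oracle(p, g, self.SPACING)
            hausdorff = max(dp.max(), dg.max())
            assert hd95(p, g, self.SPACING) <= hausdorff + 1e-12

    def test_symmetry(self):
        p = random_mask((6, 8, 8), 0.2, 12)
        g = random_mask((6, 8, 8), 0.2, 13)
        assert asd(p, g, self.SPACING) == pytest.approx(
            asd(g, p, self.SPACING), abs=1e-12)
        assert hd95(p, g, self.SPACING) == pytest.approx(
            hd95(g, p, self.SPACING), abs=1e-12)
        assert dsc(p, g) == dsc(g, p) and jaccard(p, g) == jaccard(g, p)

    def test_empty_mask_raises(self):
        m = random_mask((4, 4, 4), 0.3, 5)
        with pytest.raises(UndefinedMetricError):
            asd(np.zeros((4, 4, 4), np.uint8), m, self.SPACING)
        with pytest.raises(UndefinedMetricError):
            hd95(m, np.zeros((4, 4, 4), np.uint8), self.SPACING)
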