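"""Training loops, protocols, checkpointing and sliding-window inference."""

import numpy as np
import pytest

from hcadan import nn
from hcadan.astr import AsTr
from hcadan.objectives_metrics import dis_loss_level
from hcadan.phantoms import PhantomSpec, generate_phantom, generate_set
from hcadan.trainer_eval import (Checkpoint, LabeledCase, SplitPlan, TrainConfig,
                                 UnlabeledCase, evaluate, load_checkpoint,
                                 make_five_fold, make_loco, run_protocol,
                                 save_checkpoint, sliding_window_predict,
                                 strip_labels, train_hcada, train_supervised)

SPEC = PhantomSpec(shape=(10, 40, 40), spacing=(5.0, 0.741, 0.741),
                   semi_axes=(2.0, 6.5, 6.5))


def tiny_cfg(**kw):
    base = dict(patch_shape=(8, 32, 32), iterations=2, seed=0, batch_size=1,
                disc_base=(4, 8, 16))
    base.update(kw)
    return TrainConfig.desk(**base)


@pytest.fixture(scope="module")
def cases():
    return [LabeledCase(v, m, "A", f"c{i}")
            for i, (v, m) in enumerate(generate_set(SPEC, 3, seed=0))]


@pytest.fixture(scope="module")
def target_cases():
    return [LabeledCase(v, m, "B", f"t{i}")
            for i, (v, m) in enumerate(generate_set(SPEC, 2, seed=9))]


class TestSupervised:
    def test_zero_iterations_returns_initialization(self, cases):
        cfg = tiny_cfg(iterations=0)
        rng = np.random.default_rng(cfg.seed)
        ref = AsTr(cfg.network, seed=int(rng.integers(2 ** 31)))
        ckpt = train_supervised(cfg, cases)
        for k, v in ref.state_dict().items():
            np.testing.assert_array_equal(ckpt.state[k], v)

    def test_same_seed_reproduces_loss_trajectory(self, cases):
        l1 = train_supervised(tiny_cfg(iterations=3), cases).losses
        l2 = train_supervised(tiny_cfg(iterations=3), cases).losses
        assert [x["L_seg"] for x in l1] == [x["L_seg"] for x in l2]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_supervised(tiny_cfg(), [])


class TestHcada:
    def test_off_mode_equals_supervised(self, cases, target_cases):
        sup = train_supervised(tiny_cfg(iterations=3), cases)
        off = train_hcada(tiny_cfg(iterations=3, align_mode="off"), cases,
                          strip_labels(target_cases))
        assert [x["L_seg"] for x in sup.losses] == \
            [x["L_seg"] for x in off.losses]
        for k in sup.state:
            np.testing.assert_array_equal(sup.state[k], off.state[k])

    def test_labeled_target_rejected(self, cases, target_cases):
        with pytest.raises(TypeError, match="mask"):
            train_hcada(tiny_cfg(), cases, target_cases)

    def test_unlabeled_view_carries_no_mask(self, target_cases):
        for c in strip_labels(target_cases):
            assert isinstance(c, UnlabeledCase)
            assert not hasattr(c, "mask")

    def test_adversarial_losses_logged_per_level_mode(self, cases, target_cases):
        ck = train_hcada(tiny_cfg(iterations=2, align_mode="m1"), cases,
                         strip_labels(target_cases))
        assert {"L_seg", "L_dis_h", "L_da_h"} <= set(ck.losses[0])


class TestProtocols:
    def test_five_fold_partitions_each_case_once(self):
        ids = [f"c{i}" for i in range(10)]
        plan = make_five_fold(ids, seed=1)
        assert sorted(plan.folds) == sorted(ids)
        counts = {f: 0 for f in range(5)}
        for f in plan.folds.values():
            counts[f] += 1
        assert all(c == 2 for c in counts.values())

    def test_loco_needs_multiple_centers(self):
        with pytest.raises(ValueError):
            make_loco({"a": "C0", "b": "C0"})

    def test_loco_never_leaks_target_center(self, cases, target_cases):
        all_cases = cases + target_cases
        plan = make_loco({c.case_id: c.center for c in all_cases})
        results = run_protocol(plan, tiny_cfg(iterations=1), all_cases,
                               iterations=1)
        assert set(results) == {"A", "B"}

    def test_report_means_equal_hand_average(self, cases):
        ckpt = train_supervised(tiny_cfg(iterations=1), cases)
        agg, per = evaluate(ckpt, cases)
        vals = [c["DSC"] for c in per]
        assert agg["DSC"][0] == pytest.approx(np.mean(vals))
        assert agg["DSC"][1] == pytest.approx(np.std(vals))


class _OracleNet:
    """Stub predictor emitting +/-10 logits from a fixed mask."""

    def __init__(self, mask):
        self.mask = mask

    def eval(self):
        return self

    def __call__(self, x):
        m = self.mask[None, None].astype(np.float32)
        logits = np.concatenate([-10 * (2 * m - 1), 10 * (2 * m - 1)], axis=1)
        return nn.Tensor(logits), {}


class TestEvaluate:
    def test_oracle_predictor_scores_perfectly(self, cases):
        case = cases[0]
        ckpt = Checkpoint(state={}, config=tiny_cfg(
            patch_shape=case.image.data.shape), seed=0)
        agg, per = evaluate(ckpt, [case], net=_OracleNet(case.mask.data))
        assert agg["DSC"][0] == 100.0
        assert agg["ASD"][0] == pytest.approx(0.0, abs=1e-12)

    def test_all_background_prediction_flagged_undefined(self, cases):
        case = cases[0]
        ckpt = Checkpoint(state={}, config=tiny_cfg(
            patch_shape=case.image.data.shape), seed=0)
        empty = np.zeros_like(case.mask.data)
        agg, per = evaluate(ckpt, [case], net=_OracleNet(empty))
        assert per[0]["DSC"] == 0.0
        assert not per[0]["distance_defined"]
        assert agg["n_distance_excluded"] == 1

    def test_single_window_equals_direct_inference(self, cases):
        net = AsTr(tiny_cfg().network, seed=0).eval()
        img = cases[0].image.data[:8, :32, :32]
        logits = sliding_window_predict(net, img, (8, 32, 32))
        with nn.no_grad():
            direct, _ = net(img[None, None].astype(np.float32))
        np.testing.assert_allclose(logits, direct.data[0], atol=1e-6)

    def test_overlapping_windows_average_smoothly(self, cases):
        net = AsTr(tiny_cfg().network, seed=0).eval()
        img = cases[0].image.data  # 10x40x40 > patch: overlapping windows
        logits = sliding_window_predict(net, img, (8, 32, 32))
        assert logits.shape == (2,) + img.shape
        assert np.all(np.isfinite(logits))

    def test_spacing_mismatch_rejected(self, cases):
        ckpt = Checkpoint(state={}, config=tiny_cfg(
            patch_shape=cases[0].image.data.shape,
            expected_spacing=(2.0, 1.0, 1.0)), seed=0)
        with pytest.raises(ValueError, match="spacing"):
            evaluate(ckpt, [cases[0]], net=_OracleNet(cases[0].mask.data))


class TestCheckpointRoundtrip:
    def test_save_load_evaluate_bitwise(self, tmp_path, cases):
        ckpt = train_supervised(tiny_cfg(iterations=1), cases)
        path = str(tmp_path / "ck.npz")
        save_checkpoint(ckpt, path)
        loaded = load_checkpoint(path)
        a1, p1 = evaluate(ckpt, cases[:1])
        a2, p2 = evaluate(loaded, cases[:1])
        assert p1[0]["DSC"] == p2[0]["DSC"]
        assert p1[0]["HD95"] == p2[0]["HD95"] or (
            np.isnan(p1[0]["HD95"]) and np.isnan(p2[0]["HD95"]))

    def test_nonfinite_loss_aborts_with_diagnostic(self, cases):
        from hcadan.io_preprocess import Volume3D
        bad_img = Volume3D(np.full_like(cases[0].image.data, np.nan),
                           cases[0].image.spacing)
        bad = [LabeledCase(bad_img, cases[0].mask, "A", "bad")]
        with pytest.raises(RuntimeError, match="non-finite"):
            train_supervised(tiny_cfg(iterations=2), bad)
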