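"""Architecture contracts of the AsTr backbone and its blocks."""

import numpy as np
import pytest

from hcadan import nn
from hcadan.astr import (AsBlock, AsTr, DeTransEncoder, NetworkConfig,
                         PBABlock, SEResBlock, summary)

RNG = np.random.default_rng(3)


def _rand(shape):
    return nn.Tensor(RNG.standard_normal(shape).astype(np.float32))


class TestAsBlock:
    def test_spatial_shape_preserved(self):
        blk = AsBlock(3, 5, np.random.default_rng(0))
        y = blk(_rand((2, 3, 4, 8, 8)))
        assert y.shape == (2, 5, 4, 8, 8)

    def test_zero_weights_give_zero_output(self):
        blk = AsBlock(2, 4, np.random.default_rng(0))
        for conv in blk.conv_layers:
            conv.weight.data[:] = 0
            conv.bias.data[:] = 0
        # GroupNorm of a zero field is beta = 0; PReLU(0) = 0
        y = blk(_rand((1, 2, 3, 6, 6)))
        np.testing.assert_allclose(y.data, 0.0, atol=1e-7)

    @pytest.mark.parametrize("c_in,c_out", [(2, 4), (4, 4), (3, 8)])
    def test_conv_parameter_count_closed_form(self, c_in, c_out):
        blk = AsBlock(c_in, c_out, np.random.default_rng(0))
        # 4 conv layers: 1x3x3, 3x1x1, two 1x1x1 projections (+ biases)
        expect = (c_out * c_in * 9 + c_out            # in-plane
                  + c_out * c_in * 3 + c_out          # through-plane
                  + c_out * c_in * 1 + c_out          # input projection
                  + c_out * 3 * c_out * 1 + c_out)    # output projection
        got = sum(conv.weight.data.size + conv.bias.data.size
                  for conv in blk.conv_layers)
        assert got == expect


class TestSEResBlock:
    def test_zeroed_branch_is_identity_for_any_gate(self):
        blk = SEResBlock(4, np.random.default_rng(0))
        blk.conv1.conv.weight.data[:] = 0
        blk.conv1.conv.bias.data[:] = 0
        blk.conv2.weight.data[:] = 0
        blk.conv2.bias.data[:] = 0
        x = _rand((1, 4, 3, 6, 6))
        np.testing.assert_allclose(blk(x).data, x.data, atol=1e-7)

    def test_gate_saturated_high_passes_branch(self):
        blk = SEResBlock(4, np.random.default_rng(0))
        blk.se.fc2.bias.data[:] = 50.0  # sigmoid -> 1
        x = _rand((1, 4, 3, 6, 6))
        branch = blk.norm2(blk.conv2(blk.conv1(x)))
        np.testing.assert_allclose(blk(x).data, x.data + branch.data, atol=1e-5)

    def test_gate_values_in_unit_interval(self):
        blk = SEResBlock(8, np.random.default_rng(1))
        g = blk.se.gate(_rand((2, 8, 3, 4, 4))).data
        assert np.all(g > 0) and np.all(g < 1)


class TestPBABlock:
    def test_constant_field_branches_are_half_constant(self):
        # F == c -> every pooled field == c, sigmoid(0) = 0.5, branch = 0.5c
        for kernels in [(3, 5), (5, 7)]:
            blk = PBABlock(2, kernels, np.random.default_rng(0))
            x = nn.Tensor(np.full((1, 2, 4, 8, 8), 3.0, dtype=np.float32))
            for br in blk.branches(x):
                np.testing.assert_allclose(br.data, 1.5, atol=1e-6)

    def test_hand_computed_single_branch(self):
        # one branch, window spanning the whole 1x2x2 grid F=[[1,2],[3,4]]
        blk = PBABlock(1, (3,), np.random.default_rng(0))
        x = nn.Tensor(np.array([1.0, 2, 3, 4]).reshape(1, 1, 1, 2, 2))
        br = blk.branches(x)[0].data.ravel()
        f = np.array([1.0, 2, 3, 4])
        expect = 1 / (1 + np.exp(-(f - 2.5))) * f
        np.testing.assert_allclose(br, expect, atol=1e-6)

    def test_default_kernel_sets_per_level(self):
        cfg = NetworkConfig()
        assert cfg.pba_kernels == ((3, 5), (3, 5), (5, 7), (5, 7))

    def test_even_or_small_kernels_rejected(self):
        with pytest.raises(ValueError):
            PBABlock(2, (4,), np.random.default_rng(0))


class TestEncoder:
    def test_pyramid_shapes_and_channels(self):
        cfg = NetworkConfig.desk()
        net = AsTr(cfg, seed=0)
        x = _rand((1, 1, 16, 64, 64))
        pyr = net.encoder(x)
        c1, c2, c3, c4 = cfg.channels
        assert pyr[4].shape == (1, c1, 16, 32, 32)
        assert pyr[3].shape == (1, c2, 16, 16, 16)
        assert pyr[2].shape == (1, c3, 8, 8, 8)
        assert pyr[1].shape == (1, c4, 4, 4, 4)

    def test_stage_counts(self):
        cfg = NetworkConfig()
        enc = AsTr(NetworkConfig.desk(), seed=0).encoder
        assert cfg.as_blocks == (2, 3) and cfg.se_blocks == (3, 2)
        assert len(enc.as_stage1) == 2 and len(enc.as_stage2) == 3
        assert len(enc.se_stage1) == 3 and len(enc.se_stage2) == 2

    def test_pyramid_monotone_spatial_volume(self):
        net = AsTr(NetworkConfig.desk(), seed=0)
        pyr = net.encoder(_rand((1, 1, 8, 32, 32)))
        vols = [np.prod(pyr[l].shape[2:]) for l in (1, 2, 3, 4)]
        assert vols == sorted(vols) and len(set(vols)) == 4

    def test_indivisible_shape_rejected(self):
        net = AsTr(NetworkConfig.desk(), seed=0)
        with pytest.raises(ValueError, match="divisible"):
            net(np.zeros((1, 1, 6, 32, 32), dtype=np.float32))


@pytest.fixture(scope="module")
def net():
    return AsTr(NetworkConfig.desk(), seed=1)


class TestDeTrans:
    def test_shapes_preserved(self, net):
        pyr = net.encoder(_rand((1, 1, 8, 32, 32)))
        out = net.detrans(pyr)
        for l in (1, 2, 3, 4):
            assert out[l].shape == pyr[l].shape

    def test_attention_weights_sum_to_one(self, net):
        layer = net.detrans.layers[0]
        x = _rand((2, 10, net.detrans.d_model))
        w = layer.attn.attention_weights(x).data
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)

    def test_zeroed_attention_reduces_to_ffn_path(self, net):
        cfg = NetworkConfig.desk(detrans_layers=1)
        net1 = AsTr(cfg, seed=2)
        layer = net1.detrans.layers[0]
        for lin in (layer.attn.value_proj, layer.attn.offset_proj,
                    layer.attn.weight_proj, layer.attn.out_proj):
            lin.weight.data[:] = 0
            lin.bias.data[:] = 0
        pyr = net1.encoder(_rand((1, 1, 8, 32, 32)))
        shapes = {l: t.shape[2:] for l, t in pyr.levels.items()}
        # assemble the token sequence exactly as the encoder does
        toks = []
        import numpy as _np
        for l in sorted(shapes):
            t = net1.detrans.in_proj[l](pyr[l])
            nb, d = t.shape[0], t.shape[1]
            tok = t.reshape(nb, d, int(_np.prod(shapes[l]))).transpose((0, 2, 1))
            toks.append(tok + net1.detrans.level_embed[l - 1].reshape(1, 1, d))
        from hcadan.astr import sinusoidal_position_encoding
        x = nn.cat(toks, axis=1) + nn.Tensor(
            sinusoidal_position_encoding(shapes, net1.detrans.d_model)[None])
        expect = layer.ffn_only(x)
        refs = net1.detrans.reference_points(shapes)
        got = layer(x, shapes, refs)
        np.testing.assert_allclose(got.data, expect.data, atol=1e-5)


class TestForward:
    def test_full_resolution_logits_and_pyramid_pba_feats(self, net):
        x = RNG.standard_normal((1, 1, 16, 64, 64)).astype(np.float32)
        with nn.no_grad():
            logits, pba = net(x)
        assert logits.shape == (1, 2, 16, 64, 64)
        c1, c2, c3, c4 = net.cfg.channels
        assert pba[1].shape == (1, c4, 4, 4, 4)
        assert pba[2].shape == (1, c3, 8, 8, 8)
        assert pba[3].shape == (1, c2, 16, 16, 16)
        assert pba[4].shape == (1, c1, 16, 32, 32)

    def test_eval_mode_deterministic(self, net):
        net.eval()
        x = RNG.standard_normal((1, 1, 8, 32, 32)).astype(np.float32)
        with nn.no_grad():
            l1, _ = net(x)
            l2, _ = net(x)
        np.testing.assert_array_equal(l1.data, l2.data)

    def test_pba_disabled_returns_pre_pba_features(self):
        cfg = NetworkConfig.desk(use_pba=False)
        net = AsTr(cfg, seed=0)
        x = RNG.standard_normal((1, 1, 8, 32, 32)).astype(np.float32)
        with nn.no_grad():
            logits, pba = net(x)
        assert logits.shape == (1, 2, 8, 32, 32)
        assert set(pba) == {1, 2, 3, 4}

    def test_summary_total_matches_independent_count(self, net):
        text = summary(net)
        total_line = int(text.strip().splitlines()[-1].split()[-1])
        independent = sum(int(np.prod(p.data.shape))
                          for _, p in net.named_parameters())
        assert total_line == independent == net.num_parameters()

    def test_all_decoder_parameters_receive_gradient(self, net):
        net.train()
        x = RNG.standard_normal((1, 1, 8, 32, 32)).astype(np.float32)
        logits, _ = net(x)
        (logits ** 2).mean().backward()
        missing = [n for n, p in net.decoder.named_parameters()
                   if p.grad is None or not np.any(p.grad)]
        assert missing == []
        net.zero_grad()
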