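"""Architecture contracts: dice-loss analytics, PSA block equations,
attention gating, U-net shape arithmetic and gradient flow."""

import numpy as np
import pytest

from mammoseg import nn
from mammoseg.networks import (AttentionGate, CascadeAttentionUNet, LossInputs,
                               NetConfig, PSABlock, UNet,
                               attention_gate_forward, build_cascade_segmenter,
                               build_presegmenter, dice_loss,
                               psa_block_forward)

DESK = dict(levels=3, filters_per_level=(4, 8, 16), input_size=32)


class TestDiceLoss:
    def test_perfect_overlap_approaches_zero(self):
        # p = g = 1 over n=100: 1 - 200/(200 + 1e-6)
        val = dice_loss(np.ones(100), np.ones(100), eps=1e-6)
        assert np.isclose(val, 1e-6 / (200 + 1e-6), rtol=1e-9)

    def test_disjoint_prediction_is_one(self):
        g = np.zeros(64)
        g[:8] = 1
        assert dice_loss(np.zeros(64), g) == 1.0

    def test_both_empty_is_one(self):
        assert dice_loss(np.zeros(50), np.zeros(50)) == 1.0

    def test_loss_inputs_container(self):
        li = LossInputs(p=np.ones(10), g=np.ones(10), epsilon=1e-6)
        assert np.isclose(dice_loss(li), 1e-6 / (20 + 1e-6), rtol=1e-9)

    def test_bounded_and_monotone_in_correct_pixel(self, rng):
        g = (rng.uniform(0, 1, 64) > 0.5).astype(float)
        p = rng.uniform(0, 1, 64)
        base = dice_loss(p, g)
        assert 0.0 <= base <= 1.0
        idx = int(np.nonzero(g)[0][0])
        p2 = p.copy()
        p2[idx] = min(p[idx] + 0.2, 1.0)
        # raising a correctly-predicted mass pixel's probability lowers loss
        assert dice_loss(p2, g) < base

    def test_shape_mismatch_and_bad_eps(self):
        with pytest.raises(ValueError):
            dice_loss(np.ones(4), np.ones(5))
        with pytest.raises(ValueError):
            dice_loss(np.ones(4), np.ones(4), eps=0.0)


class TestPSABlock:
    def test_level1_shapes_from_fullscale_model(self, rng):
        """F1 of 256x256x32 with P0 of 512x512 yields O1 256x256x32 and
        P1 256x256."""
        block = PSABlock(32, rng)
        p0 = rng.uniform(0, 1, (512, 512))
        f1 = rng.normal(0, 1, (256, 256, 32))
        o1, p1 = psa_block_forward(p0, f1, block)
        assert o1.shape == (256, 256, 32)
        assert p1.shape == (256, 256)

    def test_avgpool_halves_saliency(self, rng):
        block = PSABlock(4, rng)
        p0 = rng.uniform(0, 1, (16, 16))
        f = rng.normal(0, 1, (8, 8, 4))
        _, p1 = psa_block_forward(p0, f, block)
        expected = p0.reshape(8, 2, 8, 2).mean(axis=(1, 3))
        assert np.allclose(p1, expected, atol=1e-6)

    def test_zero_features_give_zero_output(self, rng):
        block = PSABlock(8, rng)
        o, _ = psa_block_forward(rng.uniform(0, 1, (16, 16)),
                                 np.zeros((8, 8, 8)), block)
        assert np.allclose(o, 0.0)

    def test_attenuation_bound_and_coefficient_range(self, rng):
        """Across random weight draws: coefficients strictly in (0,1) and
        |O| <= |F| elementwise."""
        for draw in range(10):
            block = PSABlock(6, np.random.default_rng(draw))
            p = rng.uniform(0, 1, (16, 16))
            f = rng.normal(0, 2, (8, 8, 6))
            p_t = nn.Tensor(p[None, None].astype(np.float32))
            f_t = nn.Tensor(f.transpose(2, 0, 1)[None].astype(np.float32))
            o_n, _, coeff = block(p_t, f_t)
            assert np.all(coeff.data > 0) and np.all(coeff.data < 1)
            assert np.all(np.abs(o_n.data) <= np.abs(f_t.data) + 1e-7)

    def test_spatial_misalignment_rejected(self, rng):
        block = PSABlock(4, rng)
        with pytest.raises(ValueError):
            psa_block_forward(rng.uniform(0, 1, (16, 16)),
                              rng.normal(0, 1, (4, 4, 4)), block)


class TestAttentionGate:
    def test_output_shape_equals_skip(self, rng):
        gate = AttentionGate(8, 16, rng)
        out = attention_gate_forward(rng.normal(0, 1, (8, 8, 16)),
                                     rng.normal(0, 1, (8, 8, 8)), gate)
        assert out.shape == (8, 8, 8)

    def test_zero_skip_gives_zero_output(self, rng):
        gate = AttentionGate(4, 4, rng)
        out = attention_gate_forward(rng.normal(0, 1, (8, 8, 4)),
                                     np.zeros((8, 8, 4)), gate)
        assert np.allclose(out, 0.0)

    def test_gate_attenuates_never_amplifies(self, rng):
        gate = AttentionGate(4, 8, rng)
        skip = rng.normal(0, 1, (8, 8, 4))
        out = attention_gate_forward(rng.normal(0, 1, (8, 8, 8)), skip, gate)
        assert np.all(np.abs(out) <= np.abs(skip) + 1e-7)


class TestPresegmenterUNet:
    def test_forward_maps_to_probability_map(self, rng):
        net = build_presegmenter(NetConfig(**DESK, seed=1))
        out = net.predict(rng.uniform(0, 1, (32, 32, 3)))
        assert out.shape == (32, 32)
        assert out.min() >= 0 and out.max() <= 1

    def test_bottleneck_side_and_pool_count(self):
        net = UNet(NetConfig(**DESK, seed=0))
        x = nn.Tensor(np.zeros((1, 3, 32, 32), np.float32))
        h = x
        for block in net.enc:
            h = nn.maxpool2(block(h))
        assert h.shape[2] == 32 // 2 ** 3  # one pool per level
        assert len(net.enc) == 3

    def test_same_seed_identical_weights(self):
        a = UNet(NetConfig(**DESK, seed=5))
        b = UNet(NetConfig(**DESK, seed=5))
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)

    def test_net_config_yaml_roundtrip(self):
        cfg = NetConfig(**DESK, with_psa=True, seed=3)
        assert NetConfig.from_yaml(cfg.to_yaml()) == cfg

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            UNet(NetConfig(levels=3, filters_per_level=(4, 8), input_size=32))
        with pytest.raises(ValueError):
            UNet(NetConfig(levels=3, filters_per_level=(4, 8, 16), input_size=30))
        with pytest.raises(ValueError):
            build_presegmenter(NetConfig(**DESK, with_psa=True))


class TestCascadeSegmenter:
    def test_two_input_forward_shape(self, rng):
        net = build_cascade_segmenter(NetConfig(**DESK, with_psa=True, seed=2))
        out = net.predict(rng.uniform(0, 1, (32, 32, 3)),
                          rng.uniform(0, 1, (32, 32)))
        assert out.shape == (32, 32)
        assert out.min() >= 0 and out.max() <= 1

    def test_one_psa_block_per_level(self):
        net = build_cascade_segmenter(NetConfig(**DESK, with_psa=True, seed=0))
        assert len(net.psa) == 3
        with pytest.raises(ValueError):
            build_cascade_segmenter(NetConfig(**DESK, with_psa=False))

    def test_saliency_cascade_sizes(self, rng):
        """P_n side halves at every encoder level: input_size / 2^n."""
        cfg = NetConfig(levels=3, filters_per_level=(2, 4, 8), input_size=64,
                        with_psa=True, seed=3)
        net = CascadeAttentionUNet(cfg)
        sal = nn.Tensor(rng.uniform(0, 1, (1, 1, 64, 64)).astype(np.float32))
        img = nn.Tensor(rng.uniform(0, 1, (1, 3, 64, 64)).astype(np.float32))
        h, p = img, sal
        for n, block in enumerate(net.enc, start=1):
            pooled = nn.maxpool2(block(h))
            o_n, p, _ = net.psa[n - 1](p, pooled)
            assert p.shape[2] == 64 // 2 ** n
            h = o_n

    def test_output_is_sensitive_to_saliency(self, rng):
        net = build_cascade_segmenter(NetConfig(**DESK, with_psa=True, seed=4))
        img = rng.uniform(0, 1, (32, 32, 3))
        out0 = net.predict(img, np.zeros((32, 32)))
        out1 = net.predict(img, np.ones((32, 32)))
        assert np.abs(out0 - out1).max() > 1e-6

    def test_missing_saliency_rejected(self, rng):
        net = build_cascade_segmenter(NetConfig(**DESK, with_psa=True, seed=4))
        with pytest.raises(ValueError):
            net.forward(nn.Tensor(np.zeros((1, 3, 32, 32), np.float32)), None)

    def test_gradients_reach_both_input_paths(self, rng):
        """Nonzero finite loss gradients flow to the image and the saliency
        branch: neither path is dead."""
        net = build_cascade_segmenter(NetConfig(**DESK, with_psa=True, seed=6))
        img = nn.Tensor(rng.uniform(0, 1, (2, 3, 32, 32)).astype(np.float32),
                        requires_grad=True)
        sal = nn.Tensor(rng.uniform(0, 1, (2, 1, 32, 32)).astype(np.float32),
                        requires_grad=True)
        gt = (rng.uniform(0, 1, (2, 1, 32, 32)) > 0.8).astype(np.float32)
        loss = nn.dice_loss_tensor(net.forward(img, sal), gt)
        loss.backward()
        for t in (img, sal):
            assert t.grad is not None
            assert np.all(np.isfinite(t.grad))
            assert np.abs(t.grad).max() > 0

    def test_state_dict_roundtrip(self, rng, tmp_path):
        net = build_cascade_segmenter(NetConfig(**DESK, with_psa=True, seed=7))
        img = rng.uniform(0, 1, (32, 32, 3))
        sal = rng.uniform(0, 1, (32, 32))
        before = net.predict(img, sal)
        net.save(tmp_path / "w.npz")
        other = build_cascade_segmenter(NetConfig(**DESK, with_psa=True, seed=99))
        other.load(tmp_path / "w.npz")
        assert np.allclose(other.predict(img, sal), before)
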