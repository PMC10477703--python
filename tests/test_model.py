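"""Network forward operations against independent loop-based oracles."""

import numpy as np
import pytest

from preictal import reference as ref
from preictal.model import (CbamGruNet, CbamParams, ConfigurationError,
                            ConvBlockParams, GruParams, VARIANTS, cbam,
                            channel_attention, conv_block_forward, gru_forward,
                            gru_step, network_forward, spatial_attention)


def _random_block(rng, c_in=3, c_out=4, k=(3, 3), stride=(1, 1), pool=(2, 2)):
    return ConvBlockParams(
        bn_gamma=rng.uniform(0.5, 1.5, c_in).astype(np.float32),
        bn_beta=rng.standard_normal(c_in).astype(np.float32),
        bn_running_mean=rng.standard_normal(c_in).astype(np.float32),
        bn_running_var=rng.uniform(0.5, 2.0, c_in).astype(np.float32),
        kernels=rng.standard_normal((c_out, c_in) + k).astype(np.float32),
        bias=rng.standard_normal(c_out).astype(np.float32),
        stride=stride, pool=pool,
    )


def _random_cbam(rng, C=8):
    return CbamParams(
        mlp_w1=rng.standard_normal((C, C // 4)).astype(np.float32),
        mlp_b1=rng.standard_normal(C // 4).astype(np.float32),
        mlp_w2=rng.standard_normal((C // 4, C)).astype(np.float32),
        mlp_b2=rng.standard_normal(C).astype(np.float32),
        spatial_kernel=rng.standard_normal((1, 2, 1, 1)).astype(np.float32),
        spatial_bias=rng.standard_normal(1).astype(np.float32),
    )


def _random_gru(rng, nx, nh):
    return GruParams(
        W_rx=rng.standard_normal((nx, nh)).astype(np.float32),
        W_rh=rng.standard_normal((nh, nh)).astype(np.float32),
        b_r=rng.standard_normal(nh).astype(np.float32),
        W_ux=rng.standard_normal((nx, nh)).astype(np.float32),
        W_uh=rng.standard_normal((nh, nh)).astype(np.float32),
        b_u=rng.standard_normal(nh).astype(np.float32),
        W_xh=rng.standard_normal((nx, nh)).astype(np.float32),
        W_hh=rng.standard_normal((nh, nh)).astype(np.float32),
        nh=nh,
    )


class TestConvBlock:
    def test_shape_chain_matches_printed_feature_map(self):
        net = CbamGruNet(n_channels=22, seed=0)
        x = np.random.default_rng(0).standard_normal((22, 59, 114)).astype(np.float32)
        shapes = []
        h = x
        for blk in net.conv_blocks:
            h = conv_block_forward(h, blk)
            shapes.append(h.shape)
        assert shapes == [(16, 14, 27), (32, 6, 12), (64, 2, 5)]

    def test_zero_input_zero_beta_gives_zero_output(self):
        rng = np.random.default_rng(1)
        p = _random_block(rng)
        p.bn_beta[:] = 0
        p.bn_running_mean[:] = 0
        p.bias[:] = 0
        out = conv_block_forward(np.zeros((3, 8, 8), dtype=np.float32), p)
        assert np.all(out == 0)

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = _random_block(rng, stride=(2, 1) if seed % 2 else (1, 1))
        x = rng.standard_normal((3, 9, 11)).astype(np.float32)
        prod = conv_block_forward(x, p)
        loop = ref.conv_block_reference(x, p)
        assert np.abs(prod - loop).max() < 1e-5

    def test_kernel_larger_than_input_rejected(self):
        rng = np.random.default_rng(2)
        p = _random_block(rng, k=(5, 5))
        with pytest.raises(ValueError, match="smaller than kernel"):
            conv_block_forward(rng.standard_normal((3, 4, 4)).astype(np.float32), p)

    def test_nan_input_rejected(self):
        rng = np.random.default_rng(3)
        p = _random_block(rng)
        x = np.full((3, 8, 8), np.nan, dtype=np.float32)
        with pytest.raises(ValueError, match="NaN"):
            conv_block_forward(x, p)


class TestChannelAttention:
    def test_zero_weights_give_half_attention(self):
        p = _random_cbam(np.random.default_rng(0))
        for f in ("mlp_w1", "mlp_b1", "mlp_w2", "mlp_b2"):
            getattr(p, f)[:] = 0
        F = np.random.default_rng(1).standard_normal((8, 3, 5)).astype(np.float32)
        ce, Fp = channel_attention(F, p)
        assert np.allclose(ce, 0.5)
        assert np.allclose(Fp, 0.5 * F, atol=1e-7)

    def test_constant_map_makes_pools_coincide(self):
        rng = np.random.default_rng(2)
        p = _random_cbam(rng)
        means = rng.standard_normal(8).astype(np.float32)
        F = np.broadcast_to(means[:, None, None], (8, 3, 5)).copy()
        ce, _ = channel_attention(F, p)
        # CE = sigmoid(2 * MLP(channel means)) since max-pool == avg-pool
        hid = np.maximum(means @ p.mlp_w1 + p.mlp_b1, 0)
        expected = 1 / (1 + np.exp(-2 * (hid @ p.mlp_w2 + p.mlp_b2)))
        assert np.allclose(ce, expected, atol=1e-6)

    def test_swapping_pooled_descriptors_leaves_ce_unchanged(self):
        """The shared MLP outputs are added, so descriptor order is irrelevant."""
        rng = np.random.default_rng(3)
        p = _random_cbam(rng)
        F = rng.standard_normal((8, 3, 5)).astype(np.float32)
        ce, _ = channel_attention(F, p)
        mx, av = F.max(axis=(1, 2)), F.mean(axis=(1, 2))

        def mlp(d):
            return np.maximum(d @ p.mlp_w1 + p.mlp_b1, 0) @ p.mlp_w2 + p.mlp_b2

        swapped = 1 / (1 + np.exp(-(mlp(av) + mlp(mx))))
        assert np.allclose(ce, swapped, atol=1e-6)

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_loop_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        p = _random_cbam(rng)
        F = rng.standard_normal((8, 3, 5)).astype(np.float32)
        ce, Fp = channel_attention(F, p)
        ce_ref, Fp_ref = ref.channel_attention_reference(F, p)
        assert np.abs(ce - ce_ref).max() < 1e-6
        assert np.abs(Fp - Fp_ref).max() < 1e-6


class TestSpatialAttention:
    def test_zero_conv_gives_half_attention(self):
        p = _random_cbam(np.random.default_rng(0))
        p.spatial_kernel[:] = 0
        p.spatial_bias[:] = 0
        F = np.random.default_rng(1).standard_normal((8, 3, 5)).astype(np.float32)
        se, Fpp = spatial_attention(F, p)
        assert np.allclose(se, 0.5)
        assert np.allclose(Fpp, 0.5 * F, atol=1e-7)

    def test_identical_channels_make_pools_coincide(self):
        rng = np.random.default_rng(2)
        p = _random_cbam(rng)
        one = rng.standard_normal((3, 5)).astype(np.float32)
        F = np.repeat(one[None], 8, axis=0)
        se, _ = spatial_attention(F, p)
        w = p.spatial_kernel[0, :, 0, 0]
        expected = 1 / (1 + np.exp(-(w[0] * one + w[1] * one + p.spatial_bias[0])))
        assert np.allclose(se, expected, atol=1e-6)

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_loop_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        p = _random_cbam(rng)
        F = rng.standard_normal((8, 3, 5)).astype(np.float32)
        se, Fpp = spatial_attention(F, p)
        se_ref, Fpp_ref = ref.spatial_attention_reference(F, p)
        assert np.abs(se - se_ref).max() < 1e-6
        assert np.abs(Fpp - Fpp_ref).max() < 1e-6


class TestCbamVariants:
    def test_none_is_identity(self):
        rng = np.random.default_rng(0)
        p = _random_cbam(rng)
        F = rng.standard_normal((8, 3, 5)).astype(np.float32)
        assert np.array_equal(cbam(F, p, "none"), F)

    def test_cbam_is_spatial_after_channel(self):
        rng = np.random.default_rng(1)
        p = _random_cbam(rng)
        F = rng.standard_normal((8, 3, 5)).astype(np.float32)
        _, Fp = channel_attention(F, p)
        _, Fpp = spatial_attention(Fp, p)
        assert np.allclose(cbam(F, p, "cbam"), Fpp, atol=1e-6)

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_attention_shrinks_nonnegative_maps(self, variant):
        """All attention weights are < 1, so outputs never exceed inputs (F >= 0)."""
        rng = np.random.default_rng(2)
        p = _random_cbam(rng)
        F = np.abs(rng.standard_normal((8, 3, 5))).astype(np.float32)
        out = cbam(F, p, variant)
        assert out.shape == F.shape
        if variant != "none":
            assert np.all(out <= F + 1e-7)

    def test_unknown_variant_rejected(self):
        p = _random_cbam(np.random.default_rng(0))
        with pytest.raises(ValueError, match="variant"):
            cbam(np.zeros((8, 2, 2), dtype=np.float32), p, "both")


class TestGru:
    def test_zero_input_zero_state_zero_bias(self):
        rng = np.random.default_rng(0)
        p = _random_gru(rng, 4, 3)
        p.b_r[:] = 0
        p.b_u[:] = 0
        h = gru_step(np.zeros(4, dtype=np.float32), np.zeros(3, dtype=np.float32), p)
        assert np.allclose(h, 0)   # r=u=0.5, candidate tanh(0)=0, h=(1-u)*0+u*0

    def test_saturated_update_gate_freezes_state(self):
        rng = np.random.default_rng(1)
        p = _random_gru(rng, 4, 3)
        p.b_u[:] = -50.0           # u -> 0 => h_t = h_prev
        h_prev = rng.standard_normal(3).astype(np.float32)
        h = gru_step(rng.standard_normal(4).astype(np.float32), h_prev, p)
        assert np.allclose(h, h_prev, atol=1e-5)

    def test_scalar_case_matches_hand_evaluation(self):
        p = GruParams(W_rx=np.array([[0.5]]), W_rh=np.array([[-0.3]]), b_r=np.array([0.1]),
                      W_ux=np.array([[0.2]]), W_uh=np.array([[0.4]]), b_u=np.array([-0.2]),
                      W_xh=np.array([[0.7]]), W_hh=np.array([[0.6]]), nh=1)
        x, h0 = 0.8, -0.5
        import math
        r = 1 / (1 + math.exp(-(h0 * -0.3 + x * 0.5 + 0.1)))
        u = 1 / (1 + math.exp(-(h0 * 0.4 + x * 0.2 - 0.2)))
        cand = math.tanh((h0 * 0.6) * r + x * 0.7)    # reset gate after the product
        expected = (1 - u) * h0 + u * cand
        h = gru_step(np.array([x]), np.array([h0]), p)
        assert abs(float(h[0]) - expected) < 1e-8

    @pytest.mark.parametrize("standard", [False, True])
    def test_step_agrees_with_loop_oracle(self, standard):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = _random_gru(rng, 6, 5)
            x = rng.standard_normal(6).astype(np.float32)
            h = rng.standard_normal(5).astype(np.float32)
            prod = gru_step(x, h, p, standard=standard)
            loop = ref.gru_step_reference(x, h, p, standard=standard)
            assert np.abs(prod - loop).max() < 1e-6

    def test_length_one_sequence_equals_single_step(self):
        rng = np.random.default_rng(3)
        p = _random_gru(rng, 4, 3)
        x = rng.standard_normal((1, 4)).astype(np.float32)
        seq = gru_forward(x, p)
        step = gru_step(x[0], np.zeros(3, dtype=np.float32), p)
        assert np.allclose(seq[0], step)

    def test_sequence_agrees_with_loop_oracle(self):
        rng = np.random.default_rng(4)
        p = _random_gru(rng, 4, 3)
        xs = rng.standard_normal((7, 4)).astype(np.float32)
        assert np.abs(gru_forward(xs, p) -
                      ref.gru_forward_reference(xs, p)).max() < 1e-6
        assert np.abs(gru_forward(xs, p, return_mode="last") -
                      ref.gru_forward_reference(xs, p, return_mode="last")).max() < 1e-6

    def test_zero_weights_halve_state_each_step(self):
        """With all weights/biases zero, u=0.5 and candidate=0: h_T = h0 / 2^T."""
        p = GruParams(**{k: np.zeros((3, 3), dtype=np.float32)
                         for k in ("W_rh", "W_uh", "W_hh")},
                      **{k: np.zeros((2, 3), dtype=np.float32)
                         for k in ("W_rx", "W_ux", "W_xh")},
                      b_r=np.zeros(3, dtype=np.float32),
                      b_u=np.zeros(3, dtype=np.float32), nh=3)
        h0 = np.array([1.0, -2.0, 4.0], dtype=np.float32)
        T = 5
        hT = gru_forward(np.zeros((T, 2), dtype=np.float32), p, h0=h0,
                         return_mode="last")
        assert np.allclose(hT, h0 / 2 ** T)

    def test_empty_sequence_rejected(self):
        p = _random_gru(np.random.default_rng(5), 4, 3)
        with pytest.raises(ValueError, match="nonempty"):
            gru_forward(np.empty((0, 4)), p)


class TestFullNetwork:
    def test_output_is_probability_pair(self):
        net = CbamGruNet(n_channels=5, seed=7)
        x = np.random.default_rng(0).standard_normal((5, 59, 114)).astype(np.float32)
        p0, p1 = network_forward(x, net)
        assert 0 < p0 < 1 and 0 < p1 < 1
        assert p0 + p1 == pytest.approx(1.0, abs=1e-6)

    def test_inference_is_deterministic(self):
        net = CbamGruNet(n_channels=5, seed=7)
        x = np.random.default_rng(1).standard_normal((5, 59, 114)).astype(np.float32)
        assert network_forward(x, net) == network_forward(x, net)

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_agrees_with_composed_loop_oracle(self, variant):
        net = CbamGruNet(n_channels=4, variant=variant, seed=11)
        x = np.random.default_rng(2).standard_normal((4, 59, 114)).astype(np.float32)
        prod = network_forward(x, net)
        loop = ref.network_forward_reference(x, net)
        assert max(abs(prod[0] - loop[0]), abs(prod[1] - loop[1])) < 1e-5

    def test_wrong_spatial_size_raises_with_shape_chain(self):
        with pytest.raises(ConfigurationError, match="->"):
            CbamGruNet(n_channels=22, input_hw=(60, 100))

    def test_attention_weights_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(3)
        p = _random_cbam(rng)
        F = rng.standard_normal((8, 3, 5)).astype(np.float32) * 3
        ce, _ = channel_attention(F, p)
        se, _ = spatial_attention(F, p)
        for w in (ce, se.ravel()):
            assert np.all(w > 0) and np.all(w < 1)

    def test_checkpoint_round_trip(self, tmp_path):
        net = CbamGruNet(n_channels=3, seed=5, variant="sam_then_cam")
        x = np.random.default_rng(4).standard_normal((3, 59, 114)).astype(np.float32)
        before = network_forward(x, net)
        path = tmp_path / "ckpt.h5"
        net.save(path, tmp_path / "cfg.yaml")
        loaded = CbamGruNet.load(path)
        assert loaded.variant == "sam_then_cam"
        assert network_forward(x, loaded) == before

    def test_parameter_count_matches_architecture_arithmetic(self):
        # conv: 16*22*25+16 + BN(22*2) + 32*16*9+32 + BN(32) + 64*32*9+64 + BN(64)
        # cbam: 64*16*2 + 16 + 64 + 2 + 1
        # gru1: 3*(320*256 + 256*256) + 2*256 ; fc1: 256*64+64
        # gru2: 3*(64*128 + 128*128) + 2*128  ; fc2: 128*2+2
        net = CbamGruNet(n_channels=22, seed=0)
        expected = (16 * 22 * 25 + 16 + 44) + (32 * 16 * 9 + 32 + 32) + \
            (64 * 32 * 9 + 64 + 64) + (64 * 16 * 2 + 16 + 64 + 2 + 1) + \
            (3 * (320 * 256 + 256 * 256) + 512) + (256 * 64 + 64) + \
            (3 * (64 * 128 + 128 * 128) + 256) + (128 * 2 + 2)
        assert net.n_parameters() == expected
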