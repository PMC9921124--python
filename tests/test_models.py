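"""Architecture contracts and structural properties of the four builders."""

import numpy as np
import pytest

from prostseg.models import (
    FusionWeights,
    ModelConfig,
    build_discriminator,
    build_efficientdet3d,
    build_efficientnet_b0_encoder,
    build_model,
    build_tl_unet,
    build_vnet,
    default_config,
    desk_config,
    effdet3d_level_channels,
    fast_normalized_fusion,
    tl_decoder_filter_plan,
    vnet_filter_plan,
)
from prostseg.models.blocks import ResConvBlock
from prostseg.nn import Tensor

DESK_SHAPE = (32, 32, 8)


@pytest.fixture(scope="module")
def x_desk():
    return Tensor(np.random.default_rng(0).normal(size=(1, 1, *DESK_SHAPE)))


class TestShapeAndRangeContracts:
    @pytest.mark.parametrize("arch", ["vnet", "tl_unet", "effdet3d"])
    def test_output_matches_input_shape_with_sigmoid_range(self, arch, x_desk):
        model = build_model(desk_config(arch, input_shape=DESK_SHAPE, seed=1))
        y = model(x_desk, train=False)
        assert y.shape == x_desk.shape
        assert y.data.min() >= 0.0 and y.data.max() < 1.0
        interior = y.data[y.data > 0]
        assert interior.min() > 0.0  # sigmoid outputs are strictly inside (0,1)

    def test_tl_unet_padding_region_is_exactly_zero(self, x_desk):
        cfg = desk_config("tl_unet", input_shape=DESK_SHAPE, seed=1)
        model = build_tl_unet(cfg)
        y = model(x_desk).data[0, 0]
        pad = (DESK_SHAPE[0] - cfg.crop_size) // 2
        assert pad > 0
        assert np.all(y[:pad] == 0.0) and np.all(y[-pad:] == 0.0)
        assert np.all(y[:, :pad] == 0.0) and np.all(y[:, -pad:] == 0.0)
        assert y[pad:-pad, pad:-pad].min() > 0.0

    def test_discriminator_outputs_one_scalar_per_pair(self):
        cfg = desk_config("gan", input_shape=DESK_SHAPE, seed=0)
        disc = build_discriminator(cfg)
        a = Tensor(np.random.default_rng(1).random((2, 1, *DESK_SHAPE)))
        b = Tensor(np.random.default_rng(2).random((2, 1, *DESK_SHAPE)))
        assert disc(a, b).shape == (2, 1)

    def test_discriminator_sensitive_to_swapped_inputs(self):
        cfg = desk_config("gan", input_shape=DESK_SHAPE, seed=0)
        disc = build_discriminator(cfg)
        a = Tensor(np.random.default_rng(1).random((1, 1, *DESK_SHAPE)))
        b = Tensor(np.random.default_rng(2).random((1, 1, *DESK_SHAPE)))
        assert disc(a, b).item() != pytest.approx(disc(b, a).item(), abs=1e-9)

    def test_vnet_rejects_indivisible_shapes(self):
        cfg = desk_config("vnet", input_shape=(30, 30, 8))
        with pytest.raises(ValueError, match="divisible"):
            build_vnet(cfg)


class TestStructuralPlans:
    def test_vnet_arithmetic_filter_progression(self):
        assert vnet_filter_plan(default_config("vnet")) == [48, 96, 144, 192]

    def test_tl_decoder_filters_at_full_scale(self):
        assert tl_decoder_filter_plan(default_config("tl_unet")) == [360, 288, 216, 144, 72]

    def test_effdet3d_level_channels_at_full_scale(self):
        assert effdet3d_level_channels(default_config("effdet3d")) == [32, 24, 48, 48, 64, 80, 96]

    def test_effdet3d_full_scale_backbone_channels(self):
        cfg = default_config("effdet3d")
        model = build_efficientdet3d(cfg)
        assert model.level_channels == [32, 24, 48, 48, 64, 80, 96]
        assert model.fused_channels == 48

    def test_effdet3d_single_fusion_pass(self):
        cfg = desk_config("effdet3d", input_shape=DESK_SHAPE)
        model = build_efficientdet3d(cfg)
        assert len(model.fusion_nodes) == len(model.level_channels) - 1

    def test_efficientnet_2d_stage_channels(self):
        cfg = default_config("tl_unet")
        enc = build_efficientnet_b0_encoder(cfg, dims="2d")
        # skip-level channels at strides 2..32 from the printed stage plan
        assert enc.level_channels == [16, 24, 40, 112, 320]

    def test_pyramid_levels_halve_in_plane(self, x_desk):
        cfg = desk_config("effdet3d", input_shape=DESK_SHAPE)
        enc = build_efficientnet_b0_encoder(cfg, dims="3d", in_ch=1)
        feats = enc(x_desk)
        sizes = [f.shape[2] for f in feats]
        assert sizes == [DESK_SHAPE[0] // 2 ** (i + 1) for i in range(len(feats))]

    def test_discriminator_first_block_has_no_normalization(self):
        disc = build_discriminator(desk_config("gan", input_shape=DESK_SHAPE))
        assert disc.blocks[0].norm is None
        assert all(b.norm is not None for b in disc.blocks[1:])

    def test_parameter_count_grows_with_base_filters(self):
        small = desk_config("vnet", input_shape=DESK_SHAPE)
        big = desk_config("vnet", input_shape=DESK_SHAPE)
        big.base_filters = small.base_filters * 2
        assert build_vnet(big).n_parameters() > build_vnet(small).n_parameters()


class TestResConvBlock:
    def test_zero_conv_weights_give_residual_identity(self, rng):
        block = ResConvBlock(3, rng=rng, dropout_rate=0.0)
        block.conv.weight.data[:] = 0.0
        block.conv.bias.data[:] = 0.0
        x = Tensor(rng.normal(size=(1, 3, 4, 4, 2)))
        np.testing.assert_allclose(block(x, train=False).data, x.data, atol=1e-12)

    def test_channel_mismatch_rejected(self, rng):
        block = ResConvBlock(4, rng=rng)
        with pytest.raises(ValueError, match="channels"):
            block(Tensor(rng.normal(size=(1, 3, 4, 4, 2))))

    def test_shape_preserved(self, rng):
        block = ResConvBlock(5, rng=rng, dropout_rate=0.5)
        x = Tensor(rng.normal(size=(2, 5, 6, 6, 3)))
        assert block(x, train=True).shape == x.shape


class TestFastNormalizedFusion:
    def test_matches_scalar_loop_recomputation(self, rng):
        inputs = [Tensor(rng.normal(size=(1, 3, 2, 2, 1))) for _ in range(3)]
        w = FusionWeights(3, 3)
        w.omega.data = rng.random((3, 3)) + 0.1
        out = fast_normalized_fusion(inputs, w).data
        expected = np.zeros_like(out)
        for c in range(3):
            denom = w.eps + w.omega.data[:, c].sum()
            for i, t in enumerate(inputs):
                expected[:, c] += max(w.omega.data[i, c], 0.0) / denom * t.data[:, c]
        np.testing.assert_allclose(out, expected, atol=1e-9)

    def test_single_input_large_weight_approaches_identity(self, rng):
        x = Tensor(rng.normal(size=(1, 2, 2, 2, 1)))
        w = FusionWeights(1, 2, eps=1e-6)
        w.omega.data[:] = 1e4
        np.testing.assert_allclose(fast_normalized_fusion([x], w).data, x.data, rtol=1e-9)

    def test_equal_inputs_equal_weights_reproduce_input(self, rng):
        x = Tensor(rng.normal(size=(1, 2, 2, 2, 1)))
        w = FusionWeights(2, 2, eps=1e-8)
        out = fast_normalized_fusion([x, x], w).data
        np.testing.assert_allclose(out, x.data, rtol=1e-6)

    def test_output_in_convex_hull_for_equal_weights(self, rng):
        a = Tensor(rng.normal(size=(1, 2, 3, 3, 1)))
        b = Tensor(rng.normal(size=(1, 2, 3, 3, 1)))
        w = FusionWeights(2, 2, eps=1e-9)
        out = fast_normalized_fusion([a, b], w).data
        lo = np.minimum(a.data, b.data) - 1e-6
        hi = np.maximum(a.data, b.data) + 1e-6
        assert np.all(out >= lo) and np.all(out <= hi)


class TestMBConv:
    def test_expansion_one_skips_expand_conv(self, rng):
        from prostseg.models.blocks import MBConv

        block = MBConv(4, 4, expansion=1.0, rng=rng)
        assert block.expand is None

    def test_expansion_channel_count(self, rng):
        from prostseg.models.blocks import MBConv

        block = MBConv(5, 8, expansion=2.0, rng=rng)
        assert block.expand.conv.weight.shape[0] == 10  # ceil(5 * 2.0)

    def test_forced_all_ones_se_gate_is_identity_of_ungated_path(self, rng):
        from prostseg.models.blocks import MBConv

        block = MBConv(3, 3, expansion=2.0, rng=rng, norm="group")
        x = Tensor(rng.normal(size=(1, 3, 4, 4, 2)))
        y_gated = block(x, train=False)
        # force the excite conv to emit +inf-like logits -> gate ~= 1
        block.se.excite.bias.data[:] = 60.0
        block.se.excite.weight.data[:] = 0.0
        y_open = block(x, train=False)
        assert not np.allclose(y_gated.data, y_open.data)
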