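"""Architecture contracts: shapes, closed forms, variants, accounting."""

import numpy as np
import pytest

from caneseg.autograd import Tensor, no_grad, softmax
from caneseg.model import (
    ASPP,
    BackboneConfig,
    CoordinateAttention,
    InvertedResidual,
    MDSCDeepLabV3Plus,
    MobileNetV2Backbone,
    ModelConfig,
    StripPooling,
    VARIANT_NAMES,
    build_model,
    count_flops,
    count_parameters,
    load_checkpoint,
    make_variant,
    save_checkpoint,
)

RNG = lambda s=0: np.random.default_rng(s)  # noqa: E731


class TestInvertedResidual:
    def test_stride1_block_keeps_shape_and_uses_shortcut(self):
        blk = InvertedResidual(16, 16, t=6, stride=1, rng=RNG())
        assert blk.use_shortcut
        assert blk.hidden_channels == 96  # expansion widens to t * c_in
        x = Tensor(RNG(1).normal(size=(1, 16, 64, 64)).astype(np.float32))
        assert blk(x).shape == (1, 16, 64, 64)

    def test_stride2_block_halves_and_drops_shortcut(self):
        blk = InvertedResidual(24, 32, t=6, stride=2, rng=RNG())
        assert not blk.use_shortcut
        x = Tensor(RNG(1).normal(size=(1, 24, 64, 64)).astype(np.float32))
        assert blk(x).shape == (1, 32, 32, 32)

    def test_stride2_with_dilation_is_an_error(self):
        with pytest.raises(ValueError, match="dilation"):
            InvertedResidual(16, 16, t=6, stride=2, dilation=2)

    def test_shortcut_actually_adds_the_input(self):
        blk = InvertedResidual(8, 8, t=2, stride=1, rng=RNG())
        # zero the projection so the residual branch contributes nothing
        blk.project.layers[0].weight.data[:] = 0.0
        blk.project.layers[1].weight.data[:] = 1.0
        blk.project.layers[1].bias.data[:] = 0.0
        blk.eval()
        x = Tensor(RNG(2).normal(size=(1, 8, 6, 6)).astype(np.float32))
        assert np.allclose(blk(x).data, x.data, atol=1e-5)


class TestBackbone:
    def test_table_default_stage_plan(self):
        cfg = BackboneConfig.improved()
        assert cfg.stages == (
            (1, 16, 1, 1, 1), (6, 24, 2, 2, 1), (6, 32, 3, 2, 1), (6, 64, 4, 2, 1),
            (6, 96, 3, 1, 1), (6, 160, 3, 1, 2), (6, 320, 1, 1, 5),
        )

    @pytest.mark.parametrize("size,low,high", [(512, 128, 32), (256, 64, 16)])
    def test_feature_map_sizes(self, size, low, high):
        bb = MobileNetV2Backbone(rng=RNG())
        bb.eval()
        with no_grad():
            lo, hi = bb(Tensor(np.zeros((1, 3, size, size), np.float32)))
        assert lo.shape == (1, 24, low, low)
        assert hi.shape == (1, 320, high, high)

    def test_original_strides_give_deeper_downsampling(self):
        orig = MobileNetV2Backbone(BackboneConfig.original(), rng=RNG())
        orig.eval()
        with no_grad():
            _, hi = orig(Tensor(np.zeros((1, 3, 256, 256), np.float32)))
        assert hi.shape == (1, 320, 8, 8)  # stride 32, vs 16 for the dilated plan

    def test_output_stride_8_conversion(self):
        cfg = BackboneConfig.improved().with_output_stride(8)
        bb = MobileNetV2Backbone(cfg, rng=RNG())
        bb.eval()
        with no_grad():
            lo, hi = bb(Tensor(np.zeros((1, 3, 256, 256), np.float32)))
        assert hi.shape == (1, 320, 32, 32)
        assert lo.shape == (1, 24, 64, 64)


class TestStripPooling:
    def test_output_shape_equals_input_shape(self):
        sp = StripPooling(6, rng=RNG())
        x = Tensor(RNG(1).normal(size=(2, 6, 9, 13)).astype(np.float32))
        assert sp(x).shape == x.shape

    def test_zeroed_fusion_gives_half_input(self):
        sp = StripPooling(4, rng=RNG())
        sp.fuse.weight.data[:] = 0.0
        sp.fuse.bias.data[:] = 0.0
        x = Tensor(RNG(2).normal(size=(1, 4, 5, 7)).astype(np.float32))
        assert np.allclose(sp(x).data, 0.5 * x.data, atol=1e-6)

    def test_constant_input_pools_to_constant(self):
        x = np.full((1, 3, 6, 8), 2.5, np.float32)
        t = Tensor(x)
        assert np.allclose(t.mean(axis=3, keepdims=True).data, 2.5)
        assert np.allclose(t.mean(axis=2, keepdims=True).data, 2.5)


class TestCoordinateAttention:
    def test_output_shape_and_gate_range(self):
        ca = CoordinateAttention(16, rng=RNG())
        ca.eval()
        x = Tensor(RNG(1).normal(size=(2, 16, 8, 10)).astype(np.float32))
        y = ca(x)
        assert y.shape == x.shape
        # gates are sigmoids, so |output| can never exceed |input|
        assert (np.abs(y.data) <= np.abs(x.data) + 1e-6).all()

    def test_zeroed_direction_convs_give_quarter_input(self):
        ca = CoordinateAttention(8, rng=RNG())
        ca.eval()
        for conv in (ca.attn_h, ca.attn_w):
            conv.weight.data[:] = 0.0
            conv.bias.data[:] = 0.0
        x = Tensor(RNG(2).normal(size=(1, 8, 6, 6)).astype(np.float32))
        assert np.allclose(ca(x).data, 0.25 * x.data, atol=1e-6)


class TestASPP:
    def test_output_channels_and_spatial_size(self):
        aspp = ASPP(320, 256, (4, 8, 12), use_strip_pooling=True, rng=RNG())
        aspp.eval()
        x = Tensor(RNG(1).normal(size=(1, 320, 32, 32)).astype(np.float32))
        with no_grad():
            assert aspp(x).shape == (1, 256, 32, 32)

    def test_branch_count_with_and_without_strip(self):
        with_strip = ASPP(32, 16, (4, 8, 12), True, rng=RNG())
        without = ASPP(32, 16, (6, 12, 18), False, rng=RNG())
        assert with_strip.n_branches == 6
        assert without.n_branches == 5

    def test_all_zero_input_gives_zero_preactivation_conv_branches(self):
        aspp = ASPP(8, 4, (2, 4, 6), False, rng=RNG())
        x = Tensor(np.zeros((1, 8, 16, 16), np.float32))
        # bias-free convolution on zeros is exactly zero
        assert np.abs(aspp.conv1x1.layers[0](x).data).max() == 0.0
        for b in aspp.branches:
            assert np.abs(b.layers[0].layers[0](x).data).max() == 0.0


class TestVariants:
    def test_base_has_all_enhancements_off(self):
        cfg = make_variant("base")
        assert not cfg.use_improved_backbone and not cfg.use_strip_pooling
        assert not cfg.ca_before_decoder and not cfg.ca_after_aspp

    def test_mdsc_has_all_enhancements_on(self):
        cfg = make_variant("MDSC")
        assert cfg.use_improved_backbone and cfg.use_strip_pooling
        assert cfg.ca_before_decoder and cfg.ca_after_aspp
        assert cfg.aspp_dilations == (4, 8, 12)

    def test_all_seven_variants_are_pairwise_distinct(self):
        configs = [make_variant(v) for v in VARIANT_NAMES]
        assert len(set(configs)) == 7

    def test_unknown_variant_error_lists_valid_names(self):
        with pytest.raises(ValueError, match="base"):
            make_variant("XL")

    def test_parameter_ordering_and_band(self):
        counts = {v: count_parameters(build_model(v, seed=0)) for v in ("M", "MDS", "MDSC")}
        assert counts["MDSC"] > counts["MDS"] > counts["M"]
        # soft expectation, logged not asserted: MDSC in the low-single-digit
        # millions, far below an Xception-backbone DeepLabv3+ (~40M+)
        print(f"MDSC parameter count: {counts['MDSC'] / 1e6:.2f}M")
        assert counts["MDSC"] < 41_000_000


class TestForwardContracts:
    @pytest.mark.parametrize("variant", VARIANT_NAMES)
    def test_output_shape_at_256(self, variant):
        model = build_model(variant, input_size=256, seed=0)
        out = model.predict(np.zeros((1, 3, 256, 256), np.float32))
        assert out.scores.shape == (1, 5, 256, 256)
        assert out.labels.shape == (1, 256, 256)
        assert out.labels.min() >= 0 and out.labels.max() < 5

    @pytest.mark.parametrize("size", [512, 768])
    def test_output_shape_scales_with_input(self, size, tiny_model):
        out = tiny_model.predict(np.zeros((1, 3, size, size), np.float32))
        assert out.scores.shape == (1, 5, size, size)

    def test_batched_input(self, tiny_model):
        out = tiny_model.predict(np.zeros((2, 3, 256, 256), np.float32))
        assert out.scores.shape == (2, 5, 256, 256)

    def test_indivisible_size_raises_with_resize_hint(self, tiny_model):
        with pytest.raises(ValueError, match="resize"):
            tiny_model.predict(np.zeros((1, 3, 250, 250), np.float32))

    def test_forward_is_deterministic(self, tiny_model, rng):
        x = rng.random((1, 3, 256, 256), np.float32)
        a = tiny_model.predict(x).scores
        b = tiny_model.predict(x).scores
        assert np.array_equal(a, b)

    def test_same_seed_builds_identical_models(self, rng):
        m1 = build_model("MDS", input_size=256, seed=42)
        m2 = build_model("MDS", input_size=256, seed=42)
        x = rng.random((1, 3, 256, 256), np.float32)
        assert np.array_equal(m1.predict(x).scores, m2.predict(x).scores)

    def test_constant_background_prediction_is_translation_consistent(self, tiny_model):
        """Shifting a constant background image changes nothing, so the
        prediction must be identical; two copies in one batch must agree."""
        x = np.full((1, 3, 256, 256), 0.1, np.float32)
        shifted = np.roll(x, 16, axis=3)
        a = tiny_model.predict(x).labels
        b = tiny_model.predict(shifted).labels
        assert np.array_equal(a, b)
        both = tiny_model.predict(np.concatenate([x, shifted])).labels
        assert np.array_equal(both[0], both[1])


class TestGradientFlow:
    def test_every_parameter_of_mdsc_receives_gradient(self):
        from caneseg.losses_metrics import combined_loss

        model = build_model("MDSC", input_size=256, seed=3)
        rng = np.random.default_rng(3)
        # batch of 2: batch-norm over the global-pool branch is degenerate
        # (and gradient-free) with a single value per channel
        x = Tensor(rng.random((2, 3, 256, 256)).astype(np.float32))
        y = rng.integers(0, 5, (2, 256, 256))
        loss = combined_loss(softmax(model.forward_scores(x)), y)
        loss.backward()
        dead = [n for n, p in model.named_parameters()
                if p.grad is None or np.abs(p.grad).max() == 0.0]
        assert dead == []


class TestAccounting:
    def test_parameter_count_hand_example(self):
        from caneseg.autograd import Conv2d

        class Solo(MDSCDeepLabV3Plus.__mro__[1]):  # a bare Module container
            def __init__(self):
                super().__init__()
                self.conv = Conv2d(3, 32, 3, rng=RNG())

        assert count_parameters(Solo()) == 3 * 3 * 3 * 32

    def test_flops_hand_example_1x1(self):
        from caneseg.autograd import Conv2d

        conv = Conv2d(32, 64, 1, rng=RNG())
        assert conv.flops(64, 64) == 2 * 64 * 64 * 32 * 64

    def test_model_flops_increase_with_resolution(self, tiny_model):
        f256 = count_flops(tiny_model, 256)
        f512 = count_flops(tiny_model, 512)
        assert f512 > f256
        assert f512 == pytest.approx(4 * f256, rel=0.01)  # cost is quadratic in side


class TestConfig:
    def test_yaml_round_trip(self):
        cfg = make_variant("MDS", input_size=256)
        assert ModelConfig.from_yaml(cfg.to_yaml()) == cfg

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(num_classes=1)
        with pytest.raises(ValueError):
            ModelConfig(aspp_dilations=(8, 4, 12))
        with pytest.raises(ValueError):
            ModelConfig(output_stride=4)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, rng):
        model = build_model("MDS", input_size=256, seed=5)
        save_checkpoint(model, tmp_path / "ckpt")
        back = load_checkpoint(tmp_path / "ckpt.npz")
        x = rng.random((1, 3, 256, 256), np.float32)
        assert back.config == model.config
        assert np.array_equal(model.predict(x).scores, back.predict(x).scores)
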