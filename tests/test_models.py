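import numpy as np
import pytest

from lesionview.errors import ShapeError, TransferError, ValidationError
from lesionview.models import (
    CompressionBranch,
    CompressionConfig,
    ConvSpec,
    ModelSpec,
    build_model,
    compress_view,
    count_learnable_parameters,
    forward_classify,
    fuse_views,
    load_checkpoint,
    load_pretrained_backbone,
    save_checkpoint,
)

RNG = np.random.default_rng(7)


class TestConvSpec:
    def test_compression_conv_count(self):
        spec = ConvSpec(98, 32, 7, 3, has_bias=False, dimensionality="2d")
        assert spec.param_count() == 7 * 7 * 98 * 32 == 153_664

    def test_bias_and_3d_counts(self):
        assert ConvSpec(1, 64, 7, 2, True, "3d").param_count() == 343 * 64 + 64
        assert ConvSpec(64, 64, 3, 1, False, "3d").param_count() == 27 * 64 * 64

    def test_invalid_dimensionality(self):
        with pytest.raises(ValidationError):
            ConvSpec(1, 1, 3, 1, False, "4d")


class TestCompressView:
    def test_reference_output_shape(self):
        """(98, 100, 100) input with defaults -> (32, 32, 32)."""
        cfg = CompressionConfig()
        x = RNG.random((98, 100, 100), dtype=np.float32)
        y = compress_view(x, "h", cfg, seed=0)
        assert y.shape == (32, 32, 32)

    def test_w_axis_folding(self):
        cfg = CompressionConfig(per_view_in_channels=20)
        x = RNG.random((26, 20, 23), dtype=np.float32)
        y = compress_view(x, "w", cfg, seed=0)
        # spatial extents from the remaining axes (h=26, l=23)
        assert y.shape == (32, (26 - 7) // 3 + 1, (23 - 7) // 3 + 1)

    def test_zero_input_zero_weights_gives_zero(self):
        cfg = CompressionConfig(per_view_in_channels=10)
        branch = CompressionBranch(cfg, np.random.default_rng(0))
        branch.conv.weight.data[...] = 0.0
        y = compress_view(np.zeros((10, 16, 16), np.float32), "h", cfg, state=branch)
        np.testing.assert_array_equal(y, 0.0)

    def test_output_nonnegative(self):
        cfg = CompressionConfig(per_view_in_channels=12)
        y = compress_view(RNG.normal(size=(12, 20, 20)), "h", cfg, seed=3)
        assert y.min() >= 0.0

    def test_axis_extent_mismatch(self):
        cfg = CompressionConfig(per_view_in_channels=12)
        with pytest.raises(ShapeError):
            compress_view(RNG.random((13, 20, 20)), "h", cfg)

    @pytest.mark.parametrize("extent", list(range(16, 129, 7)) + [100, 128])
    def test_shape_law_over_extents(self, extent):
        """Output extent = floor((S - 7) / 3) + 1 for admissible S."""
        cfg = CompressionConfig(per_view_in_channels=4)
        x = RNG.random((4, extent, extent), dtype=np.float32)
        y = compress_view(x, "h", cfg, seed=0)
        expect = (extent - 7) // 3 + 1
        assert y.shape == (32, expect, expect)


class TestFuseViews:
    def test_concatenation_order_and_recovery(self):
        y1 = RNG.random((32, 5, 5), dtype=np.float32)
        y2 = RNG.random((32, 5, 5), dtype=np.float32)
        fused = fuse_views(y1, y2)
        assert fused.shape == (64, 5, 5)
        np.testing.assert_array_equal(fused[:32], y1)
        np.testing.assert_array_equal(fused[32:], y2)
        assert not np.array_equal(fuse_views(y1, y2), fuse_views(y2, y1))

    def test_spatial_mismatch(self):
        with pytest.raises(ShapeError):
            fuse_views(np.zeros((32, 5, 5)), np.zeros((32, 6, 5)))


class TestParameterAccounting:
    """The published complexity totals, reproduced exactly."""

    @pytest.mark.parametrize("family,depth,total", [
        ("two_view_2d", 18, 11_475_330),
        ("two_view_2d", 34, 21_583_490),
        ("resnet3d", 18, 33_161_986),
        ("resnet3d", 34, 63_471_618),
    ])
    def test_reference_totals(self, family, depth, total):
        model = build_model(ModelSpec(family=family, depth=depth))
        assert count_learnable_parameters(model) == total

    @pytest.mark.parametrize("depth", [18, 34])
    def test_two_view_smaller_than_3d(self, depth):
        two = count_learnable_parameters(build_model(ModelSpec("two_view_2d", depth)))
        three = count_learnable_parameters(build_model(ModelSpec("resnet3d", depth)))
        assert two < three

    def test_invalid_specs(self):
        with pytest.raises(ValidationError):
            ModelSpec(depth=50)
        with pytest.raises(ValidationError):
            ModelSpec(family="densenet")


class TestForward:
    def test_two_view_logits_and_probabilities(self, tiny_spec, tiny_easy_cohort):
        model = build_model(tiny_spec, seed=0)
        logits = model.eval()(tiny_easy_cohort[0].mask.data[None].astype(np.float32))
        assert logits.shape == (1, 2)
        probs = forward_classify(model, tiny_easy_cohort[0])
        assert probs.shape == (2,)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_inference_deterministic(self, tiny_spec, tiny_easy_cohort):
        model = build_model(tiny_spec, seed=1)
        p1 = forward_classify(model, tiny_easy_cohort[0])
        p2 = forward_classify(model, tiny_easy_cohort[0])
        np.testing.assert_array_equal(p1, p2)

    def test_forward_finite_random_weights(self, tiny_spec):
        model = build_model(tiny_spec, seed=2)
        x = RNG.normal(size=(2, 24, 24, 24)).astype(np.float32)
        model.train()
        assert np.isfinite(model(x)).all()
        model.eval()
        assert np.isfinite(model(x)).all()

    def test_resnet3d_contract_full_cube(self):
        model = build_model(ModelSpec(family="resnet3d", depth=18), seed=0)
        logits = model.eval()(np.zeros((1, 1, 100, 100, 100), dtype=np.float32))
        assert logits.shape == (1, 2)

    def test_build_deterministic_under_seed(self, tiny_spec):
        a = build_model(tiny_spec, seed=9).state_dict()
        b = build_model(tiny_spec, seed=9).state_dict()
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_bad_input_mode(self, tiny_spec, tiny_easy_cohort):
        model = build_model(tiny_spec, seed=0)
        with pytest.raises(ValidationError):
            forward_classify(model, tiny_easy_cohort[0], input_mode="t1")


def _synthetic_backbone_source(depth, rng, with_stem_and_fc=True):
    """A synthetic stand-in for a pretrained 2D residual-network archive:
    random arrays under the conventional names/shapes."""
    donor = build_model(ModelSpec("two_view_2d", depth))
    source = {}
    for name, p in donor.backbone.named_parameters():
        if name.startswith("fc."):
            continue
        source[name] = rng.normal(size=p.data.shape).astype(np.float32)
    for name, b in donor.backbone.named_buffers():
        source[name] = rng.random(b.shape).astype(np.float32) + 0.5
    if with_stem_and_fc:
        source["conv1.weight"] = rng.normal(size=(64, 3, 7, 7)).astype(np.float32)
        source["bn1.weight"] = np.ones(64, np.float32)
        source["fc.weight"] = rng.normal(size=(1000, 512)).astype(np.float32)
    return source


class TestPretrainedTransfer:
    def test_copy_semantics(self, tiny_spec):
        rng = np.random.default_rng(0)
        source = _synthetic_backbone_source(18, rng)
        model = build_model(tiny_spec, seed=3)
        before_branch = model.compress_h.conv.weight.data.copy()
        before_fc = model.backbone.fc.weight.data.copy()
        load_pretrained_backbone(model, source)
        got = dict(model.backbone.named_parameters())
        np.testing.assert_array_equal(got["layer1.0.conv1.weight"].data,
                                      source["layer1.0.conv1.weight"])
        np.testing.assert_array_equal(
            dict(model.backbone.named_buffers())["layer3.1.bn2.running_mean"],
            source["layer3.1.bn2.running_mean"])
        # compression branches and output layer stay freshly initialised
        np.testing.assert_array_equal(model.compress_h.conv.weight.data, before_branch)
        np.testing.assert_array_equal(model.backbone.fc.weight.data, before_fc)

    def test_depth_mismatch_rejected(self, tiny_spec):
        source = _synthetic_backbone_source(34, np.random.default_rng(1))
        model = build_model(tiny_spec, seed=0)
        with pytest.raises(TransferError):
            load_pretrained_backbone(model, source)

    def test_missing_array_rejected(self, tiny_spec):
        source = _synthetic_backbone_source(18, np.random.default_rng(1))
        del source["layer2.0.conv1.weight"]
        with pytest.raises(TransferError):
            load_pretrained_backbone(build_model(tiny_spec), source)

    def test_3d_family_rejected(self):
        model = build_model(ModelSpec(family="resnet3d", depth=18))
        with pytest.raises(ValidationError):
            load_pretrained_backbone(model, {})

    def test_npz_round_trip(self, tiny_spec, tmp_path):
        source = _synthetic_backbone_source(18, np.random.default_rng(2))
        np.savez(tmp_path / "weights.npz", **source)
        model = load_pretrained_backbone(build_model(tiny_spec), tmp_path / "weights.npz")
        np.testing.assert_array_equal(
            dict(model.backbone.named_parameters())["layer4.1.conv2.weight"].data,
            source["layer4.1.conv2.weight"])


class TestCheckpoint:
    def test_round_trip(self, tiny_spec, tmp_path):
        model = build_model(tiny_spec, seed=5)
        path = save_checkpoint(model, tiny_spec, tmp_path / "ckpt.npz")
        loaded, spec = load_checkpoint(path)
        assert spec == tiny_spec
        for (ka, a), (kb, b) in zip(model.named_parameters(), loaded.named_parameters()):
            assert ka == kb
            np.testing.assert_array_equal(a.data, b.data)
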