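"""Fusion-primitive contracts and model-builder tests."""

import time

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmfusion.models import (ArchitectureConfig, FusionModelSpec,
                             build_early_fusion_input, build_model, late_fuse,
                             model_fuse_features, preprocess_image,
                             standard_specs, transfer_pretrained_weights)
from mmfusion.nn import densenet121_features

ARCH = ArchitectureConfig(conv_channels=(4, 8), wide_filters=8, fc_dims=(16, 8))


class TestEarlyFusionInput:
    def test_full_scale_shape_contract(self):
        out = build_early_fusion_input(np.zeros((224, 224, 1)),
                                       np.zeros((200, 224)))
        assert out.shape == (424, 224, 1)

    def test_all_zero_blocks_give_all_zero_output(self):
        out = build_early_fusion_input(np.zeros((224, 224, 1)),
                                       np.zeros((200, 224)))
        assert not out.any()

    def test_row_layout_image_on_top_text_below(self):
        rng = np.random.default_rng(0)
        img = rng.random((224, 224))
        txt = rng.random((200, 224))
        out = build_early_fusion_input(img, txt)
        assert np.array_equal(out[223, :, 0], img[223])
        assert np.array_equal(out[224, :, 0], txt[0])
        assert np.array_equal(out[:224, :, 0], img)
        assert np.array_equal(out[224:, :, 0], txt)

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError, match="width mismatch"):
            build_early_fusion_input(np.zeros((32, 32, 1)), np.zeros((24, 16)))

    def test_batched_input_and_channel_replication(self):
        rng = np.random.default_rng(1)
        img = rng.random((5, 16, 16, 3))
        txt = rng.random((5, 8, 16))
        out = build_early_fusion_input(img, txt)
        assert out.shape == (5, 24, 16, 3)
        for c in range(3):  # text block replicated across channels
            assert np.array_equal(out[:, 16:, :, c], txt)

    def test_generic_row_additivity(self):
        out = build_early_fusion_input(np.zeros((32, 32, 1)), np.zeros((24, 32)))
        assert out.shape == (56, 32, 1)


class TestLateFuse:
    def test_hand_computed_mean(self):
        assert np.allclose(late_fuse([0.8, 0.2], [0.6, 0.4]), [0.7, 0.3])

    def test_opposite_certainty_averages_to_uniform(self):
        assert np.allclose(late_fuse([1.0, 0.0], [0.0, 1.0]), [0.5, 0.5])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
           st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6))
    def test_commutative_idempotent_and_on_simplex(self, a, b):
        k = min(len(a), len(b))
        p = np.array(a[:k]) / np.sum(a[:k])
        q = np.array(b[:k]) / np.sum(b[:k])
        assert np.allclose(late_fuse(p, q), late_fuse(q, p))
        assert np.allclose(late_fuse(p, p), p)
        assert late_fuse(p, q).sum() == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            late_fuse([0.5, 0.5], [0.2, 0.3, 0.5])

    def test_sigmoid_mode_skips_simplex_check(self):
        out = late_fuse([0.9, 0.9, 0.1], [0.7, 0.5, 0.3], mode="sigmoid_bce")
        assert np.allclose(out, [0.8, 0.7, 0.2])


class TestModelFuseFeatures:
    def test_length_additivity_and_order(self):
        a, b = np.arange(128.0), np.arange(64.0) + 1000
        out = model_fuse_features(a, b)
        assert out.shape == (192,)
        assert np.array_equal(out[:128], a)
        assert np.array_equal(out[128:], b)

    def test_empty_or_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            model_fuse_features(np.array([]), np.ones(3))
        with pytest.raises(ValueError):
            model_fuse_features(np.array([np.nan]), np.ones(3))


class TestPreprocessImage:
    def test_resize_then_center_crop(self):
        out = preprocess_image(np.random.default_rng(0).random((512, 512)))
        assert out.shape == (224, 224)

    def test_identity_when_already_target_and_resize_disabled(self):
        img = np.random.default_rng(1).random((224, 224))
        out = preprocess_image(img, resize=None)
        assert np.array_equal(out, img)

    def test_constant_input_stays_constant(self):
        out = preprocess_image(np.full((300, 300), 0.37))
        assert np.allclose(out, 0.37, atol=1e-6)

    def test_rgb_to_grayscale(self):
        img = np.ones((64, 64, 3)) * np.array([0.2, 0.4, 0.6])
        out = preprocess_image(img, grayscale=True)
        assert out.shape == (224, 224)
        assert np.allclose(out, 0.2 * 0.299 + 0.4 * 0.587 + 0.6 * 0.114, atol=1e-5)


class TestSpecValidation:
    def test_naming_convention(self):
        assert FusionModelSpec("early_fusion", "square", "square").name == \
            "Early Fusion (Square)"
        assert FusionModelSpec("early_fusion", "wide", "none").name == \
            "Early Fusion (Wide)"
        assert FusionModelSpec("late_fusion", "wide", "square",
                               pretrained=True).name == \
            "Late Fusion (Wide, Square, Pretrained)"
        assert FusionModelSpec("image_only", "none", "square").name == \
            "Image Only (Square)"

    @pytest.mark.parametrize("args", [
        ("image_only", "wide", "square"),
        ("image_only", "none", "none"),
        ("text_only", "none", "none"),
        ("early_fusion", "wide", "square"),
        ("late_fusion", "wide", "none"),
        ("model_fusion", "none", "square"),
    ])
    def test_incompatible_kernel_combinations_rejected(self, args):
        with pytest.raises(ValueError):
            FusionModelSpec(*args)

    def test_pretraining_limited_to_separable_fusion(self):
        with pytest.raises(ValueError):
            FusionModelSpec("early_fusion", "square", "square", pretrained=True)

    def test_standard_specs_cover_all_eight_variants(self):
        specs = standard_specs("softmax_cce", 2)
        assert len(specs) == 8
        assert len({s.name for s in specs}) == 8


class TestBuildModel:
    def test_tiny_backbone_instantiates_quickly(self):
        spec = FusionModelSpec("early_fusion", "square", "square")
        build_model(spec, image_size=32, text_len=24, embed_dim=32, arch=ARCH,
                    seed=0)  # warm the JIT kernel cache once
        t0 = time.time()
        build_model(spec, image_size=32, text_len=24, embed_dim=32, arch=ARCH,
                    seed=0)
        assert time.time() - t0 < 1.0

    def test_early_fusion_accepts_full_scale_input(self):
        m = build_model(FusionModelSpec("early_fusion", "square", "square"),
                        image_size=224, text_len=200, embed_dim=224, arch=ARCH,
                        seed=0)
        p = m.predict_proba(np.zeros((1, 224, 224, 1), dtype=np.float32),
                            np.zeros((1, 200, 224), dtype=np.float32))
        assert p.shape == (1, 2)

    def test_wide_kernels_span_embedding_dimension(self):
        m = build_model(FusionModelSpec("text_only", "wide", "none"),
                        image_size=32, text_len=24, embed_dim=32, arch=ARCH,
                        seed=0)
        convs = [b.layers[0] for b in m.features.layers[0].banks]
        assert sorted(c.kh for c in convs) == [2, 3]
        assert all(c.kw == 32 for c in convs)

    def test_sigmoid_head_outputs_lie_in_unit_interval(self):
        m = build_model(FusionModelSpec("model_fusion", "wide", "square",
                                        head="sigmoid_bce", n_classes=11),
                        image_size=32, text_len=24, embed_dim=32, arch=ARCH,
                        seed=0)
        rng = np.random.default_rng(0)
        p = m.predict_proba(rng.random((4, 32, 32, 1)), rng.random((4, 24, 32)))
        assert p.shape == (4, 11)
        assert np.all((p >= 0) & (p <= 1))

    def test_softmax_head_outputs_sum_to_one(self):
        m = build_model(FusionModelSpec("late_fusion", "wide", "square"),
                        image_size=32, text_len=24, embed_dim=32, arch=ARCH,
                        seed=0)
        rng = np.random.default_rng(0)
        p = m.predict_proba(rng.random((3, 32, 32, 1)), rng.random((3, 24, 32)))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)


class TestPretrainedTransfer:
    def _models(self, seed=0):
        kw = dict(image_size=16, text_len=8, embed_dim=16, arch=ARCH)
        img = build_model(FusionModelSpec("image_only", "none", "square"),
                          seed=seed, **kw)
        txt = build_model(FusionModelSpec("text_only", "wide", "none"),
                          seed=seed + 1, **kw)
        fus = build_model(FusionModelSpec("model_fusion", "wide", "square",
                                          pretrained=True), seed=seed + 2, **kw)
        return img, txt, fus

    def test_branch_parameters_copied_exactly_heads_fresh(self):
        img, txt, fus = self._models()
        head_before = [p.value.copy() for p in fus.head.params]
        transfer_pretrained_weights(img, txt, fus)
        for a, b in zip(img.features.params, fus.image_features.params):
            assert np.array_equal(a.value, b.value)
        for a, b in zip(txt.features.params, fus.text_features.params):
            assert np.array_equal(a.value, b.value)
        for before, p in zip(head_before, fus.head.params):
            assert np.array_equal(before, p.value)  # untouched by transfer
        # heads differ from both unimodal heads (independent initialisation)
        assert not np.array_equal(fus.head.params[0].value,
                                  img.head.params[0].value)

    def test_transfer_into_early_fusion_rejected(self):
        img, txt, _ = self._models()
        early = build_model(FusionModelSpec("early_fusion", "square", "square"),
                            image_size=16, text_len=8, embed_dim=16, arch=ARCH,
                            seed=9)
        with pytest.raises(ValueError, match="joint branch"):
            transfer_pretrained_weights(img, txt, early)

    def test_topology_mismatch_names_offending_parameter(self):
        img, txt, fus = self._models()
        other_arch = ArchitectureConfig(conv_channels=(4, 16), wide_filters=8,
                                        fc_dims=(16, 8))
        img2 = build_model(FusionModelSpec("image_only", "none", "square"),
                           image_size=16, text_len=8, embed_dim=16,
                           arch=other_arch, seed=0)
        with pytest.raises(ValueError, match="topology mismatch"):
            transfer_pretrained_weights(img2, txt, fus)

    def test_late_fusion_transfer_copies_both_unimodal_extractors(self):
        img, txt, _ = self._models()
        late = build_model(FusionModelSpec("late_fusion", "wide", "square",
                                           pretrained=True),
                           image_size=16, text_len=8, embed_dim=16, arch=ARCH,
                           seed=4)
        transfer_pretrained_weights(img, txt, late)
        for a, b in zip(img.features.params, late.image_model.features.params):
            assert np.array_equal(a.value, b.value)


@pytest.mark.parametrize("spec", [
    FusionModelSpec("model_fusion", "wide", "square"),
    FusionModelSpec("late_fusion", "wide", "square"),
])
def test_checkpoint_roundtrip_preserves_predictions(tmp_path, spec):
    from mmfusion.models import load_model, save_model
    m = build_model(spec, image_size=16, text_len=8, embed_dim=16, arch=ARCH,
                    seed=3)
    rng = np.random.default_rng(0)
    xi, xt = rng.random((3, 16, 16, 1)), rng.random((3, 8, 16))
    save_model(m, str(tmp_path / "ckpt"))
    back = load_model(str(tmp_path / "ckpt"))
    assert back.spec == m.spec
    assert np.allclose(back.predict_proba(xi, xt), m.predict_proba(xi, xt))


def test_densenet121_feature_extractor_topology():
    """224x224x1 input must produce the canonical 7x7x1024 feature maps."""
    net = densenet121_features(1, np.random.default_rng(0))
    out = net.forward(np.zeros((1, 224, 224, 1), dtype=np.float32))
    assert out.shape == (1, 7, 7, 1024)
    # 6+12+24+16 bottlenecked units, each with two conv layers
    n_convs = sum(1 for p in net.params if p.name == "conv_w")
    assert n_convs == 1 + 2 * 58 + 3  # stem + units + transitions
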