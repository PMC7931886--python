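"""Partitioning, splitting, class weights, training and experiment plumbing."""

import numpy as np
import pandas as pd
import pytest

from mmfusion import GeneratorConfig, generate_dataset
from mmfusion.models import ArchitectureConfig, FusionModelSpec
from mmfusion.protocol import (ExperimentResult, TrainConfig,
                               compute_class_weights, make_split,
                               partition_dataset, prepare_split, run_experiment,
                               train_model, evaluate_model)

TINY_ARCH = ArchitectureConfig(conv_channels=(4, 8), wide_filters=8,
                               fc_dims=(16, 8))


def _patients(samples):
    return {s.patient_id for s in samples}


class TestPartitioning:
    def test_n1_returns_whole_dataset(self, small_binary_dataset):
        parts = partition_dataset(small_binary_dataset, 1, seed=0)
        assert len(parts) == 1
        assert _patients(parts[0]) == _patients(small_binary_dataset)

    @pytest.mark.parametrize("n_patients,n,sizes", [
        (100, 4, {25}),
        (101, 4, {25, 26}),
        (10, 3, {3, 4}),
    ])
    def test_partition_sizes_near_equal(self, n_patients, n, sizes):
        cfg = GeneratorConfig(n_patients=n_patients, image_size=8, seed=0,
                              images_per_patient=(1, 1))
        samples = generate_dataset(cfg)
        parts = partition_dataset(samples, n, seed=1)
        observed = {len(_patients(p)) for p in parts}
        assert observed <= sizes

    def test_partitions_are_patient_disjoint_and_complete(self, small_binary_dataset):
        parts = partition_dataset(small_binary_dataset, 4, seed=3)
        seen = set()
        for p in parts:
            pats = _patients(p)
            assert not (pats & seen)
            seen |= pats
        assert seen == _patients(small_binary_dataset)

    def test_more_partitions_than_patients_rejected(self):
        cfg = GeneratorConfig(n_patients=3, image_size=8, seed=0)
        with pytest.raises(ValueError):
            partition_dataset(generate_dataset(cfg), 5, seed=0)


class TestMakeSplit:
    def test_ten_single_image_patients_split_8_1_1(self):
        cfg = GeneratorConfig(n_patients=10, images_per_patient=(1, 1),
                              image_size=8, seed=0)
        plan = make_split(generate_dataset(cfg), seed=0)
        assert (len(plan.train), len(plan.val), len(plan.test)) == (8, 1, 1)

    def test_all_records_of_a_patient_stay_together(self, small_binary_dataset):
        plan = make_split(small_binary_dataset, seed=5)
        for s in small_binary_dataset:
            memberships = [s.patient_id in grp
                           for grp in (plan.train, plan.val, plan.test)]
            assert sum(memberships) == 1

    def test_sample_fractions_within_one_patient(self, small_binary_dataset):
        plan = make_split(small_binary_dataset, seed=2)
        counts = {k: 0 for k in ("train", "val", "test")}
        for s in small_binary_dataset:
            for k, grp in (("train", plan.train), ("val", plan.val),
                           ("test", plan.test)):
                if s.patient_id in grp:
                    counts[k] += len(s.images)
        total = sum(counts.values())
        max_images = max(len(s.images) for s in small_binary_dataset)
        assert abs(counts["train"] - 0.8 * total) <= max_images
        assert abs(counts["val"] - 0.1 * total) <= max_images
        assert abs(counts["test"] - 0.1 * total) <= max_images

    def test_same_seed_same_assignment(self, small_binary_dataset):
        a = make_split(small_binary_dataset, seed=11)
        b = make_split(small_binary_dataset, seed=11)
        assert (a.train, a.val, a.test) == (b.train, b.val, b.test)

    def test_too_few_patients_rejected(self):
        cfg = GeneratorConfig(n_patients=2, image_size=8, seed=0)
        with pytest.raises(ValueError):
            make_split(generate_dataset(cfg), seed=0)


class TestClassWeights:
    def test_balanced_binary_gives_unit_weights(self):
        y = np.array([[1, 0], [0, 1]] * 25)
        assert np.allclose(compute_class_weights(y), [1.0, 1.0])

    def test_inverse_frequency_formula(self):
        # 100 samples, 25 positives in one class of two -> 100/(2*25) = 2
        y = np.zeros((100, 2), dtype=int)
        y[:25, 0] = 1
        y[:, 1] = 1  # all-positive class -> 100/(2*100) = 0.5
        w = compute_class_weights(y)
        assert w[0] == pytest.approx(2.0)
        assert w[1] == pytest.approx(0.5)

    def test_zero_positive_class_capped_with_warning(self):
        y = np.zeros((40, 2), dtype=int)
        y[:, 0] = 1
        with pytest.warns(UserWarning, match="no positive"):
            w = compute_class_weights(y, max_weight=10.0)
        assert w[1] == 10.0


@pytest.fixture(scope="module")
def prepared():
    cfg = GeneratorConfig(n_patients=80, image_size=16, seed=13,
                          signal_overlap=0.0, image_signal=0.8, text_signal=0.8)
    samples = generate_dataset(cfg)
    tc = TrainConfig.desk_scale(epochs=5, seed=1, embed_dim=16, text_len=16)
    tc.arch = TINY_ARCH
    parts = partition_dataset(samples, 1, seed=0)
    plan = make_split(parts[0], seed=0)
    return prepare_split(parts[0], plan, tc, embed_seed=0), tc


class TestTraining:
    def test_loss_decreases_on_learnable_task(self, prepared):
        prep, tc = prepared
        spec = FusionModelSpec("early_fusion", "square", "square")
        model, hist = train_model(spec, prep, tc)
        assert hist["train_loss"][-1] < hist["train_loss"][0]
        metrics = evaluate_model(model, prep)
        assert 0.0 <= metrics["auc"] <= 1.0

    def test_deterministic_history_without_flips(self, prepared):
        prep, tc = prepared
        from dataclasses import replace
        tc0 = replace(tc, hflip_prob=0.0, epochs=3)
        spec = FusionModelSpec("image_only", "none", "square")
        _, h1 = train_model(spec, prep, tc0)
        _, h2 = train_model(spec, prep, tc0)
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_loss"] == h2["val_loss"]

    def test_late_fusion_trains_both_branches(self, prepared):
        prep, tc = prepared
        from dataclasses import replace
        spec = FusionModelSpec("late_fusion", "wide", "square")
        model, hist = train_model(spec, prep, replace(tc, epochs=2))
        assert set(hist) == {"image", "text"}
        p = model.predict_proba(prep.X_img["test"], prep.X_txt["test"])
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-5)

    def test_pretrained_spec_requires_unimodal_models(self, prepared):
        prep, tc = prepared
        spec = FusionModelSpec("model_fusion", "wide", "square", pretrained=True)
        with pytest.raises(ValueError, match="unimodal"):
            train_model(spec, prep, tc)


class TestStudyProperties:
    def test_small_training_completes_within_a_minute(self):
        import time
        cfg = GeneratorConfig(n_patients=130, images_per_patient=(1, 2),
                              image_size=32, seed=23)
        samples = generate_dataset(cfg)  # ~200 patient-image records
        tc = TrainConfig.desk_scale(epochs=5, seed=0)
        parts = partition_dataset(samples, 1, seed=0)
        plan = make_split(parts[0], seed=0)
        prep = prepare_split(parts[0], plan, tc, embed_seed=0)
        spec = FusionModelSpec("early_fusion", "square", "square")
        t0 = time.time()
        train_model(spec, prep, tc)
        assert time.time() - t0 < 60.0

    def test_text_dominant_signal_makes_text_model_win_at_every_n(self):
        """With text_signal=0.9 and image_signal=0.2, the wide-kernel text
        model outperforms the image model at every data budget."""
        cfg = GeneratorConfig(n_patients=1600, images_per_patient=(1, 1),
                              image_size=16, seed=29, text_signal=0.9,
                              image_signal=0.2, signal_overlap=0.0)
        samples = generate_dataset(cfg)
        tc = TrainConfig.desk_scale(epochs=10, seed=0, embed_dim=16)
        specs = [FusionModelSpec("text_only", "wide", "none"),
                 FusionModelSpec("image_only", "none", "square")]
        res = run_experiment(samples, specs, ns=(1, 4), repeats=1, config=tc,
                             base_seed=1)
        agg = res.aggregate().set_index(["model", "n"])
        for n in (1, 4):
            assert agg.loc[("Text Only (Wide)", n), "auc"] > \
                agg.loc[("Image Only (Square)", n), "auc"]


class TestRunExperiment:
    def test_factorial_bookkeeping(self):
        cfg = GeneratorConfig(n_patients=400, images_per_patient=(1, 1),
                              image_size=8, imbalance=1.0, seed=19)
        samples = generate_dataset(cfg)
        tc = TrainConfig.desk_scale(epochs=1, seed=0, embed_dim=8)
        tc.arch = TINY_ARCH
        specs = [FusionModelSpec("text_only", "wide", "none")]
        res = run_experiment(samples, specs, ns=(1, 2, 4),
                             repeats=1, config=tc, base_seed=0)
        # 1 + 2 + 4 partition-level runs
        assert len(res.runs) == 7
        assert sorted(res.runs["n"].unique()) == [1, 2, 4]
        agg = res.aggregate()
        assert len(agg) == 3  # one aggregated row per n

    def test_two_repeats_aggregate_to_single_row(self, small_binary_dataset):
        tc = TrainConfig.desk_scale(epochs=1, seed=0)
        tc.arch = TINY_ARCH
        specs = [FusionModelSpec("text_only", "wide", "none")]
        res = run_experiment(small_binary_dataset, specs, ns=(1,), repeats=2,
                             config=tc, base_seed=3)
        assert len(res.runs) == 2
        assert len(res.aggregate()) == 1

    def test_aggregation_is_mean_of_partition_means(self):
        runs = pd.DataFrame([
            # repeat 0: partitions 0.6, 0.8 -> mean 0.7; repeat 1: 0.9 -> 0.9
            dict(model="m", n=2, repeat=0, partition=0, auc=0.6,
                 precision=0.5, recall=0.5, f1=0.5),
            dict(model="m", n=2, repeat=0, partition=1, auc=0.8,
                 precision=0.5, recall=0.5, f1=0.5),
            dict(model="m", n=2, repeat=1, partition=0, auc=0.9,
                 precision=0.5, recall=0.5, f1=0.5),
        ])
        agg = ExperimentResult(runs).aggregate()
        assert agg.loc[0, "auc"] == pytest.approx((0.7 + 0.9) / 2)
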