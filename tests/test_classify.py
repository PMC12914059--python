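"""Classification: crop assembly, residual network, linear baseline,
cross-validation, composition estimation, agreement fits."""

import numpy as np
import pandas as pd
import pytest

from deepuv import classify, pipeline


@pytest.fixture(scope="module")
def static_dataset():
    crops, labels, table = pipeline.generate_static_dataset(
        n_scenes=10, cells_per_scene=12, seed=1)
    return crops, labels, table


@pytest.fixture(scope="module")
def feature_problem(static_dataset):
    _, labels, table = static_dataset
    return pipeline.features_matrix(table), labels


class TestBuildCrops:
    def test_channel_count_by_task(self, static_dataset):
        crops, *_ = static_dataset
        x1 = classify.build_crops(crops[:4])
        assert x1.shape[:2] == (4, 1)
        dyn = [np.zeros((3,) + crops[0].image.shape) for _ in range(4)]
        x4 = classify.build_crops(crops[:4], dyn)
        assert x4.shape[:2] == (4, 4)

    def test_exterior_zero_in_every_channel(self, static_dataset):
        crops, *_ = static_dataset
        x = classify.build_crops(crops[:2])
        outside = ~np.stack([c.mask for c in crops[:2]])[:, None]
        assert np.all(x[outside] == 0)

    def test_crop_order_preserved(self, static_dataset):
        crops, *_ = static_dataset
        x = classify.build_crops(crops[:5])
        for i, c in enumerate(crops[:5]):
            assert np.array_equal(x[i, 0], c.image)

    def test_mismatched_dynamic_channels_rejected(self, static_dataset):
        crops, *_ = static_dataset
        with pytest.raises(ValueError):
            classify.build_crops(crops[:3], [np.zeros((2, 8, 8))] * 3)


class TestTrainConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            classify.TrainConfig(split=1.2)
        with pytest.raises(ValueError):
            classify.TrainConfig(folds=1)


class TestResidualNet:
    @pytest.fixture(scope="class")
    def trained(self, static_dataset):
        crops, labels, _ = static_dataset
        X = classify.build_crops(crops)
        cfg = classify.TrainConfig(epochs=12, seed=0)
        model, report, split = classify.train_cnn(X, labels, cfg)
        return X, labels, model, report, split

    def test_separable_classes_learned(self, trained):
        _, _, _, report, _ = trained
        assert report.accuracy >= 0.85

    def test_confusion_rows_sum_to_heldout_counts(self, trained):
        _, labels, _, report, (_, test_idx) = trained
        for i, c in enumerate(report.classes):
            assert report.confusion[i].sum() == np.sum(labels[test_idx] == c)
        assert report.accuracy == pytest.approx(
            np.trace(report.confusion) / report.confusion.sum())

    def test_split_deterministic_under_seed(self, static_dataset):
        crops, labels, _ = static_dataset
        from sklearn.model_selection import train_test_split

        idx = np.arange(len(labels))
        s1 = train_test_split(idx, train_size=0.8, stratify=labels, random_state=7)
        s2 = train_test_split(idx, train_size=0.8, stratify=labels, random_state=7)
        assert np.array_equal(s1[0], s2[0]) and np.array_equal(s1[1], s2[1])

    def test_shuffled_labels_fall_to_chance(self, static_dataset):
        crops, labels, _ = static_dataset
        X = classify.build_crops(crops)
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(labels)
        _, report, _ = classify.train_cnn(
            X, shuffled, classify.TrainConfig(epochs=6, seed=0))
        assert report.accuracy < 0.6

    def test_agrees_with_baseline_within_ten_points(self, trained, feature_problem):
        # wiring guard: on cleanly separated synthetic cells the conv-net
        # and the linear baseline must land in the same regime
        _, _, _, report, _ = trained
        X, labels = feature_problem
        pooled, _ = classify.cross_validate(
            classify.LinearBaselineClassifier(), X, labels, folds=5, seed=0)
        assert abs(report.accuracy - pooled.accuracy) <= 0.10


class TestLinearBaseline:
    def test_separable_features_classified(self, feature_problem):
        X, labels = feature_problem
        pooled, _ = classify.cross_validate(
            classify.LinearBaselineClassifier(), X, labels, folds=5, seed=0)
        assert pooled.accuracy >= 0.9

    def test_shuffled_labels_near_chance(self, feature_problem, rng):
        X, labels = feature_problem
        pooled, _ = classify.cross_validate(
            classify.LinearBaselineClassifier(), X, rng.permutation(labels),
            folds=5, seed=0)
        assert pooled.accuracy < 0.55

    def test_constant_feature_leaves_predictions_unchanged(self, feature_problem):
        X, labels = feature_problem
        m1 = classify.LinearBaselineClassifier().fit(X, labels)
        X2 = X.copy()
        X2["constant"] = 3.0
        m2 = classify.LinearBaselineClassifier().fit(X2, labels)
        assert np.array_equal(m1.predict(X), m2.predict(X2))


class TestCrossValidate:
    def test_folds_partition_index_set(self, feature_problem):
        from sklearn.model_selection import StratifiedKFold

        X, labels = feature_problem
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        seen = np.concatenate([test for _, test in skf.split(np.asarray(X), labels)])
        assert np.array_equal(np.sort(seen), np.arange(len(labels)))

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.raises(ValueError):
            classify.cross_validate(classify.LinearBaselineClassifier(),
                                    X, np.zeros(20), folds=5)

    def test_pooled_confusion_counts_every_cell(self, feature_problem):
        X, labels = feature_problem
        pooled, folds = classify.cross_validate(
            classify.LinearBaselineClassifier(), X, labels, folds=5, seed=0)
        assert pooled.confusion.sum() == len(labels)
        assert sum(f.confusion.sum() for f in folds) == len(labels)


class TestComposition:
    class _Fixed:
        def __init__(self, preds):
            self.preds = np.asarray(preds)

        def predict(self, X):
            return self.preds[: len(np.atleast_2d(X))]

    def test_all_dead_sample_zero_viability(self):
        model = self._Fixed(["dead"] * 5)
        v, a = classify.predict_composition(model, np.zeros((5, 2)))
        assert v == 0.0 and np.isnan(a)

    def test_all_activated_live_sample(self):
        model = self._Fixed(["activated"] * 4)
        v, a = classify.predict_composition(model, np.zeros((4, 2)))
        assert v == 100.0 and a == 100.0

    def test_mixed_sample_percentages(self):
        model = self._Fixed(["dead", "activated", "activated", "quiescent"])
        v, a = classify.predict_composition(model, np.zeros((4, 2)))
        assert v == 75.0
        assert a == pytest.approx(100 * 2 / 3)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            classify.predict_composition(self._Fixed([]), np.zeros((0, 2)))


class TestAgreementFit:
    def test_identity_fit(self):
        s, i, r2 = classify.agreement_fit([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (s, i, r2) == (pytest.approx(1), pytest.approx(0), pytest.approx(1))

    def test_doubling_fit(self):
        s, _, r2 = classify.agreement_fit([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert s == pytest.approx(2.0) and r2 == pytest.approx(1.0)

    def test_noisy_pairs_match_closed_form_r2(self, rng):
        ref = rng.uniform(0, 100, 30)
        pred = ref + rng.normal(0, 5, 30)
        _, _, r2 = classify.agreement_fit(pred, ref)
        expected = np.corrcoef(ref, pred)[0, 1] ** 2
        assert r2 == pytest.approx(expected)

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(ValueError):
            classify.agreement_fit([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
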