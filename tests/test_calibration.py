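import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from remsef.calibration import (ROCResult, calibrate_thresholds,
                                crossvalidate, optimal_operating_point,
                                roc_curve)
from remsef.detector import detect_recording
from remsef.features import EpochFeatures
from remsef.synth import labelled_feature_sample


def concordance_auc(values, labels):
    """Brute-force pairwise concordance probability, ties counted half."""
    pos = [v for v, l in zip(values, labels) if l]
    neg = [v for v, l in zip(values, labels) if not l]
    score = 0.0
    for p in pos:
        for q in neg:
            score += 1.0 if p > q else (0.5 if p == q else 0.0)
    return score / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        roc = roc_curve([1, 2, 5, 6], [False, False, True, True])
        assert roc.auc == 1.0
        assert roc.optimal_distance == 0.0

    def test_partial_overlap(self):
        # REM {3,5} vs non-REM {1,4}: 3 of 4 pairs concordant
        roc = roc_curve([3, 5, 1, 4], [True, True, False, False])
        assert roc.auc == 0.75

    def test_degenerate_identical_values(self):
        roc = roc_curve([2.0] * 6, [True, False, True, False, True, False])
        assert roc.auc == 0.5

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            roc_curve([1, 2, 3], [True, True, True])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.integers(0, 8), min_size=4, max_size=30))
    def test_auc_equals_concordance(self, raw):
        values = [float(v) for v in raw]
        labels = [i % 2 == 0 for i in range(len(values))]
        roc = roc_curve(values, labels)
        assert np.isclose(roc.auc, concordance_auc(values, labels))

    def test_auc_monotone_transform_invariant(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0, 1, 80)
        labels = rng.random(80) < 0.4
        a1 = roc_curve(values, labels).auc
        a2 = roc_curve(np.exp(2 * values) + 3, labels).auc
        assert np.isclose(a1, a2)


class TestOperatingPoint:
    def test_perfect_point_selected(self):
        roc = roc_curve([1, 2, 5, 6], [False, False, True, True])
        th = optimal_operating_point(roc)
        assert 2 < th <= 5

    def test_hand_evaluated_two_point_curve(self):
        # (fpr, tpr) = (0.1, 0.8) vs (0.3, 0.95): first is closer to (0,1)
        points = np.array([[0.1, 0.8, 5.0], [0.3, 0.95, 3.0]])
        roc = ROCResult(points=points, auc=0.9, optimal_threshold=0.0,
                        optimal_distance=0.0)
        assert optimal_operating_point(roc) == 5.0

    def test_single_point_curve(self):
        roc = ROCResult(points=np.array([[0.2, 0.9, 1.5]]), auc=0.8,
                        optimal_threshold=0.0, optimal_distance=0.0)
        assert optimal_operating_point(roc) == 1.5

    def test_empty_curve_is_error(self):
        roc = ROCResult(points=np.empty((0, 3)), auc=0.5,
                        optimal_threshold=0.0, optimal_distance=0.0)
        with pytest.raises(ValueError):
            optimal_operating_point(roc)


class TestCalibrate:
    def test_two_epoch_toy_set(self):
        feats = [EpochFeatures(sefd=5.0, ap=10.0, rp=-8.0),
                 EpochFeatures(sefd=3.0, ap=18.0, rp=-15.0)]
        th = calibrate_thresholds(feats, [True, False])
        assert 3.0 < th.sefd_th <= 5.0

    def test_single_class_is_error(self):
        feats = [EpochFeatures(sefd=5.0, ap=10.0, rp=-8.0)] * 3
        with pytest.raises(ValueError):
            calibrate_thresholds(feats, [True, True, True])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_designed_boundary_recovered(self, seed):
        feats, labels = labelled_feature_sample(boundary=4.5, seed=seed)
        th = calibrate_thresholds(feats, labels)
        assert abs(th.sefd_th - 4.5) <= 0.25

    def test_stage2_accepts_rem_cluster(self):
        feats, labels = labelled_feature_sample(seed=3)
        th = calibrate_thresholds(feats, labels)
        pred = detect_recording(feats, th).binary()
        sens = (pred & labels).sum() / labels.sum()
        assert sens >= 0.9

    def test_invalid_epochs_ignored(self):
        feats, labels = labelled_feature_sample(n_per_class=50, seed=4)
        feats.append(EpochFeatures(np.nan, np.nan, np.nan, valid=False))
        labels = np.append(labels, True)
        th_with = calibrate_thresholds(feats, labels)
        th_without = calibrate_thresholds(feats[:-1], labels[:-1])
        assert th_with == th_without


class TestCrossValidation:
    def _recordings(self, n=10, seed=0):
        out = []
        for i in range(n):
            feats, labels = labelled_feature_sample(n_per_class=30,
                                                    seed=seed + i)
            out.append((feats, labels))
        return out

    def test_every_subject_in_exactly_one_test_fold(self):
        recs = self._recordings(10)
        report = crossvalidate(recs, k=5, seed=1)
        seen = [s for fold in report["folds"] for s in fold["test_subjects"]]
        assert sorted(seen) == list(range(10))

    def test_deterministic_for_fixed_seed(self):
        recs = self._recordings(8)
        r1 = crossvalidate(recs, k=4, seed=9)
        r2 = crossvalidate(recs, k=4, seed=9)
        assert r1 == r2

    def test_mean_is_arithmetic_mean_of_folds(self):
        recs = self._recordings(8)
        report = crossvalidate(recs, k=4, seed=2)
        per_fold = [f["sensitivity"] for f in report["folds"]]
        assert np.isclose(report["mean"]["sensitivity"],
                          np.mean(per_fold), atol=1e-12)

    @pytest.mark.parametrize("k", [1, 0, 11])
    def test_invalid_fold_counts(self, k):
        with pytest.raises(ValueError):
            crossvalidate(self._recordings(10), k=k, seed=0)
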