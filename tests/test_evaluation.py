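"""Overlap statistics, volume agreement, and Fazekas-score estimation."""

import itertools

import numpy as np
import pytest

from ctwml import (ConfusionMatrix3, ImageVolume, bland_altman,
                   confusion_accuracy, cross_validated_fazekas,
                   fit_fazekas_thresholds, overlap_stats, volume_correlation)
from ctwml.volume import VolumeError


def _mask(arr, spacing=(1, 1, 1)):
    return ImageVolume.from_spacing(np.asarray(arr, dtype=np.uint8), spacing,
                                    "mask")


class TestOverlapStats:
    def test_identical_masks(self):
        m = _mask(np.ones((4, 4, 4)))
        st = overlap_stats(m, m)
        assert st.dice == 1.0
        assert st.vol_X_only_ml == 0 and st.vol_Y_only_ml == 0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4)); a[0] = 1
        b = np.zeros((4, 4, 4)); b[3] = 1
        assert overlap_stats(_mask(a), _mask(b)).dice == 0.0

    def test_printed_formula_hand_case(self):
        """300- and 500-voxel masks sharing 200 voxels: Dice = 400/800."""
        x = np.zeros((10, 10, 10)); y = np.zeros((10, 10, 10))
        x.flat[:300] = 1
        y.flat[100:600] = 1
        st = overlap_stats(_mask(x), _mask(y))
        assert st.dice == pytest.approx(0.5)
        assert st.vol_intersection_ml == pytest.approx(0.2)
        assert st.vol_X_only_ml == pytest.approx(0.1)
        assert st.vol_Y_only_ml == pytest.approx(0.3)

    def test_both_empty_convention(self):
        st = overlap_stats(_mask(np.zeros((3, 3, 3))),
                           _mask(np.zeros((3, 3, 3))))
        assert st.dice == 0.0 and st.both_empty

    def test_grid_mismatch_raises(self):
        with pytest.raises(VolumeError):
            overlap_stats(_mask(np.zeros((3, 3, 3))),
                          _mask(np.zeros((4, 4, 4))))

    def test_volume_decomposition_invariant(self, rng):
        for _ in range(20):
            x = rng.random((8, 8, 8)) > 0.6
            y = rng.random((8, 8, 8)) > 0.6
            st = overlap_stats(_mask(x, (2, 2, 4)), _mask(y, (2, 2, 4)))
            assert st.vol_X_ml == pytest.approx(
                st.vol_intersection_ml + st.vol_X_only_ml)
            assert st.vol_Y_ml == pytest.approx(
                st.vol_intersection_ml + st.vol_Y_only_ml)


class TestVolumeAgreement:
    def test_perfect_line(self):
        recs = [(i, i) for i in range(5)]
        r, slope, intercept = volume_correlation(recs)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0)

    def test_anticorrelation(self):
        recs = [(-float(i), float(i)) for i in range(4)]
        r, _, _ = volume_correlation(recs)
        assert r == pytest.approx(-1.0)

    def test_hand_ols(self):
        # (flair, ct) pairs (0,0),(1,2),(2,4): ct = 2*flair exactly
        r, slope, intercept = volume_correlation([(0, 0), (2, 1), (4, 2)])
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            volume_correlation([(1, 1), (1, 2), (1, 3)])

    def test_bland_altman_zero_difference(self):
        md, (lo, hi), _ = bland_altman([(1, 1), (2, 2), (3, 3)])
        assert md == 0 and lo == 0 and hi == 0

    def test_bland_altman_constant_offset(self):
        md, (lo, hi), _ = bland_altman([(3, 1), (4, 2), (5, 3)])
        assert md == pytest.approx(2.0)
        assert lo == pytest.approx(2.0) and hi == pytest.approx(2.0)

    def test_bland_altman_hand_case(self):
        # differences {-1, 0, 1}: population SD sqrt(2/3)
        md, (lo, hi), pairs = bland_altman([(0, 1), (1, 1), (2, 1)])
        sd = np.sqrt(2.0 / 3.0)
        assert md == pytest.approx(0.0)
        assert lo == pytest.approx(-1.96 * sd)
        assert hi == pytest.approx(1.96 * sd)
        assert pairs.shape == (3, 2)


def brute_force_thresholds(volumes, labels):
    """Independent oracle: try all pairs of cut points drawn from the
    observed volumes (and sentinels), count correct labels directly."""
    order = {"0_1": 0, "2": 1, "3": 2}
    y = np.array([order[l] for l in labels])
    v = np.asarray(volumes, dtype=float)
    cands = sorted(set(np.concatenate([[0.0], v, [np.inf]])))
    best_acc, best = -1, None
    for lo, hi in itertools.combinations(cands, 2):
        pred = np.where(v < lo, 0, np.where(v < hi, 1, 2))
        acc = (pred == y).sum()
        if acc > best_acc:
            best_acc, best = acc, (lo, hi)
    return best_acc / len(v)


class TestFazekasThresholds:
    def test_separable_volumes_perfect_accuracy(self):
        vols = [1, 2, 10, 11, 30, 31]
        labels = ["0_1", "0_1", "2", "2", "3", "3"]
        thr = fit_fazekas_thresholds(vols, labels)
        assert 2 < thr.t_low < 10
        assert 11 < thr.t_high < 30
        assert thr.predict(vols) == labels

    def test_matches_brute_force_with_overlap(self, rng):
        vols = np.concatenate([rng.uniform(0, 4, 10), rng.uniform(3, 14, 10),
                               rng.uniform(12, 40, 10)])
        labels = ["0_1"] * 10 + ["2"] * 10 + ["3"] * 10
        thr = fit_fazekas_thresholds(vols, labels)
        acc = np.mean(np.array(thr.predict(vols)) == np.array(labels))
        assert acc == pytest.approx(brute_force_thresholds(vols, labels))

    def test_single_overlapping_point(self):
        # one class-2 point sits below the 0-1 maximum
        vols = [1, 2, 1.5, 10, 30, 31]
        labels = ["0_1", "0_1", "2", "2", "3", "3"]
        thr = fit_fazekas_thresholds(vols, labels)
        acc = np.mean(np.array(thr.predict(vols)) == np.array(labels))
        assert acc == pytest.approx(5 / 6)
        assert acc == pytest.approx(brute_force_thresholds(vols, labels))

    def test_random_labels_at_least_majority_floor(self, rng):
        vols = rng.uniform(0, 50, 30)
        labels = list(rng.permutation(["0_1"] * 10 + ["2"] * 10 + ["3"] * 10))
        thr = fit_fazekas_thresholds(vols, labels)
        acc = np.mean(np.array(thr.predict(vols)) == np.array(labels))
        assert acc >= 1 / 3

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            fit_fazekas_thresholds([1, 2, 3], ["0_1", "0_1", "2"])


class TestCrossValidatedFazekas:
    def test_separable_case_is_perfect(self):
        vols = ([0.5 + 0.1 * i for i in range(10)]
                + [8 + 0.2 * i for i in range(10)]
                + [30 + 0.5 * i for i in range(10)])
        labels = ["0_1"] * 10 + ["2"] * 10 + ["3"] * 10
        cm, acc = cross_validated_fazekas(vols, labels, n_folds=5, seed=0)
        assert acc == 1.0
        assert np.trace(cm.counts) == 30

    def test_scale_invariance(self, rng):
        vols = np.concatenate([rng.uniform(0, 4, 12), rng.uniform(3, 15, 12),
                               rng.uniform(10, 50, 12)])
        labels = ["0_1"] * 12 + ["2"] * 12 + ["3"] * 12
        _, acc1 = cross_validated_fazekas(list(vols), labels, 6, seed=5)
        _, acc2 = cross_validated_fazekas(list(vols * 7.3), labels, 6, seed=5)
        assert acc1 == acc2

    def test_row_sums_match_group_sizes(self, rng):
        vols = list(rng.uniform(0, 50, 30))
        labels = ["0_1"] * 8 + ["2"] * 12 + ["3"] * 10
        cm, _ = cross_validated_fazekas(vols, labels, 5, seed=2)
        np.testing.assert_array_equal(cm.counts.sum(axis=1), [8, 12, 10])


class TestConfusionAccuracy:
    def test_perfect_diagonal(self):
        cm = ConfusionMatrix3(np.diag([5, 6, 7]))
        assert confusion_accuracy(cm) == 1.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            confusion_accuracy(ConfusionMatrix3(np.zeros((3, 3))))
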