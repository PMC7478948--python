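"""Fold plans, probability thresholding and the repeated-CV ensemble."""

import numpy as np
import pytest

from ctwml import (ImageVolume, ModelSpec, make_fold_plan, run_cv_ensemble,
                   threshold_map, volume_ml)
from ctwml.ensemble import FoldError, PipelineError


class TestFoldPlan:
    def test_147_subjects_10_folds_sizes(self):
        ids = [f"s{i}" for i in range(147)]
        plan = make_fold_plan(ids, 10, 10, seed=4)
        for r in range(10):
            sizes = sorted(np.bincount(plan.assignment[r], minlength=10))
            # 147 = 10 x 14 + 7: three folds of 14, seven of 15
            assert sizes == [14] * 3 + [15] * 7

    def test_each_subject_once_per_repetition(self):
        plan = make_fold_plan([f"s{i}" for i in range(25)], 5, 3, seed=1)
        assert plan.assignment.shape == (3, 25)
        for r in range(3):
            assert np.bincount(plan.assignment[r], minlength=5).sum() == 25

    def test_forced_singleton_folds(self):
        plan = make_fold_plan([f"s{i}" for i in range(10)], 10, 2, seed=0)
        for r in range(2):
            assert sorted(plan.assignment[r]) == list(range(10))

    def test_deterministic(self):
        ids = [f"s{i}" for i in range(30)]
        a = make_fold_plan(ids, 10, 4, seed=9)
        b = make_fold_plan(ids, 10, 4, seed=9)
        np.testing.assert_array_equal(a.assignment, b.assignment)

    def test_too_few_subjects(self):
        with pytest.raises(FoldError):
            make_fold_plan(["a", "b"], 10, 1, seed=0)

    def test_stratified_folds_spread_groups(self):
        ids = [f"s{i}" for i in range(30)]
        strata = (["0_1"] * 10 + ["2"] * 10 + ["3"] * 10)
        plan = make_fold_plan(ids, 5, 2, seed=2, strata=strata)
        strata_arr = np.array(strata)
        for r in range(2):
            for f in range(5):
                groups = set(strata_arr[plan.assignment[r] == f])
                assert groups == {"0_1", "2", "3"}


class TestThresholdMap:
    def _prob(self, value):
        return ImageVolume.from_spacing(
            np.full((4, 4, 4), value, dtype=np.float32), (1, 1, 1),
            "probability")

    def test_inclusive_at_threshold(self):
        mask = threshold_map(self._prob(0.25), 0.25)
        assert np.all(mask.data == 1)

    def test_strictly_below_is_empty(self):
        mask = threshold_map(self._prob(0.249), 0.25)
        assert np.all(mask.data == 0)

    def test_out_of_range_threshold_warns(self):
        with pytest.warns(UserWarning):
            threshold_map(self._prob(0.5), 1.5)

    def test_volume_matches_voxel_count(self, rng):
        data = rng.random((8, 8, 8)).astype(np.float32)
        prob = ImageVolume.from_spacing(data, (2, 2, 4), "probability")
        mask = threshold_map(prob, 0.25)
        expected = (data >= 0.25).sum() * 16.0 / 1000.0
        assert volume_ml(mask) == pytest.approx(expected)


def _toy_cohort(n, shape=(64, 64, 6), seed=0):
    """Tiny preprocessed cohort with bright square lesions."""
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        img = rng.normal(0, 0.3, size=shape).astype(np.float32)
        lab = np.zeros(shape, dtype=np.uint8)
        c = 16 + 4 * (i % 3)
        lab[c:c + 10, c:c + 10, 2:4] = 1
        img[lab == 1] += 3.0
        mask = np.ones(shape, np.uint8)
        cohort.append({
            "subject_id": f"t{i:02d}",
            "ct": ImageVolume.from_spacing(img, (2, 2, 4), "ct"),
            "flair": ImageVolume.from_spacing(img, (2, 2, 4), "flair"),
            "wml_truth": ImageVolume.from_spacing(lab, (2, 2, 4), "mask"),
            "brain_mask": ImageVolume.from_spacing(mask, (2, 2, 4), "mask"),
            "fazekas_label": ["0_1", "2", "3"][i % 3],
        })
    return cohort


TINY_SPEC = ModelSpec(depth=3, base_channels=4, epochs=3, batch_size=16,
                      seed=1)


class TestRunCvEnsemble:
    @pytest.fixture(scope="class")
    def small_run(self):
        cohort = _toy_cohort(6)
        plan = make_fold_plan([c["subject_id"] for c in cohort], 2, 2, seed=3)
        results = run_cv_ensemble(cohort, plan, TINY_SPEC, threshold=0.25,
                                  n_patches=48, keep_repetition_maps=True)
        return cohort, plan, results

    def test_mean_equals_recomputed_repetition_average(self, small_run):
        _, plan, results = small_run
        for res in results:
            assert res.n_contributing_models == plan.n_repetitions
            stack = np.stack([m.data for m in res.repetition_maps])
            np.testing.assert_allclose(res.mean_probability.data,
                                       stack.mean(axis=0), atol=1e-6)

    def test_final_mask_consistent_with_threshold(self, small_run):
        _, _, results = small_run
        for res in results:
            expected = (res.mean_probability.data >= 0.25).astype(np.uint8)
            np.testing.assert_array_equal(res.final_mask.data, expected)
            assert res.wml_volume_ml == pytest.approx(
                volume_ml(res.final_mask))

    def test_volume_non_increasing_in_threshold(self, small_run):
        _, _, results = small_run
        for res in results:
            vols = [volume_ml(threshold_map(res.mean_probability, t))
                    for t in np.linspace(0, 1, 11)]
            assert all(a >= b for a, b in zip(vols, vols[1:]))

    def test_single_repetition_equals_single_model_map(self):
        from ctwml.cnn import predict_probability, sample_patches, train
        from ctwml.ensemble import _derive_seed
        cohort = _toy_cohort(4)
        plan = make_fold_plan([c["subject_id"] for c in cohort], 2, 1, seed=7)
        results = run_cv_ensemble(cohort, plan, TINY_SPEC, n_patches=48)
        # recompute one fold's model independently
        f = plan.assignment[0][0]
        train_idx = np.where(plan.assignment[0] != f)[0]
        seed = _derive_seed(plan.seed, 0, int(f))
        triples = [(cohort[i]["ct"], cohort[i]["wml_truth"],
                    cohort[i]["brain_mask"]) for i in train_idx]
        patches = sample_patches(triples, 48, 0.5, seed=seed)
        spec = ModelSpec(**{**TINY_SPEC.__dict__, "seed": seed})
        model = train(spec, patches)
        prob = predict_probability(model, cohort[0]["ct"],
                                   cohort[0]["brain_mask"])
        np.testing.assert_allclose(results[0].mean_probability.data,
                                   prob.data, atol=1e-6)

    def test_plan_cohort_mismatch_raises(self):
        cohort = _toy_cohort(4)
        plan = make_fold_plan(["x0", "x1", "x2", "x3"], 2, 1, seed=0)
        with pytest.raises(PipelineError):
            run_cv_ensemble(cohort, plan, TINY_SPEC, n_patches=16)
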