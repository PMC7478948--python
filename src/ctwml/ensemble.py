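"""Repeated cross-validation ensemble for CT segmentation.

Each subject is segmented by a model that never saw it: within each
repetition the cohort is split into folds, one model is trained per
fold on the out-of-fold subjects, and predicts its test-fold subjects.
Repeating the whole cross-validation (with re-randomized folds and
re-initialized weights) gives every subject several independent
probability maps; their arithmetic mean, thresholded at 0.25
(inclusive ≥), is the final segmentation.  Averaging across
repetitions is what stabilizes the per-subject volume estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cnn import ModelSpec, predict_probability, sample_patches, train
from .volume import ImageVolume, volume_ml


class FoldError(ValueError):
    """Fold-plan contract violation."""


class PipelineError(RuntimeError):
    """Ensemble bookkeeping integrity failure."""


@dataclass
class FoldPlan:
    """Subject→fold assignment for every repetition.

    ``assignment[r, i]`` is the fold index of subject ``i`` in
    repetition ``r``.  Within a repetition every subject sits in
    exactly one fold and fold sizes differ by at most 1.
    """

    n_subjects: int
    n_folds: int
    n_repetitions: int
    assignment: np.ndarray
    seed: int
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment)
        if a.shape != (self.n_repetitions, self.n_subjects):
            raise FoldError("assignment shape mismatch")
        for r in range(self.n_repetitions):
            counts = np.bincount(a[r], minlength=self.n_folds)
            if counts.max() - counts.min() > 1:
                raise FoldError(f"repetition {r}: fold sizes differ by >1")
            if counts.sum() != self.n_subjects:
                raise FoldError(f"repetition {r}: subjects not partitioned")


def make_fold_plan(subject_ids: list[str], n_folds: int = 10,
                   n_repetitions: int = 10, seed: int = 0,
                   strata: list | None = None) -> FoldPlan:
    """Random, optionally stratified fold assignment per repetition.

    With ``strata`` (e.g. Fazekas labels) subjects are shuffled within
    stratum, concatenated, and dealt round-robin into folds: strata are
    spread evenly AND global fold sizes still differ by at most 1.
    """
    n = len(subject_ids)
    if n < n_folds:
        raise FoldError(f"{n} subjects cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    assignment = np.zeros((n_repetitions, n), dtype=int)
    for r in range(n_repetitions):
        if strata is not None:
            order = []
            for s in sorted(set(strata), key=str):
                members = [i for i, lab in enumerate(strata) if lab == s]
                rng.shuffle(members)
                order.extend(members)
        else:
            order = list(rng.permutation(n))
        fold_perm = rng.permutation(n_folds)
        for pos, subj in enumerate(order):
            assignment[r, subj] = fold_perm[pos % n_folds]
    return FoldPlan(n, n_folds, n_repetitions, assignment, seed,
                    list(subject_ids))


@dataclass
class EnsembleResult:
    subject_id: str
    mean_probability: ImageVolume
    final_mask: ImageVolume
    wml_volume_ml: float
    n_contributing_models: int
    fazekas_label: str | None = None
    repetition_maps: list[ImageVolume] | None = None


def threshold_map(prob: ImageVolume, threshold: float) -> ImageVolume:
    """Binary mask: 1 where probability ≥ threshold (inclusive)."""
    if not 0.0 <= threshold <= 1.0:
        warnings.warn(f"threshold {threshold} outside [0, 1]")
    return prob.like((prob.data >= threshold).astype(np.uint8), "mask")


def _derive_seed(base: int, *parts: int) -> int:
    s = base & 0x7FFFFFFF
    for p in parts:
        s = (s * 1000003 + p * 7919 + 17) % (2**31 - 1)
    return int(s)


def run_cv_ensemble(cohort: list[dict], plan: FoldPlan,
                    model_spec: ModelSpec, threshold: float = 0.25,
                    channel: str = "ct", n_patches: int = 600,
                    lesion_fraction: float = 0.5,
                    keep_repetition_maps: bool = False
                    ) -> list[EnsembleResult]:
    """Train/predict across all repetitions and folds, then aggregate.

    ``cohort`` entries are the dicts produced by
    :func:`ctwml.preprocessing.preprocess_pair` (keys ``subject_id``,
    ``flair``, ``ct``, ``brain_mask``, ``wml_truth``).  ``channel``
    selects the image fed to the network; labels are always the
    FLAIR-derived lesion masks, so ``channel="ct"`` is the
    cross-modality transfer setting.  All randomness derives from
    ``plan.seed``.
    """
    ids = [c["subject_id"] for c in cohort]
    if plan.subject_ids and plan.subject_ids != ids:
        raise PipelineError("fold plan does not cover this cohort")
    if plan.n_subjects != len(cohort):
        raise PipelineError("fold plan size does not match cohort")
    n = len(cohort)
    sums = [np.zeros(c[channel].shape, dtype=np.float64) for c in cohort]
    counts = np.zeros(n, dtype=int)
    rep_maps: list[list[ImageVolume | None]] = [
        [None] * plan.n_repetitions for _ in range(n)]

    for r in range(plan.n_repetitions):
        for f in range(plan.n_folds):
            test_idx = np.where(plan.assignment[r] == f)[0]
            train_idx = np.where(plan.assignment[r] != f)[0]
            if len(test_idx) == 0:
                continue
            triples = [(cohort[i][channel], cohort[i]["wml_truth"],
                        cohort[i]["brain_mask"]) for i in train_idx]
            seed = _derive_seed(plan.seed, r, f)
            patches = sample_patches(triples, n_patches, lesion_fraction,
                                     seed=seed)
            spec = ModelSpec(**{**model_spec.__dict__, "seed": seed})
            model = train(spec, patches)
            net = model.network()
            for i in test_idx:
                prob = predict_probability(model, cohort[i][channel],
                                           cohort[i]["brain_mask"], _net=net)
                sums[i] += prob.data
                counts[i] += 1
                if keep_repetition_maps:
                    rep_maps[i][r] = prob

    results = []
    for i, c in enumerate(cohort):
        if counts[i] != plan.n_repetitions:
            raise PipelineError(
                f"subject {c['subject_id']} has {counts[i]} predictions, "
                f"expected {plan.n_repetitions}")
        mean = (sums[i] / counts[i]).astype(np.float32)
        mean_vol = c[channel].like(np.clip(mean, 0.0, 1.0), "probability")
        final = threshold_map(mean_vol, threshold)
        results.append(EnsembleResult(
            subject_id=c["subject_id"], mean_probability=mean_vol,
            final_mask=final, wml_volume_ml=volume_ml(final),
            n_contributing_models=plan.n_repetitions,
            fazekas_label=c.get("fazekas_label"),
            repetition_maps=rep_maps[i] if keep_repetition_maps else None))
    return results
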