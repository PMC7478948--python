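"""Volumetric agreement statistics and Fazekas-score estimation.

Covers everything the validation stage needs: Dice overlap with
correctly/incorrectly segmented volumes, Pearson correlation and an
ordinary-least-squares fit of CT on FLAIR volumes, Bland-Altman
agreement summaries, and a volume-threshold Fazekas classifier — two
cut points on total lesion volume separating groups 0–1 / 2 / 3 —
fitted by exhaustive search and evaluated with cross-validation into a
3x3 confusion matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .volume import ImageVolume, VolumeError

FAZEKAS_ORDER = ("0_1", "2", "3")


@dataclass
class OverlapStats:
    """Dice plus the correct/incorrect volume decomposition (mL).

    X is the CT segmentation, Y the FLAIR reference;
    ``dice = 2|X∩Y| / (|X|+|Y|)``, defined as 0 when both are empty
    (``both_empty`` flags that convention).
    """

    dice: float
    vol_X_ml: float
    vol_Y_ml: float
    vol_intersection_ml: float
    vol_X_only_ml: float
    vol_Y_only_ml: float
    both_empty: bool = False


def overlap_stats(seg_ct: ImageVolume, seg_flair: ImageVolume) -> OverlapStats:
    """Voxel-overlap statistics between two binary segmentations on one grid."""
    for m in (seg_ct, seg_flair):
        if not np.isin(m.data, (0, 1)).all():
            raise VolumeError("overlap_stats requires binary masks")
    if seg_ct.shape != seg_flair.shape:
        raise VolumeError("masks must share a grid")
    if not np.allclose(seg_ct.spacing, seg_flair.spacing):
        raise VolumeError("masks must share voxel spacing")
    vox_ml = seg_ct.voxel_volume_mm3 / 1000.0
    x = seg_ct.data.astype(bool)
    y = seg_flair.data.astype(bool)
    nx, ny = int(x.sum()), int(y.sum())
    ni = int(np.logical_and(x, y).sum())
    both_empty = (nx + ny) == 0
    dice = 0.0 if both_empty else 2.0 * ni / (nx + ny)
    return OverlapStats(dice=dice, vol_X_ml=nx * vox_ml, vol_Y_ml=ny * vox_ml,
                        vol_intersection_ml=ni * vox_ml,
                        vol_X_only_ml=(nx - ni) * vox_ml,
                        vol_Y_only_ml=(ny - ni) * vox_ml,
                        both_empty=both_empty)


def volume_correlation(records) -> tuple[float, float, float]:
    """Pearson r plus OLS (CT regressed on FLAIR) slope and intercept.

    ``records`` is a sequence of (vol_ct_ml, vol_flair_ml) pairs.
    """
    arr = np.asarray(records, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
        raise ValueError("need >= 3 (ct, flair) volume pairs")
    ct, flair = arr[:, 0], arr[:, 1]
    if ct.std() == 0 or flair.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(stats.pearsonr(ct, flair).statistic)
    slope, intercept = np.polyfit(flair, ct, 1)
    return r, float(slope), float(intercept)


def bland_altman(records):
    """Bland-Altman summary for CT−FLAIR volume differences.

    Returns ``(mean_diff, (lo, hi), pairs)`` where the limits of
    agreement are mean ± 1.96·SD (population SD) and ``pairs`` holds
    the per-record (mean, difference) points for plotting.
    """
    arr = np.asarray(records, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
        raise ValueError("need >= 3 (ct, flair) volume pairs")
    diff = arr[:, 0] - arr[:, 1]
    mean = arr.mean(axis=1)
    md = float(diff.mean())
    sd = float(diff.std())
    return md, (md - 1.96 * sd, md + 1.96 * sd), np.c_[mean, diff]


# ---------------------------------------------------------------------------
# Fazekas estimation from WML volume


@dataclass
class FazekasThresholds:
    """Volume cut points (mL): ≤? t_low → 0–1, (t_low, t_high] → ... .

    A volume v is scored 0–1 if v < t_low, 2 if t_low ≤ v < t_high,
    and 3 if v ≥ t_high.
    """

    t_low: float
    t_high: float

    def __post_init__(self) -> None:
        if not (0 <= self.t_low < self.t_high):
            raise ValueError("need 0 <= t_low < t_high")

    def predict(self, volumes_ml) -> list[str]:
        v = np.asarray(volumes_ml, dtype=float)
        out = np.where(v < self.t_low, "0_1",
                       np.where(v < self.t_high, "2", "3"))
        return list(out)


@dataclass
class ConfusionMatrix3:
    """3x3 counts, rows = visual score (0–1, 2, 3), cols = automatic."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3, 3) or (self.counts < 0).any():
            raise ValueError("counts must be a non-negative 3x3 matrix")


def confusion_accuracy(cm: ConfusionMatrix3) -> float:
    """Share of correct estimates: trace / grand total."""
    total = int(cm.counts.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / total


def _accuracy(t_low, t_high, volumes, labels) -> int:
    pred = np.where(volumes < t_low, 0, np.where(volumes < t_high, 1, 2))
    return int((pred == labels).sum())


def fit_fazekas_thresholds(volumes_ml, labels) -> FazekasThresholds:
    """Exhaustive search for the accuracy-maximizing volume cut points.

    Candidates are midpoints between consecutive distinct sorted
    volumes, plus 0 and +inf sentinels; ties broken by the
    lexicographically smallest (t_low, t_high).
    """
    v = np.asarray(volumes_ml, dtype=float)
    labs = list(labels)
    if set(labs) != set(FAZEKAS_ORDER):
        missing = set(FAZEKAS_ORDER) - set(labs)
        raise ValueError(f"all three Fazekas groups required; missing {missing}")
    y = np.array([FAZEKAS_ORDER.index(l) for l in labs])
    uniq = np.unique(v)
    cands = [0.0] + [float((a + b) / 2) for a, b in zip(uniq[:-1], uniq[1:])] \
        + [float("inf")]
    best = None
    for i, lo in enumerate(cands):
        for hi in cands[i + 1:]:
            if not lo < hi:
                continue
            acc = _accuracy(lo, hi, v, y)
            key = (-acc, lo, hi)
            if best is None or key < best[0]:
                best = (key, lo, hi)
    _, lo, hi = best
    if lo == 0.0:
        lo = np.nextafter(0.0, 1.0)  # satisfy 0 <= t_low < t_high strictly
    return FazekasThresholds(float(lo), float(hi))


def _stratified_folds(labels, n_folds, rng):
    n = len(labels)
    order = []
    for s in FAZEKAS_ORDER:
        members = [i for i, lab in enumerate(labels) if lab == s]
        rng.shuffle(members)
        order.extend(members)
    fold_perm = rng.permutation(n_folds)
    folds = np.zeros(n, dtype=int)
    for pos, subj in enumerate(order):
        folds[subj] = fold_perm[pos % n_folds]
    return folds


def cross_validated_fazekas(volumes_ml, labels, n_folds: int = 10,
                            seed: int = 0) -> tuple[ConfusionMatrix3, float]:
    """Cross-validated Fazekas estimation from WML volumes.

    Thresholds are fitted on each training split and applied to the
    held-out split; test predictions accumulate into the confusion
    matrix (rows: visual rating, columns: automatic estimate).
    """
    v = np.asarray(volumes_ml, dtype=float)
    labs = list(labels)
    if len(v) < n_folds:
        raise ValueError("need at least n_folds subjects")
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(labs, n_folds, rng)
    counts = np.zeros((3, 3), dtype=int)
    for f in range(n_folds):
        test = folds == f
        train_labs = [l for l, t in zip(labs, test) if not t]
        if set(train_labs) != set(FAZEKAS_ORDER):
            warnings.warn(f"fold {f}: training split missing a class; skipped")
            continue
        thr = fit_fazekas_thresholds(v[~test], train_labs)
        preds = thr.predict(v[test])
        for true, pred in zip(np.array(labs)[test], preds):
            counts[FAZEKAS_ORDER.index(true), FAZEKAS_ORDER.index(pred)] += 1
    cm = ConfusionMatrix3(counts)
    return cm, confusion_accuracy(cm)
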