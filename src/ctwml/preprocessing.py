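"""Pre-processing chain: brain extraction, spatial normalization,
rigid CT→FLAIR registration by normalized mutual information, and
z-score intensity normalization within the brain mask.

Registration conventions
------------------------
Both registration routines estimate a world-space transform ``T`` such
that ``resample(moving, T, fixed)`` aligns the moving image with the
fixed one (pull-back sampling: the aligned image is ``moving(T(x))``).
Rotations are Euler xyz angles in degrees about the fixed image's grid
center; translations are in mm.

The rigid similarity metric is normalized mutual information,
NMI = (H(F) + H(M)) / H(F, M), computed from a 32x32 joint histogram
over voxels inside the fixed head region.  Optimization is Powell's
method over the 6 (rigid) or 9 (affine) parameters, run coarse-to-fine
on a 2-level pyramid with an iteration cap per level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage.filters import threshold_otsu

from .volume import (AffineTransform, ImageVolume, RigidTransform, VolumeError,
                     resample)


class PreprocessingError(RuntimeError):
    """Brain extraction or normalization failed on degenerate input."""


@dataclass
class NormalizationParams:
    """Mean/SD used for z-scoring inside the brain mask (population SD)."""

    mean_in_mask: float
    sd_in_mask: float


@dataclass
class RegistrationResult:
    transform: RigidTransform | AffineTransform
    final_metric: float
    converged: bool
    iterations: int
    initial_metric: float = float("nan")


# ---------------------------------------------------------------------------
# Brain extraction


def extract_brain(vol: ImageVolume) -> ImageVolume:
    """Threshold-plus-morphology brain mask: Otsu threshold, binary
    closing, hole filling, largest connected component."""
    data = vol.data.astype(np.float32)
    if not np.any(data != 0):
        raise PreprocessingError("empty volume: no foreground to extract")
    thr = threshold_otsu(data)
    fg = data > thr
    if not fg.any():
        raise PreprocessingError("no voxels above the Otsu threshold")
    fg = ndimage.binary_closing(fg, structure=np.ones((3, 3, 3)))
    fg = ndimage.binary_fill_holes(fg)
    labels, n = ndimage.label(fg)
    if n == 0:
        raise PreprocessingError("no connected component found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    return vol.like(mask.astype(np.uint8), "mask")


# ---------------------------------------------------------------------------
# Intensity normalization


def zscore_in_mask(vol: ImageVolume,
                   mask: ImageVolume) -> tuple[ImageVolume, NormalizationParams]:
    """Z-score ``vol`` within the brain mask (population SD); voxels
    outside the mask are set to 0."""
    if mask.modality_tag != "mask":
        raise VolumeError("second argument must be a mask volume")
    m = mask.data.astype(bool)
    vals = vol.data[m]
    if vals.size < 2:
        raise PreprocessingError("need at least 2 in-mask voxels")
    mu = float(vals.mean())
    sd = float(vals.std())  # population (n) convention
    if sd == 0:
        raise PreprocessingError("zero intensity variance inside the mask")
    out = np.zeros_like(vol.data, dtype=np.float32)
    out[m] = (vals - mu) / sd
    return vol.like(out, vol.modality_tag), NormalizationParams(mu, sd)


# ---------------------------------------------------------------------------
# Registration machinery


def _downsample(vol: ImageVolume, factor: int) -> ImageVolume:
    """Antialiased integer downsampling used for the pyramid."""
    if factor == 1:
        return vol
    data = ndimage.gaussian_filter(vol.data.astype(np.float32),
                                   sigma=0.5 * factor)
    data = data[::factor, ::factor, ::factor]
    scale = np.diag([factor, factor, factor, 1.0])
    affine = vol.affine @ scale
    spacing = tuple(s * factor for s in vol.spacing)
    tag = vol.modality_tag if vol.modality_tag != "mask" else "flair"
    return ImageVolume(data, spacing, affine, tag)


def nmi(fixed: np.ndarray, moving: np.ndarray, region: np.ndarray,
        bins: int = 32) -> float:
    """Normalized mutual information (H(F)+H(M))/H(F,M) over ``region``."""
    f = fixed[region]
    m = moving[region]
    if f.size == 0:
        return 1.0
    hist, _, _ = np.histogram2d(f, m, bins=bins)
    p = hist / hist.sum()
    pf = p.sum(axis=1)
    pm = p.sum(axis=0)

    def ent(q):
        q = q[q > 0]
        return -(q * np.log(q)).sum()

    hj = ent(p.ravel())
    if hj == 0:
        return 2.0
    return (ent(pf) + ent(pm)) / hj


def _resample_data(moving: ImageVolume, T: np.ndarray,
                   fixed: ImageVolume) -> np.ndarray:
    M = np.linalg.inv(moving.affine) @ T @ fixed.affine
    return ndimage.affine_transform(moving.data.astype(np.float32),
                                    M[:3, :3], offset=M[:3, 3],
                                    output_shape=fixed.shape, order=1,
                                    mode="constant", cval=0.0)


class _NMISampler:
    """Point-sampled NMI cost for one pyramid level.

    Fixed-image bin indices over the (subsampled) head region are
    precomputed; each evaluation only interpolates the moving image at
    the transformed points and bins it with integer arithmetic, which
    is what makes the Powell search affordable.
    """

    def __init__(self, fixed: ImageVolume, moving: ImageVolume,
                 bins: int = 32, max_points: int = 20000):
        region = fixed.data != 0
        if not region.any():
            region = np.ones(fixed.shape, dtype=bool)
        region = ndimage.binary_dilation(region, iterations=2)
        idx = np.argwhere(region)
        step = max(1, len(idx) // max_points)
        idx = idx[::step]
        world = (fixed.affine @ np.c_[idx, np.ones(len(idx))].T)[:3]
        self.world = world  # 3 x P
        fvals = fixed.data[tuple(idx.T)].astype(np.float32)
        lo, hi = float(fvals.min()), float(fvals.max())
        scale = (bins - 1e-5) / (hi - lo) if hi > lo else 0.0
        self.fbin = np.minimum((np.maximum(fvals - lo, 0) * scale),
                               bins - 1).astype(np.int32)
        self.bins = bins
        self.moving = np.ascontiguousarray(moving.data, dtype=np.float32)
        self.inv_affine = np.linalg.inv(moving.affine)
        mlo, mhi = float(self.moving.min()), float(self.moving.max())
        self.mlo = mlo
        self.mscale = (bins - 1e-5) / (mhi - mlo) if mhi > mlo else 0.0

    def nmi_at(self, T: np.ndarray) -> float:
        M = self.inv_affine @ T
        coords = M[:3, :3] @ self.world + M[:3, 3:4]
        vals = ndimage.map_coordinates(self.moving, coords, order=1,
                                       mode="constant", cval=0.0)
        # linear (Parzen-style) binning of the moving channel keeps the
        # metric smooth under sub-voxel transform changes
        pos = np.clip((vals - self.mlo) * self.mscale, 0, self.bins - 1 - 1e-6)
        i0 = pos.astype(np.int32)
        frac = pos - i0
        base = self.fbin * self.bins + i0
        nb = self.bins * self.bins
        joint = (np.bincount(base, weights=1.0 - frac, minlength=nb + 1)
                 + np.bincount(base + 1, weights=frac, minlength=nb + 1))[:nb]
        p = joint / joint.sum()
        pf = p.reshape(self.bins, self.bins).sum(axis=1)
        pm = p.reshape(self.bins, self.bins).sum(axis=0)

        def ent(q):
            q = q[q > 0]
            return -(q * np.log(q)).sum()

        hj = ent(p)
        if hj == 0:
            return 2.0
        return (ent(pf) + ent(pm)) / hj


def register_rigid_nmi(moving: ImageVolume, fixed: ImageVolume,
                       bins: int = 32, maxiter: int = 200) -> RegistrationResult:
    """Rigid CT→FLAIR registration maximizing NMI.

    Returns the 6-parameter transform that, applied via ``resample``,
    brings ``moving`` onto the fixed grid.  ``converged`` is False when
    the optimizer cannot improve on the identity, in which case the
    best-so-far transform is still returned.
    """
    center = tuple(fixed.center_world())

    def centroid_world(vol):
        idx = np.argwhere(vol.data != 0)
        if len(idx) == 0:
            return np.zeros(3)
        return (vol.affine @ np.append(idx.mean(axis=0), 1.0))[:3]

    # initialize: match head centroids, then coarse rotation grid search
    t0 = centroid_world(moving) - centroid_world(fixed)
    params = np.r_[np.zeros(3), t0]
    iterations = 0
    # second pass at full resolution restarts Powell's direction set,
    # which recovers the occasional stalled search
    for li, factor in enumerate((2, 1, 1)):
        sampler = _NMISampler(_downsample(fixed, factor),
                              _downsample(moving, factor), bins)

        def fun(p, sampler=sampler):
            t = RigidTransform(tuple(p[:3]), tuple(p[3:6]), center)
            return -sampler.nmi_at(t.as_matrix())

        if li == 0:
            grid = (-4.0, 0.0, 4.0)
            best = min(
                (np.r_[rx, ry, rz, params[3:6]]
                 for rx in grid for ry in grid for rz in grid),
                key=fun)
            params = best
        res = optimize.minimize(
            fun, params, method="Powell",
            options={"maxiter": maxiter, "xtol": 1e-3, "ftol": 1e-7,
                     "disp": False})
        params = res.x
        iterations += int(res.nit)

    full = _NMISampler(fixed, moving, bins)
    transform = RigidTransform(tuple(params[:3]), tuple(params[3:6]), center)
    final = full.nmi_at(transform.as_matrix())
    initial = full.nmi_at(np.eye(4))
    return RegistrationResult(transform, final, final >= initial - 1e-9,
                              iterations, initial)


def normalize_spatial(brain_mask: ImageVolume,
                      template_mask: ImageVolume,
                      maxiter: int = 200) -> RegistrationResult:
    """9-DOF affine registration of a binary brain mask to a template mask.

    Both masks are Gaussian-smoothed and the mean squared difference is
    minimized (a smooth surrogate for mask overlap); the reported
    ``final_metric`` is the Dice overlap of the aligned binary masks.
    """
    for m in (brain_mask, template_mask):
        if not np.isin(m.data, (0, 1)).all():
            raise VolumeError("normalize_spatial requires binary masks")
    center = tuple(template_mask.center_world())

    def soft(vol):
        data = ndimage.gaussian_filter(vol.data.astype(np.float32),
                                       (2.0, 2.0, 1.0))
        return ImageVolume(data, vol.spacing, vol.affine, "flair")

    soft_moving = soft(brain_mask)
    soft_fixed = soft(template_mask)

    # coarse centering: match mask centroids in world coordinates
    def centroid(vol):
        idx = np.argwhere(vol.data > 0)
        if len(idx) == 0:
            return np.asarray(center)
        h = np.c_[idx, np.ones(len(idx))]
        return (vol.affine @ h.mean(axis=0))[:3]

    t0 = centroid(brain_mask) - centroid(template_mask)
    params = np.r_[np.zeros(3), t0, np.ones(3)]

    def make_transform(p):
        return AffineTransform(tuple(p[:3]), tuple(p[3:6]),
                               tuple(np.clip(p[6:9], 0.2, 5.0)), center)

    def make_cost(fx, mv, max_points=20000):
        idx = np.argwhere(np.ones(fx.shape, dtype=bool))
        idx = idx[::max(1, len(idx) // max_points)]
        world = (fx.affine @ np.c_[idx, np.ones(len(idx))].T)[:3]
        fvals = fx.data[tuple(idx.T)].astype(np.float32)
        mdata = np.ascontiguousarray(mv.data, dtype=np.float32)
        inv_affine = np.linalg.inv(mv.affine)

        def cost(p):
            M = inv_affine @ make_transform(p).as_matrix()
            coords = M[:3, :3] @ world + M[:3, 3:4]
            warped = ndimage.map_coordinates(mdata, coords, order=1,
                                             mode="constant", cval=0.0)
            return float(((warped - fvals) ** 2).mean())

        return cost

    iterations = 0
    for factor in (2, 1):
        fx = _downsample(soft_fixed, factor)
        mv = _downsample(soft_moving, factor)
        res = optimize.minimize(
            make_cost(fx, mv), params, method="Powell",
            options={"maxiter": maxiter, "xtol": 1e-4, "ftol": 1e-9,
                     "disp": False})
        params = res.x
        iterations += int(res.nit)

    transform = make_transform(params)
    aligned = resample(brain_mask, transform, template_mask, "nearest")
    inter = float(np.logical_and(aligned.data, template_mask.data).sum())
    denom = float(aligned.data.sum() + template_mask.data.sum())
    dice = 2.0 * inter / denom if denom > 0 else 0.0
    # identity baseline for the convergence check
    ident = resample(brain_mask, AffineTransform(center=center),
                     template_mask, "nearest")
    i_inter = float(np.logical_and(ident.data, template_mask.data).sum())
    i_denom = float(ident.data.sum() + template_mask.data.sum())
    i_dice = 2.0 * i_inter / i_denom if i_denom > 0 else 0.0
    converged = dice >= i_dice and dice > 0.0
    return RegistrationResult(transform, dice, converged, iterations, i_dice)


# ---------------------------------------------------------------------------
# Subject-level convenience


def preprocess_pair(pair, register: bool = True):
    """Run the full chain on one phantom pair.

    Registers CT to FLAIR (unless ``register`` is False, e.g. when the
    generator applied no misalignment), then z-scores both channels
    inside the brain mask.  Returns a dict with the aligned, normalized
    volumes, the registration result, and the NormalizationParams.
    """
    out = {"subject_id": getattr(pair, "subject_id", "subj"),
           "brain_mask": pair.brain_mask, "wml_truth": pair.wml_truth,
           "fazekas_label": pair.fazekas_label}
    if register:
        reg = register_rigid_nmi(pair.ct, pair.flair)
        ct_aligned = resample(pair.ct, reg.transform, pair.flair, "linear")
        out["registration"] = reg
    else:
        ct_aligned = pair.ct
        out["registration"] = None
    flair_z, flair_params = zscore_in_mask(pair.flair, pair.brain_mask)
    ct_z, ct_params = zscore_in_mask(ct_aligned, pair.brain_mask)
    out.update(flair=flair_z, ct=ct_z,
               flair_norm=flair_params, ct_norm=ct_params)
    return out
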