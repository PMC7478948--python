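"""Synthetic paired pseudo-FLAIR / pseudo-CT phantoms with known lesions.

A phantom pair stands in for one clinical subject: an ellipsoidal
"brain" carrying a smooth tissue texture, white-matter lesions placed in
a periventricular/deep shell, a FLAIR channel in which lesions are
hyperintense at high contrast, and a CT channel showing the same lesions
at lower contrast and higher noise.  The CT channel is additionally
resampled through a known rigid misalignment so the registration stage
has a recoverable ground truth.

Lesion burden is stratified into the three Fazekas groups used in
clinical ratings (0–1 none/mild, 2 moderate, 3 severe) via disjoint
total-volume intervals, so a cohort reproduces the separated per-group
volume distributions the volumetry stage must discriminate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volume import ImageVolume, RigidTransform, resample, volume_ml

FAZEKAS_GROUPS = ("0_1", "2", "3")

#: Total-lesion-volume intervals (mL) per Fazekas group: monotone and
#: well-separated strata.
GROUP_VOLUME_ML: dict[str, tuple[float, float]] = {
    "0_1": (0.0, 2.0),
    "2": (5.0, 15.0),
    "3": (25.0, 60.0),
}


class PhantomError(RuntimeError):
    """Lesion-load target infeasible inside the brain mask."""


@dataclass
class PhantomSpec:
    """Generation parameters for one phantom pair.

    Contrasts are in z-units of the tissue texture; CT contrast must be
    below FLAIR contrast (CT shows WML more faintly).  ``misalignment``
    is the rigid transform that ALIGNS the generated CT back to the
    FLAIR grid (i.e. what registration should recover); ``None`` draws a
    random one with rotations <= 5 deg and translations <= 4 mm.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 24)
    spacing: tuple[float, float, float] = (2.0, 2.0, 4.0)
    n_lesions: int = 6
    lesion_radius_range: tuple[float, float] = (3.0, 9.0)
    fazekas_target: str = "2"
    flair_contrast: float = 5.0
    ct_contrast: float = 3.0
    noise_sd_flair: float = 0.5
    noise_sd_ct: float = 1.0
    misalignment: RigidTransform | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fazekas_target not in FAZEKAS_GROUPS:
            raise ValueError(f"fazekas_target must be one of {FAZEKAS_GROUPS}")
        if self.ct_contrast >= self.flair_contrast:
            raise ValueError("ct_contrast must be smaller than flair_contrast")


@dataclass
class PhantomPair:
    """One synthetic subject: FLAIR, misaligned CT, masks and ground truth."""

    flair: ImageVolume
    ct: ImageVolume
    brain_mask: ImageVolume
    wml_truth: ImageVolume
    true_misalignment: RigidTransform
    fazekas_label: str
    subject_id: str = "subj"
    true_volume_ml: float = field(default=0.0)


# ---------------------------------------------------------------------------


def _ellipsoid_mask(shape, spacing, center_mm, semiaxes_mm):
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                        indexing="ij")
    rho2 = sum(((g - c) / a) ** 2
               for g, c, a in zip(grids, center_mm, semiaxes_mm))
    return rho2, np.sqrt(rho2) <= 1.0


def _smooth_field(rng, shape, sigma_vox):
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox)
    sd = f.std()
    return f / sd if sd > 0 else f


def _place_lesions(rng, spec, brain, rho2, target_ml):
    """Add quasi-spherical blobs in the 0.1 < rho < 0.7 shell until the
    total volume reaches ``target_ml``; returns the binary truth array."""
    shape, spacing = spec.grid_shape, spec.spacing
    vox_ml = float(np.prod(spacing)) / 1000.0
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                        indexing="ij")
    rho = np.sqrt(rho2)
    shell = brain & (rho > 0.1) & (rho < 0.7)
    shell_idx = np.argwhere(shell)
    if shell_idx.size == 0:
        raise PhantomError("brain too small to host lesions")
    truth = np.zeros(shape, dtype=bool)
    r_lo, r_hi = spec.lesion_radius_range
    for attempt in range(400):
        if truth.sum() * vox_ml >= target_ml:
            break
        c = shell_idx[rng.integers(len(shell_idx))]
        c_mm = c * np.asarray(spacing)
        radius = rng.uniform(r_lo, r_hi)
        # shrink the last blob so the group interval is not overshot
        remaining = target_ml - truth.sum() * vox_ml
        r_fit = (3.0 * remaining * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        radius = min(radius, max(r_fit * 1.15, r_lo))
        d2 = sum((g - cm) ** 2 for g, cm in zip(grids, c_mm))
        truth |= (d2 <= radius ** 2) & brain & (rho < 0.85)
    got = truth.sum() * vox_ml
    if got < 0.5 * target_ml and target_ml > 0:
        raise PhantomError(
            f"could not place {target_ml:.1f} mL of lesions (got {got:.1f})")
    return truth


def generate_pair(spec: PhantomSpec) -> PhantomPair:
    """Generate one phantom pair; bit-deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    spacing = tuple(spec.spacing)
    extent = np.asarray(shape) * np.asarray(spacing)
    center_mm = (extent - np.asarray(spacing)) / 2.0
    # anteroposteriorly elongated head shape; unequal in-plane axes also
    # leave no rotational symmetry for registration to fall into
    semiaxes = np.array([0.45, 0.38, 0.45]) * extent

    rho2, brain = _ellipsoid_mask(shape, spacing, center_mm, semiaxes)

    # smooth tissue texture shared (up to gain) by the two channels
    texture = _smooth_field(rng, shape, sigma_vox=(3.0, 3.0, 1.5))

    if spec.n_lesions == 0:
        truth = np.zeros(shape, dtype=bool)
        label = "0_1"
    else:
        lo, hi = GROUP_VOLUME_ML[spec.fazekas_target]
        target = rng.uniform(max(lo, 0.3), hi)
        truth = _place_lesions(rng, spec, brain, rho2, target)
        label = spec.fazekas_target

    # soft lesion support for smooth intensity edges; truth stays binary
    lesion_soft = ndimage.gaussian_filter(truth.astype(np.float32),
                                          (0.8, 0.8, 0.4))
    m = lesion_soft.max()
    if m > 0:
        lesion_soft /= m

    flair = np.zeros(shape, dtype=np.float32)
    ct_aligned = np.zeros(shape, dtype=np.float32)
    flair[brain] = (10.0 + 1.0 * texture[brain]
                    + spec.flair_contrast * lesion_soft[brain]
                    + spec.noise_sd_flair * rng.standard_normal(brain.sum()))
    ct_aligned[brain] = (30.0 - 0.8 * texture[brain]
                         + spec.ct_contrast * lesion_soft[brain]
                         + spec.noise_sd_ct * rng.standard_normal(brain.sum()))

    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    flair_vol = ImageVolume(flair, spacing, affine, "flair")
    brain_vol = ImageVolume(brain.astype(np.uint8), spacing, affine, "mask")
    truth_vol = ImageVolume(truth.astype(np.uint8), spacing, affine, "mask")

    mis = spec.misalignment
    if mis is None:
        mis = RigidTransform(
            rotation=tuple(rng.uniform(-5.0, 5.0, 3)),
            translation=tuple(rng.uniform(-4.0, 4.0, 3)),
            center=tuple(flair_vol.center_world()))
    ct_aligned_vol = ImageVolume(ct_aligned, spacing, affine, "ct")
    # resampling through the INVERSE misaligns the CT; resampling the
    # result through `mis` itself brings it back onto the FLAIR grid
    ct_vol = resample(ct_aligned_vol, mis.inverse(), flair_vol, "linear")

    return PhantomPair(flair=flair_vol, ct=ct_vol, brain_mask=brain_vol,
                       wml_truth=truth_vol, true_misalignment=mis,
                       fazekas_label=label,
                       true_volume_ml=volume_ml(truth_vol))


def generate_cohort(n_per_group: tuple[int, int, int],
                    base_spec: PhantomSpec | None = None,
                    seed: int = 0) -> list[PhantomPair]:
    """Generate a Fazekas-stratified cohort.

    ``n_per_group`` gives the subject counts for groups (0–1, 2, 3);
    the clinical stratification this emulates is 50/48/49.  Per-subject
    seeds derive deterministically from ``seed``.
    """
    if any(n < 1 for n in n_per_group):
        raise ValueError("n_per_group entries must all be >= 1")
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    pairs: list[PhantomPair] = []
    k = 0
    for group, n in zip(FAZEKAS_GROUPS, n_per_group):
        for _ in range(n):
            child_seed = int(rng.integers(0, 2**31 - 1))
            n_lesions = base.n_lesions if group != "0_1" else max(
                1, base.n_lesions // 3)
            spec = replace(base, fazekas_target=group, seed=child_seed,
                           n_lesions=n_lesions)
            pair = generate_pair(spec)
            pair.subject_id = f"s{k:03d}"
            pairs.append(pair)
            k += 1
    return pairs
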