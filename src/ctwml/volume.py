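"""3D volume container, NIfTI I/O, spatial transforms and resampling.

Every image in the pipeline — FLAIR, CT, brain mask, lesion mask,
probability map — travels as an :class:`ImageVolume`: a 3D scalar grid
with voxel spacing (mm), a 4x4 grid-index→world-mm affine following the
NIfTI convention, and a modality tag that enforces value-domain
invariants (masks are {0,1}, probabilities lie in [0,1]).

Transforms are world-coordinate maps.  ``resample(vol, T, reference)``
produces the pull-back: ``out(x) = vol(T(x))`` for every world point x
on the reference grid.  Out-of-field voxels are filled with 0, matching
brain-extracted images which are 0 outside the head.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

MODALITY_TAGS = ("flair", "ct", "mask", "probability")


class VolumeError(ValueError):
    """Contract violation on an ImageVolume operation."""


@dataclass
class ImageVolume:
    """A 3D scalar grid with geometry metadata.

    Parameters
    ----------
    data:
        3D array. Stored as float32 for intensities/probabilities and
        uint8 for masks.
    spacing:
        Per-axis voxel size in mm, all strictly positive.
    affine:
        4x4 grid-index→world-mm matrix (NIfTI convention, 0-based
        indices); upper-left 3x3 must be non-singular.
    modality_tag:
        One of ``flair``, ``ct``, ``mask``, ``probability``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray
    modality_tag: str = "flair"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeError(f"expected 3D data, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeError(f"spacing must be 3 positive values, got {self.spacing}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise VolumeError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise VolumeError("affine upper-left 3x3 is singular")
        if self.modality_tag not in MODALITY_TAGS:
            raise VolumeError(f"unknown modality_tag {self.modality_tag!r}")
        if self.modality_tag == "mask":
            if not np.isin(self.data, (0, 1)).all():
                raise VolumeError("mask volume contains values outside {0, 1}")
            self.data = self.data.astype(np.uint8)
        elif self.modality_tag == "probability":
            if self.data.size and (self.data.min() < 0 or self.data.max() > 1):
                raise VolumeError("probability volume contains values outside [0, 1]")
            self.data = self.data.astype(np.float32)
        else:
            self.data = self.data.astype(np.float32)

    # -- convenience -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @classmethod
    def from_spacing(cls, data, spacing, modality_tag="flair") -> "ImageVolume":
        """Build a volume with a diagonal affine (grid axis = world axis)."""
        affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
        return cls(data, tuple(spacing), affine, modality_tag)

    def like(self, data, modality_tag=None) -> "ImageVolume":
        """New volume on this grid with different data."""
        return ImageVolume(data, self.spacing, self.affine.copy(),
                           modality_tag or self.modality_tag)

    def center_world(self) -> np.ndarray:
        """World coordinates (mm) of the grid center."""
        idx = (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
        return (self.affine @ np.append(idx, 1.0))[:3]


@dataclass
class RigidTransform:
    """Rotation (Euler xyz angles, degrees) + translation (mm) about ``center``.

    Maps a world point p to ``R (p - c) + c + t``.
    """

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation, degrees=True).as_matrix()

    def as_matrix(self) -> np.ndarray:
        R = self.rotation_matrix()
        c = np.asarray(self.center, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = c + t - R @ c
        return M

    def inverse(self) -> "RigidTransform":
        R = self.rotation_matrix()
        t = np.asarray(self.translation, dtype=float)
        ang = Rotation.from_matrix(R.T).as_euler("xyz", degrees=True)
        return RigidTransform(tuple(ang), tuple(-R.T @ t), self.center)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array of world points."""
        M = self.as_matrix()
        pts = np.atleast_2d(points)
        return pts @ M[:3, :3].T + M[:3, 3]


@dataclass
class AffineTransform:
    """9-parameter affine: rotation (deg), translation (mm), per-axis scale.

    Maps a world point p to ``R S (p - c) + c + t`` where S is the
    diagonal scale matrix.  Scales must be strictly positive.
    """

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.scale):
            raise VolumeError(f"scale factors must be positive, got {self.scale}")

    def as_matrix(self) -> np.ndarray:
        R = Rotation.from_euler("xyz", self.rotation, degrees=True).as_matrix()
        A = R @ np.diag(self.scale)
        c = np.asarray(self.center, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        M = np.eye(4)
        M[:3, :3] = A
        M[:3, 3] = c + t - A @ c
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        M = self.as_matrix()
        pts = np.atleast_2d(points)
        return pts @ M[:3, :3].T + M[:3, 3]


# ---------------------------------------------------------------------------
# NIfTI I/O


def _infer_modality(path: Path) -> str:
    name = path.name.lower()
    if "mask" in name or "truth" in name:
        return "mask"
    if "prob" in name:
        return "probability"
    if "ct" in name:
        return "ct"
    return "flair"


def read_volume(path, modality_tag: str | None = None) -> ImageVolume:
    """Read a 3D NIfTI-1 file (.nii / .nii.gz).

    ``modality_tag`` overrides the filename-based inference (names
    containing "mask"/"truth" → mask, "prob" → probability, "ct" → ct,
    otherwise flair).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeError(f"{path}: expected a 3D image, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    tag = modality_tag or _infer_modality(path)
    return ImageVolume(data, spacing, np.asarray(img.affine, dtype=float), tag)


def write_volume(vol: ImageVolume, path) -> None:
    """Write to NIfTI-1; masks as uint8, everything else float32."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dtype = np.uint8 if vol.modality_tag == "mask" else np.float32
    img = nib.Nifti1Image(vol.data.astype(dtype), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_sidecar(path, meta: dict) -> None:
    """Write a provenance sidecar JSON next to a volume."""
    Path(path).write_text(json.dumps(meta, indent=2, default=str))


# ---------------------------------------------------------------------------
# Resampling and volumetry


def resample(vol: ImageVolume,
             transform: RigidTransform | AffineTransform | np.ndarray | None,
             reference: ImageVolume,
             interpolation: str = "linear") -> ImageVolume:
    """Sample ``vol`` through a world-space transform onto the reference grid.

    ``out(x) = vol(T(x))`` for every reference-grid world point x;
    voxels falling outside ``vol``'s field of view are 0.  Masks must
    use nearest interpolation and stay binary.
    """
    if interpolation not in ("linear", "nearest"):
        raise VolumeError(f"unknown interpolation {interpolation!r}")
    if vol.modality_tag == "mask" and interpolation != "nearest":
        raise VolumeError("masks must be resampled with nearest interpolation")
    if transform is None:
        T = np.eye(4)
    elif isinstance(transform, np.ndarray):
        T = np.asarray(transform, dtype=float)
    else:
        T = transform.as_matrix()
    # reference index -> reference world -> (T) -> vol world -> vol index
    M = np.linalg.inv(vol.affine) @ T @ reference.affine
    order = 0 if interpolation == "nearest" else 1
    out = ndimage.affine_transform(
        vol.data.astype(np.float32), M[:3, :3], offset=M[:3, 3],
        output_shape=reference.shape, order=order, mode="constant", cval=0.0)
    if vol.modality_tag == "mask":
        out = (out > 0.5).astype(np.uint8)
    elif vol.modality_tag == "probability":
        out = np.clip(out, 0.0, 1.0)
    return ImageVolume(out, reference.spacing, reference.affine.copy(),
                       vol.modality_tag)


def volume_ml(mask: ImageVolume) -> float:
    """Lesion volume in millilitres: (# foreground voxels) x voxel mm^3 / 1000."""
    vals = np.unique(mask.data)
    if not np.isin(vals, (0, 1)).all():
        raise VolumeError("volume_ml requires a binary mask")
    return float(np.count_nonzero(mask.data) * mask.voxel_volume_mm3 / 1000.0)
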