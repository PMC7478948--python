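"""Patch-based residual U-shaped CNN for voxelwise WML probability.

The network is trained on 64x64 axial patches — large enough to expose
both local lesion texture and surrounding context — with FLAIR-derived
binary lesion masks as ground truth.  The same machinery serves the
MRI model (FLAIR input) and the CT model (CT input, cross-modality
labels): only the image channel fed to :func:`sample_patches` differs.

Inference tiles each axial slice with 50%-overlapping patches and
averages the per-pixel sigmoid outputs of every patch covering a pixel,
yielding a seam-free full-volume probability map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, UResNet2D, bce_with_logits, sigmoid
from .volume import ImageVolume

PATCH = 64  # in-plane patch edge, pixels


class TrainingError(RuntimeError):
    """Training diverged or the patch set is degenerate."""


@dataclass
class PatchSample:
    """One axial 64x64 training sample."""

    image_patch: np.ndarray
    label_patch: np.ndarray
    subject_id: str
    slice_index: int
    corner: tuple[int, int]

    def __post_init__(self) -> None:
        if self.image_patch.shape != (PATCH, PATCH):
            raise ValueError("image patch must be 64x64")
        if self.label_patch.shape != (PATCH, PATCH):
            raise ValueError("label patch must be 64x64")
        if not np.isin(self.label_patch, (0, 1)).all():
            raise ValueError("label patch must be binary")


@dataclass
class ModelSpec:
    """Architecture and training hyperparameters.

    The architecture family is fixed (residual encoder-decoder); depth,
    width and the training schedule are the exposed knobs so the same
    code runs desk-scale and larger.
    """

    architecture_id: str = "uresnet-like"
    depth: int = 3
    base_channels: int = 8
    residual_blocks_per_level: int = 1
    loss_id: str = "bce"
    learning_rate: float = 1e-3
    epochs: int = 20
    batch_size: int = 32
    augment_flips: bool = True
    seed: int = 0


@dataclass
class TrainedModel:
    spec: ModelSpec
    weights: list[np.ndarray]
    training_subjects: list[str] = field(default_factory=list)
    training_loss_curve: list[float] = field(default_factory=list)

    def network(self) -> UResNet2D:
        net = UResNet2D(self.spec.depth, self.spec.base_channels,
                        self.spec.residual_blocks_per_level, self.spec.seed)
        net.set_weights(self.weights)
        return net


# ---------------------------------------------------------------------------
# Patch sampling


def _pad_to_patch(plane: np.ndarray) -> np.ndarray:
    h, w = plane.shape
    ph, pw = max(0, PATCH - h), max(0, PATCH - w)
    if ph or pw:
        plane = np.pad(plane, ((0, ph), (0, pw)))
    return plane


def sample_patches(volumes, n_patches: int, lesion_fraction: float = 0.5,
                   seed: int = 0) -> list[PatchSample]:
    """Draw 64x64 axial patches from ``(image, label, mask)`` triples.

    At least ``lesion_fraction`` of the returned patches contain a
    lesion pixel when the cohort has any; the remainder are drawn
    uniformly from in-brain axial positions.  Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    subjects = []
    lesion_voxels = []
    for i, (image, label, mask) in enumerate(volumes):
        sid = getattr(image, "subject_id", None) or f"v{i}"
        subjects.append((sid, image.data, label.data.astype(np.uint8),
                         mask.data.astype(np.uint8)))
        lv = np.argwhere(label.data > 0)
        lesion_voxels.append(lv)
    total_lesion = sum(len(lv) for lv in lesion_voxels)
    if total_lesion == 0 and lesion_fraction > 0:
        warnings.warn("cohort contains no lesion voxels; returning "
                      "background-only patches")
    n_lesion_target = int(round(n_patches * lesion_fraction)) \
        if total_lesion > 0 else 0

    weights = np.array([max(len(lv), 1) for lv in lesion_voxels], dtype=float)
    weights = weights / weights.sum()

    out: list[PatchSample] = []
    for k in range(n_patches):
        want_lesion = k < n_lesion_target
        if want_lesion:
            si = rng.choice(len(subjects), p=weights)
            while len(lesion_voxels[si]) == 0:
                si = rng.choice(len(subjects), p=weights)
        else:
            si = int(rng.integers(len(subjects)))
        sid, img, lab, msk = subjects[si]
        nx, ny, nz = img.shape
        if want_lesion:
            vx, vy, vz = lesion_voxels[si][rng.integers(len(lesion_voxels[si]))]
            z = int(vz)
            cx = int(np.clip(vx - rng.integers(PATCH),
                             0, max(0, nx - PATCH)))
            cy = int(np.clip(vy - rng.integers(PATCH),
                             0, max(0, ny - PATCH)))
        else:
            z = int(rng.integers(nz))
            cx = int(rng.integers(max(1, nx - PATCH + 1)))
            cy = int(rng.integers(max(1, ny - PATCH + 1)))
        ipatch = _pad_to_patch(img[cx:cx + PATCH, cy:cy + PATCH, z])
        lpatch = _pad_to_patch(lab[cx:cx + PATCH, cy:cy + PATCH, z])
        out.append(PatchSample(ipatch.astype(np.float32),
                               lpatch.astype(np.uint8), sid, z, (cx, cy)))
    return out


# ---------------------------------------------------------------------------
# Training


def train(spec: ModelSpec, patches: list[PatchSample]) -> TrainedModel:
    """Optimize the network on a patch set with Adam + pixelwise BCE.

    Deterministic given ``spec.seed`` (weight init, shuffling).  Raises
    :class:`TrainingError` on a non-finite loss or when no patch
    contains a lesion pixel.
    """
    if not patches:
        raise TrainingError("no patches supplied")
    if not any(p.label_patch.any() for p in patches):
        raise TrainingError("no lesion-containing patch in the training set")
    rng = np.random.default_rng(spec.seed)
    net = UResNet2D(spec.depth, spec.base_channels,
                    spec.residual_blocks_per_level, spec.seed)
    opt = Adam(net, lr=spec.learning_rate)
    lr0 = spec.learning_rate
    x = np.stack([p.image_patch for p in patches])[:, None].astype(np.float32)
    y = np.stack([p.label_patch for p in patches])[:, None].astype(np.float32)
    n = len(patches)
    bs = min(spec.batch_size, n)
    curve: list[float] = []
    subjects = sorted({p.subject_id for p in patches})
    for epoch in range(spec.epochs):
        # cosine decay to 10% of the initial rate over the schedule
        opt.lr = lr0 * (0.55 + 0.45 * np.cos(np.pi * epoch
                                             / max(1, spec.epochs - 1)))
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            xb, yb = x[idx], y[idx]
            if spec.augment_flips:
                flip = rng.random(len(idx)) < 0.5
                xb = xb.copy()
                yb = yb.copy()
                xb[flip] = xb[flip, :, :, ::-1]
                yb[flip] = yb[flip, :, :, ::-1]
            logits = net.forward(xb)
            loss, grad = bce_with_logits(logits, yb)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}: {loss}")
            net.backward(grad)
            opt.step()
            losses.append(loss)
        curve.append(float(np.mean(losses)))
    return TrainedModel(spec=spec, weights=net.get_weights(),
                        training_subjects=subjects,
                        training_loss_curve=curve)


# ---------------------------------------------------------------------------
# Inference


def predict_probability(model: TrainedModel, vol: ImageVolume,
                        mask: ImageVolume, overlap: int = 32,
                        _net: UResNet2D | None = None) -> ImageVolume:
    """Full-volume WML probability map from overlap-tiled 64x64 patches.

    Each axial slice is tiled with stride ``overlap`` (50% by default);
    per-pixel probabilities are the mean of all covering patch outputs.
    Values are in [0,1] and exactly 0 outside the brain mask.
    """
    net = _net or model.network()
    nx, ny, nz = vol.shape
    px = max(PATCH, -(-nx // overlap) * overlap)
    py = max(PATCH, -(-ny // overlap) * overlap)
    img = np.zeros((px, py, nz), dtype=np.float32)
    img[:nx, :ny, :] = vol.data
    xs = list(range(0, px - PATCH + 1, overlap))
    ys = list(range(0, py - PATCH + 1, overlap))
    if xs[-1] != px - PATCH:
        xs.append(px - PATCH)
    if ys[-1] != py - PATCH:
        ys.append(py - PATCH)

    acc = np.zeros((px, py, nz), dtype=np.float64)
    cnt = np.zeros((px, py), dtype=np.float64)
    batch, coords = [], []

    def flush():
        if not batch:
            return
        x = np.stack(batch)[:, None]
        probs = sigmoid(net.forward(x))[:, 0]
        for p, (cx, cy, z) in zip(probs, coords):
            acc[cx:cx + PATCH, cy:cy + PATCH, z] += p
        batch.clear()
        coords.clear()

    for cx in xs:
        for cy in ys:
            cnt[cx:cx + PATCH, cy:cy + PATCH] += 1
    for z in range(nz):
        for cx in xs:
            for cy in ys:
                batch.append(img[cx:cx + PATCH, cy:cy + PATCH, z])
                coords.append((cx, cy, z))
                if len(batch) >= 64:
                    flush()
    flush()
    prob = (acc / cnt[:, :, None])[:nx, :ny, :].astype(np.float32)
    prob *= mask.data.astype(np.float32)
    return vol.like(np.clip(prob, 0.0, 1.0), "probability")
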