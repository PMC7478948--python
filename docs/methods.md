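# Methods

## Problem and pipeline

White matter lesions (WML) are regions of chronic small-vessel damage in
cerebral white matter: bright on MRI-FLAIR, subtly hypodense on
non-contrast CT. The package estimates WML burden from CT by
cross-modality label transfer: each training subject's FLAIR-derived
binary lesion mask serves as the ground truth for a CNN that sees only
the (co-registered, intensity-normalized) CT. The pipeline is

brain extraction → spatial normalization → rigid CT→FLAIR registration →
z-scoring → patch CNN → repeated-CV ensemble → thresholding at 0.25 →
volumetry, Dice, correlation, Bland-Altman, Fazekas scoring.

## Volumes and transforms

All images are `ImageVolume`s: a 3D grid, voxel spacing in mm, and a
NIfTI-convention grid→world affine (0-based indices). Masks are {0,1}
uint8, probabilities float32 in [0,1]. Resampling is a pull-back:
`resample(vol, T, ref)` returns `vol(T(x))` on the reference grid, with
out-of-field voxels set to 0 (brain-extracted images are 0 outside the
head). Intensities are interpolated linearly, masks with nearest
neighbour — the source does not dictate this; it is this package's
choice. Rigid and 9-DOF affine transforms act about an explicit center
(the fixed image's grid center during registration), with Euler-xyz
rotations in degrees and translations in mm.

## Phantom generator

The generator emulates the study conditions the pipeline was built for:
paired volumes on a 64×64×24 grid at (2, 2, 4) mm — desk-scale, with the
anisotropy typical of 4–5 mm clinical slices. Each subject is an
ellipsoidal "brain" (semi-axis fractions 0.45/0.38/0.45 of the field of
view; the unequal in-plane axes both mimic head shape and leave no
rotational symmetry for registration to fall into), carrying:

- a smooth Gaussian tissue texture (σ = 3, 3, 1.5 voxels), gain 1.0 in
  the FLAIR channel and 0.8 in CT — modest tissue inhomogeneity that
  gives the multi-modal registration structure to lock onto while
  staying clearly below lesion contrast, as in real images where normal
  white matter varies less than a lesion's signal;
- quasi-spherical lesions (radius 3–9 mm) placed in the shell
  0.1 < ρ < 0.7 of normalized ellipsoid radius (the
  periventricular/deep white matter zone), with smooth intensity edges;
  the binary truth mask is the un-smoothed support;
- lesion contrast 5.0 (FLAIR) and 3.0 (CT) intensity units with additive
  Gaussian noise of SD 0.5 and 1.0 respectively. After in-mask
  z-scoring this makes FLAIR lesions ≈ 4σ events (unambiguous, as
  clinically) and CT lesions ≈ 1.9σ (detectable in aggregate, ambiguous
  per voxel) — the qualitative CT-harder-than-FLAIR ordering the
  cross-modality transfer must overcome;
- a rigid misalignment of the CT channel, rotations ≤ 5° and
  translations ≤ 4 mm, plausible head repositioning between scans. The
  stored `true_misalignment` is the transform that re-aligns the CT to
  the FLAIR grid.

Lesion load is stratified by Fazekas group into disjoint intervals
0–2 / 5–15 / 25–60 mL. No clinical per-group volume ranges were
available to anchor these; they were fixed once as monotone,
well-separated strata. Blobs are added until a target volume drawn from
the group interval is reached, shrinking the final blob so the interval
is not overshot (discretization can still overshoot by a voxel shell).

What the phantoms do **not** contain: real anatomy (gyri, ventricles),
CT artifacts (beam hardening, streaks), lacunes or microbleeds, partial
volume at tissue interfaces, or scanner-dependent intensity scales.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and self-consistent at realistic noise/contrast ratios — not
that clinical accuracy transfers.

## Preprocessing

**Brain extraction** is an Otsu threshold followed by morphological
closing, hole filling and largest-connected-component selection — a
stand-in for dedicated clinical skull-stripping tools, adequate for
phantoms and smoke tests on real data.

**Spatial normalization** registers the subject's binary brain mask to a
template mask with a 9-parameter affine (3 rotations, 3 translations,
3 scales). Both masks are Gaussian-smoothed (σ = 2, 2, 1 voxels) and the
mean squared difference is minimized — a smooth surrogate for mask
overlap; the reported metric is the Dice of the aligned binary masks.
Initialization matches mask centroids; failure to reach the identity
baseline sets `converged=False` rather than silently returning a wrong
answer.

**Rigid CT→FLAIR registration** maximizes normalized mutual information
NMI = (H(F) + H(M)) / H(F, M) over a 32×32 joint histogram. Numerical
choices: the histogram is built over at most 20 000 points sampled from
the dilated head region of the fixed image; fixed-image bins are
precomputed; the moving intensity is soft-binned (linear interpolation
between adjacent bins) so the cost is smooth under sub-voxel motion.
Optimization is Powell's method, coarse-to-fine over a 2-level pyramid
(downsampling factor 2), preceded by centroid matching and a coarse
3×3×3 rotation grid search at ±4°, and followed by a second Powell pass
at full resolution that restarts the direction set (this recovers the
occasional stalled search). Iterations are capped at 200 per level.
On default phantoms this recovers simulated misalignments with median
errors well under 1° and 1 mm in ~3 s per pair on one CPU.

**Intensity normalization** z-scores within the brain mask using the
population (n) SD — a convention fixed for reproducibility; out-of-mask
voxels are set to 0. Zero in-mask variance is an error, not a NaN. CT
intensities are not windowed before z-scoring; clinical deployments may
prefer an HU window first.

## Segmentation network

A residual encoder–decoder over single-channel 64×64 axial patches:
stem convolution, then per level one residual block
(conv–ReLU–conv–add–ReLU) and a 2×2 max-pool + 3×3 convolution doubling
the channels; the decoder mirrors with nearest-neighbour upsampling and
additive skip connections; a 1×1 head yields one logit per pixel. With
the default `ModelSpec` (3 levels, 8 base channels) this is a
deliberately narrow member of the U-shaped residual family, sized for
CPU training. Patches are 2D because 4–5 mm slices make 3D kernels
ill-posed at this resolution.

Training: pixelwise binary cross-entropy (the probability-vs-binary-mask
error), Adam at 1e-3 with cosine decay to 10%, batch 16–32, horizontal
flip augmentation, 20 epochs by default. Patch sampling draws half of
the patches centered near lesion voxels (subjects weighted by lesion
count) and half uniformly — without the lesion half, the ~1% foreground
rate stalls learning. All randomness (sampling, initialization,
shuffling, flips) derives from one seed recorded in the model artifact;
inference is deterministic.

The convolution forward/backward passes are numba-compiled scalar
loops; at 8–32 channels these outperform BLAS-backed im2col on one CPU
by avoiding the column-matrix materialization.

Inference tiles each axial slice with 50%-overlapping patches and
averages the sigmoid outputs of every patch covering a pixel; the map is
zeroed outside the brain mask. Volumes smaller than one patch are
zero-padded, never rejected.

## Repeated cross-validation ensemble

Subjects are dealt into k folds (default 10; 3 in the desk-scale runs);
per repetition, one model per fold is trained on the out-of-fold
subjects and predicts its test fold, so every subject is segmented by
models that never saw it. The whole cross-validation is repeated R times
(default 10; 3 at desk scale) with re-randomized fold membership *and*
re-initialized weights — both, since re-randomizing only one of the two
is a weaker ensemble. Per-subject maps are averaged arithmetically and
thresholded at 0.25 with an **inclusive** ≥ comparison (a convention
that had to be fixed). Fold assignment is stratified by Fazekas group by
default — at desk scale an unstratified split can produce training folds
with no severe subject — via a shuffle-within-stratum round-robin deal
that also keeps global fold sizes within 1 of each other (plain
per-class splitting does not). Per-(repetition, fold) seeds derive
deterministically from the plan seed.

## Evaluation

- **Dice** `2|X∩Y|/(|X|+|Y|)` with the correct/incorrect volume
  decomposition (|X∩Y|, X-only, Y-only, all in mL). Dice of two empty
  masks is defined as 0 and flagged `both_empty` — the formula is
  undefined there.
- **Volume agreement**: Pearson r, plus slope/intercept from ordinary
  least squares of CT volume on FLAIR volume (the regression direction
  had to be chosen; CT-on-reference is used and documented).
- **Bland-Altman**: CT−FLAIR differences, limits of agreement
  mean ± 1.96·SD with population SD.
- **Fazekas estimation**: two volume cut points (t_low, t_high) scoring
  v < t_low → 0–1, v < t_high → 2, else → 3, fitted by exhaustive search
  over midpoints of consecutive distinct sorted volumes plus 0/∞
  sentinels (a finite candidate set equivalent to all achievable
  classifications), ties broken toward the lexicographically smallest
  pair. Reported accuracy comes from 10-fold cross-validation:
  thresholds fitted per training split, applied to the held-out split,
  accumulated into a 3×3 confusion matrix (rows visual, columns
  automatic); accuracy = trace/total, reported to 2 decimals.

## Problem sizes

The test suite and the acceptance script run the full pipeline on a
45-subject cohort (15 per group), 3 folds × 3 repetitions, 160 training
patches per model, 20 epochs — sizes chosen so a complete run takes
roughly a quarter hour on a single CPU while still exercising every
stage at realistic difficulty. Larger cohorts, 10×10 cross-validation
and wider models are plain parameter changes.

## Known limitations

- Phantom realism bounds what green tests prove (see above); clinical
  accuracy requires clinical data.
- The Fazekas volume classifier presumes volume is monotone in visual
  grade; rater disagreement and non-volumetric cues are out of scope.
- The NMI registration assumes overlapping fields of view and a rigid
  relation; no deformable correction is attempted.
- Training at desk scale uses a few hundred patches; the loss surface is
  benign for blob-like lesions, but heavily textured real data would
  need more data and epochs.
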