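# Methods

This note documents the models, procedures and numerical choices behind
`cavityseg`, in the spirit of the methods appendices that accompany
scientific software: what is computed, under which assumptions, with which
defaults, and what the synthetic test bed does and does not demonstrate.

## Problem and pipeline

Postsurgical T1-weighted brain MRI of epilepsy patients contains a resection
cavity — a CSF-filled, strongly hypointense void. The package segments that
cavity automatically and quantifies which brain regions were removed. The
pipeline is a 2.5D ensemble:

1. **Canonicalization** — every volume is reoriented to RAS+ (right/
   anterior/superior), a pure re-indexing that preserves world coordinates.
   Plane names are defined against this frame: axial slices along the third
   axis, coronal along the second, sagittal along the first.
2. **Normalization** — per-volume min–max mapping to [0, 1]. A constant
   volume normalizes to zeros with a warning rather than an error.
3. **Slicing** — each plane is cut into 2D slices, center-padded with zeros
   to square (preserving anatomy's aspect ratio rather than stretching), and
   linearly resampled to the network resolution (default 256; the desk
   configuration uses 64, native for the test phantoms so no resampling
   occurs). The per-slice transform log makes the mapping invertible in
   shape; predictions are inverse-resized, inverse-padded, stacked and
   thresholded at 0.5. Empty slices are kept in training data so the network
   learns to emit empty masks on cavity-free slices — required for correct
   behavior on control subjects.
4. **Per-plane segmentation** — one 2D encoder–decoder (U-Net) per plane,
   trained independently.
5. **Fusion and post-processing** — the three reassembled 3D binary masks
   are fused per voxel by majority vote (keep iff ≥ 2 of 3 models agree),
   then cleaned by connected-component analysis, then screened: if the
   surviving volume is below 0.5 ml the result is "no resection detected"
   and the mask is emptied. The 0.5 ml default corresponds to 500 voxels at
   1 mm isotropic; the threshold is expressed in ml so it remains meaningful
   on anisotropic grids.
6. **Remnant quantification** — a parcellation aligned to the postoperative
   image is intersected with the resection mask; per region,
   resected = |region ∩ resection| voxels and remnant = total − resected.
   Registration is out of scope: inputs must share a voxel grid exactly, and
   mismatches fail loudly. Resection voxels on background (label 0) are
   reported as "unassigned" so volume is conserved and auditable.

## The network and its training

No deep-learning framework is a dependency: the 2D network and its training
loop are implemented in NumPy inside the package (`cavityseg/_nn.py`).
Convolutions are channels-last 3×3 same convolutions computed as nine
shifted BLAS matmuls, with analytic backward passes verified against central
finite differences in float64 (see `tests/test_nn.py`). The architecture is
a depth-configurable U-Net: `encoder_depth` levels of conv-ReLU + 2×2 max
pool, a bottleneck conv, and mirrored nearest-upsample + skip-concat +
conv-ReLU levels, ending in a 1×1 conv and sigmoid.

Training protocol (TrainConfig defaults): Adam, learning rate 1e-4, batch
size 16, 50 epochs, augmentation with random horizontal/vertical flips,
rotations up to ±10°, and shifts up to ±10% of each image dimension. The
same geometric transform is applied to image (linear interpolation) and mask
(nearest; masks stay binary); out-of-bounds regions fill with 0. The loss is
batch-global soft Dice (`loss_name="dice"`; `"bce_dice"` adds mean binary
cross-entropy) — chosen because model selection is DSC-driven, so a
Dice-aligned loss is the consistent objective. Model selection keeps the
parameter state of the epoch with the highest validation DSC (global Dice
over all validation slices); without a validation set the lowest-train-loss
epoch is kept. All randomness — initialization, batching, augmentation —
flows from the single config seed, so training is reproducible on a fixed
thread count.

Cross-validation uses subject-level splits: `make_folds` shuffles subjects
once, partitions them into k test groups, and assigns each fold's validation
set as the next fold's test group, producing 3:1:1 train/val/test splits
(27/9/9 for 45 subjects at k = 5) in which every subject is tested exactly
once and no subject's slices ever appear in two sets.

`fine_tune` continues optimization from an existing model's weights (no
re-initialization) under a new config — the mechanism for adapting a trained
model to a new lesion distribution. `pretrained_encoder` is accepted in the
config contract but no pretrained weights are bundled; setting it raises
immediately rather than silently training from scratch.

### Desk-scale configuration

`desk_config()` is the CPU-scale variant used by the tests and the
reproduction script: 64×64 slices (native for 64³ phantoms), encoder depth 2
with 8 base channels, 10 epochs, learning rate 1e-3. The higher rate is the
standard choice for training a small network from scratch; the 1e-4 default
belongs to the full protocol where an ImageNet-scale encoder is merely
adapted. Training all three planes on a 20-phantom cohort takes a few
minutes on one CPU.

## Evaluation metrics

* **DSC** = 2|X∩Y|/(|X|+|Y|), X manual, Y automated. Defined as 1.0 when
  both masks are empty (perfect agreement on absence — needed for control
  subjects) and 0 when exactly one is empty. The paper-silent both-empty
  case is a deliberate convention.
* **HD95**: several Hausdorff variants exist in the literature; the one
  implemented is the symmetric max of the two directed 95th-percentile
  boundary-to-boundary distances, the variant used by the large segmentation
  challenges. Boundary voxels are foreground voxels with ≥ 1 background
  6-neighbor (array edges count as background); distances are Euclidean
  between voxel centers in mm using the voxel spacing (exact distance
  transform); percentiles use linear interpolation, stated here because it
  affects cross-platform determinism. Undefined (NaN, with a warning) when
  either mask is empty; cohort summaries exclude and count such cases.
* **Volumes**: foreground count × voxel volume, in ml. **PVD** =
  |pred − true|/true × 100, with the manual volume as denominator since PVD
  is an error measure of the prediction; undefined for empty truth.
* **Detection**: a resection subject is a false negative iff the screened
  prediction has *no overlap* with the truth (an overlap criterion, not a
  DSC threshold); a control subject is a false positive iff anything
  survives screening.
* **Cohort summaries** report median/IQR/mean/SD for DSC and HD95, Pearson r
  and MAE between true and predicted volumes, and FN/FP counts.
  **Size stratification** splits subjects at 17.92 ml of true resection
  volume (the small/large lesion threshold from the prior literature) and
  compares group means with Welch two-sample t-tests.

## The phantom generator

`phantom.py` generates the synthetic study conditions: a brain-like
ellipsoid (semi-axes 26×30×24 mm) on a 64³ grid at 1 mm isotropic, with a
white-matter interior (intensity 0.75), a cortex shell (0.55, outer 15% of
the normalized radius), two CSF-dark ventricles (0.2), and additive Gaussian
noise (SD 0.03, clipped to [0, 1]) — the simplest intensity model that
exercises normalization, learning, and the cavity/ventricle/background
confusions that matter. The resection cavity is an ellipsoid of configurable
center and radius whose voxels are set to 0.05 (CSF-like) before noise; the
ground-truth mask is exactly that voxel set. Failure-mode artifacts mirror
the error sources seen in clinical practice: a hyperintense inclusion
(intensity 0.95, emulating blood products or ablation necrosis) strictly
inside the cavity, and a thin (1-voxel-radius) hypointense surgical tract
from the cavity surface to the brain surface whose voxels are *added* to the
ground truth, matching the manual-segmentation convention for tracts.

Cohorts draw cavity radii uniformly from 7–18 mm (≈1.4–24.4 ml), spanning
both sides of the 17.92 ml stratification threshold and representative of
the clinical range from selective procedures (a few ml) to lobectomies
(tens of ml); cavity centers are drawn uniformly within the margin that
keeps the cavity inside the brain. Everything is reproducible from one seed
via spawned seed sequences.

The toy parcellation divides the brain interior into 8 octant regions with
pseudo-anatomical names plus an interior "hippocampus" ellipsoid (9×7×6 mm)
at the default cavity site, so hippocampal remnant estimation is exercised
with known geometry. `analytic_region_overlap_pct` recomputes a region's
cavity overlap from the continuous ellipsoid geometry on an oversampled
grid, giving a voxelization-independent reference for the remnant tests.

**What the phantoms do not emulate**: MRI physics (bias fields, partial
volume, gyral texture), gliosis and brain shift, real anatomy, multi-site
contrast differences. Passing the phantom study therefore demonstrates that
the pipeline's machinery — slicing, training, fusion, screening, metrics,
reporting — is correct and that the network can learn a contextual
hypointensity-inside-brain concept; it does not certify clinical accuracy,
and the clinical headline numbers of the original study are not reproducible
at this scale.

## Reproduction study sizes

`scripts/acceptance.py` runs the whole study at desk scale: 25 phantoms
(16 train / 4 validation / 5 held-out test) plus 5 controls, 10 epochs per
plane at 64×64 — sizes chosen so the full study trains and evaluates in
minutes on a single CPU while leaving enough held-out subjects for stable
summary statistics.

## Known limitations

* The NumPy network is intentionally small; it is not a drop-in replacement
  for an EfficientNet-encoder U-Net and no pretrained weights are provided.
* `component_mode="largest"` assumes one contiguous resection site (the
  training-cohort inclusion criterion); use `"min_size"` for multi-site
  cases.
* HD95 is computed between voxel centers, not sub-voxel surface meshes.
* The remnant stage trusts the caller's registration; it verifies geometry
  equality only.
* Determinism holds for fixed BLAS threading; run single-threaded for
  bit-exact reproduction across machines.
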