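# Methods

This note documents the models and procedures implemented in `petlymph`,
the parameters that matter, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## Reference segmentation protocol

Training labels and evaluation references are produced the way PET-avid
lymphoma is labeled clinically with semi-automatic tools: a loose
template ROI is placed around each diseased region, and within each ROI
the segmentation is the union of

* an absolute threshold, `SUV > 2.5` (strict inequality, g/ml), and
* a relative threshold, `SUV ≥ 0.40 · SUV_max`, with SUV_max computed
  **per template ROI** (non-strict, so the hottest voxel is always
  included).

The absolute rule exists to rescue small, low-uptake lesions that share
an ROI with a hot lesion and would fall below the relative cut. After
merging all ROIs, 26-connected components smaller than 2 voxels are
removed (1-voxel islands are a thresholding artifact). One island-removal
pass after the merge, rather than per ROI, is a deliberate choice; at
2 voxel minimum size the two orders differ only for islands that touch
across ROI boundaries.

On blur-free, noise-free phantoms whose background stays below every
ROI's 40% cut, this protocol is an exact identity on planted disease;
the test suite asserts voxel-exact recovery and exact MTV/SUV_max/TLG.

## Image model and preprocessing

Volumes are 3D scalar grids with axis-aligned world frames
(`world = origin + index · spacing`); oblique NIfTI affines are rejected
rather than silently reoriented. PET is carried in body-weight SUV;
an activity volume (Bq/ml) can be converted given dose, weight and
post-injection time (dose decay-corrected with the F-18 half-life,
109.77 min).

Preprocessing for the network:

* resampling to 2 mm isotropic voxels — linear for images, nearest
  neighbour for labels; output size `ceil(extent/2)` per axis, world
  origin preserved, edge-value extension outside the field of view;
* a CT-derived body mask: largest 26-connected component of
  `HU > −500`, holes filled (−500 excludes air but keeps lung);
* z-scoring of each channel against body-mask statistics (population
  mean/variance, so normalization is idempotent). CT is clipped to
  [−1000, 1000] HU before normalization to bound the influence of
  implants; the clip applies only to the network-input copy, never to
  the HU volume used for bone exclusion. PET and CT are normalized
  independently — whether a joint or separate normalization was used
  clinically is not documented anywhere we could follow, and separate
  per-channel scaling is the standard choice.

## Network

A multi-resolution-pathway 3D patch CNN in the DeepMedic family:

* per pathway: 8 valid (unpadded) 3×3×3 convolutions; default feature
  counts (90, 90, 110, 110, 110, 110, 130, 130); leaky-ReLU (slope 0.1);
* pathways at downsampling factors (1, 3, 5); coarse pathways see
  block-averaged input, their outputs are upsampled by nearest-neighbour
  repetition and aligned with the full-resolution output tile;
* concatenated pathway features pass through two 1×1×1 "fully connected"
  layers (250 features) and a 2-class per-voxel softmax;
* a 25³ input segment yields a 9³ output tile (2 voxels lost per valid
  convolution).

**Coarse-grid alignment.** The coarse grid of every down-sampled pathway
is anchored at the volume origin: cell `j` always covers voxels
`[k·j, k·j + k)`. Training patches and dense inference use the same
anchoring, so dense (fully convolutional) inference is *exactly* equal to
tiled inference for any tiling — an invariant the tests assert. The cost
is that the coarse context of an output voxel can be off-centre by up to
k−1 voxels (≤ 8 mm at k = 5); for a context pathway summarizing a
57–90 mm receptive field this is immaterial, and it buys an unambiguous,
testable correspondence between training and inference.

**Training.** Patches are class-balanced: 50% centred on a
reference-positive voxel, 50% on a body voxel outside the reference
(restricting negatives to the body avoids spending capacity on air).
Out-of-volume context is edge-padded by clamped indexing. Loss is
voxelwise cross-entropy over the output tile; the optimizer is Adam
(lr 10⁻³). When a validation set is supplied, the weights from the epoch
with the lowest validation loss are restored at the end. All randomness
(initialization, patch sampling) derives from the config seed; training
is reproducible bit-for-bit on the same machine.

The implementation is pure NumPy: convolutions are computed as k³
accumulated shifted matrix products (both forward and for input
gradients), which avoids the 27-fold im2col blow-up and is what makes
whole-volume CPU inference practical (≈2 s for a 64³ volume with the
small configuration below).

**Inference.** Each pathway is evaluated fully convolutionally over the
edge-padded volume (chunked along the first axis for memory); the
per-voxel head then produces the lymphoma-class probability. Voxels
outside the body mask are set to 0. An explicit tiled path
(`tile_size=...`) exists and produces the same probabilities.

## Ensemble post-processing

Three networks are trained from different random initializations. Each
probability map is binarized at the cut point (default p ≥ 0.5), then
**refined**: within each 26-connected predicted contour, the clinical
threshold scheme (union of `SUV > 2.5` and `SUV ≥ 40%` of the *contour's*
SUV_max) is re-applied. The voxelwise intersection of the three refined
masks is the ensemble output; requiring unanimity is the mechanism that
removes isolated false positives, since a spurious contour proposed by
one member rarely survives all three. Finally, components dominated by
bone are removed: a component is dropped when more than `bone_fraction`
(default 0.5) of its voxels have `CT > 150 HU`. The fraction is
configurable because an any-voxel reading (`bone_fraction = 0`) deletes
true lesions abutting vertebrae; bone exclusion is applied to the mask
itself so that every downstream feature sees the same final segmentation.

Set-theoretic consequences asserted by the tests: the final mask is a
subset of every refined member mask; false-positive voxels never exceed
the best member's; predicted volume and sensitivity are non-increasing in
the cut point.

## Features

From a binary mask and the SUV volume:

* `SUV_max` (g/ml) — maximum over mask voxels (absent for empty masks);
* `MTV` (cm³) — voxel count × voxel volume;
* `TLG` (SUV·cm³) — Σ SUV × voxel volume = SUV_mean · MTV;
* surface area (cm²) — exposed voxel faces (6-neighbourhood, including
  the volume border) × face area, over all components jointly. Face
  counting is exact and oracle-checkable but overestimates a smooth
  surface by up to ~1.5×; a marching-cubes mesh estimate is available
  (`method="mesh"`) for sensitivity analysis;
* `SA/MTV` (cm⁻¹) — absent when MTV = 0;
* `Dmax_patient` (cm) — lesions are 26-connected components; the default
  measures the largest centroid-to-centroid distance in world
  coordinates (0 with fewer than two lesions), with a boundary-voxel
  variant behind a flag.

## Evaluation and statistics

DSC, sensitivity and PPV are computed voxelwise; when both masks are
empty the scores are flagged undefined rather than forced to a value.
Feature agreement uses Pearson's r and the median/IQR of relative percent
differences `100·(auto − ref)/ref` (pairs with a zero reference are
dropped and flagged). SUV_max agreement additionally counts exact matches
(relative tolerance 10⁻⁶ — "exact" means the same hottest voxel was
selected). Quantiles use linear interpolation between order statistics
throughout. Subgroup analysis splits the cohort at the median of a
feature (ties to the low group) and compares DSC and |MTV RPD| with
two-sided Wilcoxon rank-sum tests — exact null distribution when both
groups have ≤ 25 tie-free observations, normal approximation with tie
correction otherwise.

Cross-validation partitions cases into folds of near-equal size
(difference ≤ 1); per fold, the remaining cases are split 7:1 into
training and validation. The clinical-scale description of that split is
internally inconsistent in places (the held-out fold is evidently the
20-case set); the standard 20 test / 70 train / 10 validation reading is
implemented.

## Phantom generator

Each phantom is a body ellipsoid (soft tissue, 40 HU) in air (−1000 HU)
on a 64³ grid at 2 mm, with:

| parameter | default | meaning |
|---|---|---|
| `n_lesions` | 2–5 | ellipsoidal lesions per case |
| `lesion_radius_mm` | 4–12 | per-axis semi-axes |
| `lesion_suv` | 3–15 | uniform uptake per lesion (pre-blur) |
| `background_suv` | 0.5–1.5 | uniform body background |
| `n_benign_hot` | 1–3 | benign hot structures, SUV 2.5–8, 3–5 mm |
| `bone_structures` | 1 | spine-like cylinder, 400 HU |
| `psf_fwhm_mm` | 6 | isotropic Gaussian PSF |
| `noise_sigma_suv` | 0.2 | additive Gaussian PET noise |
| `ct_noise_hu` | 5 | additive Gaussian CT noise |

The PSF width approximates clinical whole-body PET of the study era;
noise is Gaussian in SUV space (post-reconstruction noise is
approximately Gaussian, and it keeps the generator simple and exactly
seedable), clipped at zero. Benign hot structures are placed outside all
template ROIs and act as false-positive bait for the ensemble; lesions
are never planted inside bone or benign structures. Template ROIs are
lesion bounding boxes dilated by 3 voxels, merged when they overlap —
so a cold lesion can share an ROI with a hot one, exercising the rescue
rule. The reference mask is built from the *observed* (blurred, noisy)
PET, as clinical labels would be; the planted pre-blur geometry is kept
separately as exact ground truth.

What the phantoms do **not** emulate: anatomical texture and organ-level
context (heart, bladder, brain uptake), respiratory motion, scanner
harmonization differences, non-uniform intratumoral uptake, osseous
involvement. Passing the synthetic experiments therefore demonstrates
the correctness of the pipeline's mechanics and its behaviour under
blur/noise — not clinical-grade accuracy on patients.

## Desk-scale experiment sizes

The learning experiments and the acceptance script use a deliberately
small configuration chosen to fit a single CPU: two pathways (factors
1, 3), conv features (8, 8, 12, 12, 12, 12, 16, 16), 32 fc features,
25³ patches, 8 epochs × 8 batches × 8 segments, 20 training phantoms
(2 of them as validation), 5–10 held-out phantoms. Under these
conditions a 3-member ensemble reaches median held-out DSC ≈ 0.78–0.81
with median false-positive volume 0 after intersection; single members
leave ~0.5–1 cm³ of false positives, which is the ensemble's main
contribution — the same mechanism reported for the clinical-scale
system. Numbers at this scale are stochastic across seeds and should be
read as behaviour demonstrations, not performance claims.

## Known limitations

* Gradient computations are float32; deep finite-difference checks agree
  at layer level but accumulate ordinary float noise through the full
  network.
* The NumPy network is single-threaded BLAS-bound; clinical-scale
  configurations (three pathways, 90–130 features, thousands of
  segments) are out of reach on one CPU and untested at that scale.
* Bit-for-bit determinism is guaranteed for reruns on the same
  machine/BLAS; across different BLAS builds, results agree only to
  float tolerance.
* `Dmax_patient` uses lesion centroids; for very large lesions the
  boundary-to-boundary variant can differ substantially.
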