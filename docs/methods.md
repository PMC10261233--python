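# Methods

This note records the models, parameter choices and numerical decisions
behind `cacforge`, and what the phantom-based validation does and does
not demonstrate.

## Quantification model

A non-contrast cardiac CT slice containing coronary calcium is treated
as the sum of a calcium-free image and a nonnegative calcium image (the
CAC-map). Because paired scans of the same heart with and without
calcium do not exist, the decomposition is learned from *unpaired*
examples with a CycleGAN: a removing generator G_Rem predicts a map and
subtracts it (CAC → noCAC), a synthesizing generator G_Syn predicts a
map and adds it (noCAC → CAC), and two patch discriminators judge
whether translated slices resemble real members of the target domain.
The decomposition identity (input = counterpart + map) is exact by
construction, and map nonnegativity is architectural (softplus output).

Calcium is then quantified as **pseudomass**: the sum of the *original*
image values over the calcium area indicated by the map, times the
voxel volume (HU·mm³). "Multiplied by the voxel spacing" is read as
voxel *volume* dx·dy·dz — pseudomass is an uncalibrated mass and mass
integrates over volume. Reading intensities from the original image
(not the map) keeps the score comparable with threshold-based scoring
where both work, while still counting lesion voxels whose HU fell below
130 through motion and partial-volume averaging. Negative HU inside a
lesion area is clipped to zero. No HU-to-mg calibration is attempted;
scores are comparable within a fixed acquisition, which is all the
within-study statistics need.

Continuous risk is `vis = α·log_β(γ·mass) − δ` for mass > 0, else 0.
β and γ are not identifiable jointly with α and δ (log_β(γm) is affine
in ln m), so `calibrate()` fixes β = 9 and γ = 1 and fits α, δ by least
squares of category on log mass. The printed rest/stress presets are
shipped for forward evaluation only — they live on the source study's
pseudomass scale, so any new data (including phantoms) must be
re-calibrated. The continuous score is mapped to the five Agatston risk
categories by round-half-up then clamping to [1, 5]; zero mass is
always category I. Rounding is the natural inverse of a calibration
against integer visual scores 2–5; the mapping is a package convention.

## Networks and training

All networks run on a small tape-based numpy autodiff core
(`cacforge.nn`): float32, seeded, single-threaded — training runs are
bit-reproducible. Convolutions are kernel-offset GEMMs on a
channels-last copy. Architectures are deliberately tiny (thousands of
parameters): the phantom task needs contrast detection, not semantic
understanding, and toy training must fit CPU minutes.

* **Heart segmenter** (3-D): conv(1→8) → residual block → conv(8→1) →
  sigmoid; soft-Dice *plus* voxel-wise cross-entropy (Dice alone is
  degenerate on foreground-dominated patches) on 16×32×32 patches, half
  of them centred on heart voxels; Adam, lr 1e-3, 250 steps. Output is
  thresholded at 0.5, reduced to the largest connected component, holes
  filled.
* **Slice classifier** (2-D): two strided convs → residual block →
  global *max* pooling → linear → sigmoid, cross-entropy on
  class-balanced batches with flip/rotation/translation augmentation;
  1500 steps with linear lr decay over the second half. Max pooling
  matters (the lesion signal is a small bright region, which average
  pooling dilutes below the noise), and so does the augmentation: a few
  hundred training slices are memorized otherwise and faint held-out
  lesions are missed.
* **Decomposition CycleGAN**: residual generators (conv(1→8), two
  residual blocks, conv(8→1), softplus) and PatchGAN discriminators
  (two strided convs + 1-channel patch head). Least-squares adversarial
  loss with per-patch terms *and* slice-level extremum terms — the patch
  map is pooled with max for the CAC domain (calcium evidence is the
  strongest patch) and min for the noCAC domain (one contaminated patch
  betrays a fake). With plain per-patch averaging, neither
  discriminator learns at this scale: informative patches are a few
  percent of all patches and their gradient drowns. Cycle-consistency
  L1 at weight 10; an identity term |G_Rem map on real noCAC slices| at
  weight 5 expresses the contract that calcium-free slices decompose
  into themselves plus an empty map (without it, clean slices leak map
  mass). Adam at lr 3e-4 for toy runs (the full-scale default remains
  1e-4), constant for the first half then decayed linearly to 5%;
  inference uses an exponential moving average (decay 0.998) of the
  generator weights. Both decay and averaging address the oscillation
  of the adversarial equilibrium, which otherwise makes the endpoint a
  lottery over seeds.

Intensity windows: the ROI networks normalize HU with a soft-tissue
window (−200, 200) → [−1, 1]; at a full CT window the 45 HU
heart/body contrast is ~2% of the input range and the toy segmenter
does not learn. The decomposition uses (−200, 400), wide enough for
degraded CTAC lesion intensities (rarely above ~300 HU) while keeping
lesion/tissue contrast large; its maps convert back to HU through the
same linear window. Windows are package constants, documented here
because they are a deliberate departure from using one display window
everywhere.

Slice gating at inference: a slice contributes to the CAC-map only if
the classifier calls it positive *and* voxels lie inside the heart
mask; maps are zeroed outside the heart. Generators run on a 64×64
heart-centred crop; the map is pasted back and masked afterwards.

## Threshold scoring

The clinical reference path forms lesions as 26-connected components of
HU ≥ 130 inside the heart; per-slice areas use in-plane
8-connectivity. Components in which no single slice reaches 1 mm² are
dropped (classic minimum-lesion convention). Agatston score = Σ over
lesions and slices of area × weight, weights 1/2/3/4 for slice-maximum
HU 130–199/200–299/300–399/≥400. No slice-thickness correction factor
is applied; scores are computed on whatever grid the volume is on.
The map-based and threshold-based routes coincide exactly when the map
is defined as HU·[HU ≥ 130] on a noise-free volume (tested).

## Agreement statistics

* ΔR = |a−b| / (½(a+b)), reported in percent; symmetric,
  scale-invariant, bounded by 200%. Both-zero pairs contribute 0%
  (perfect agreement on absence) — a flag excludes them instead;
  "concordant" restricts to pairs positive in both scans.
* Bland–Altman with heteroscedastic limits: bias b is the plain mean
  difference (the estimator is a package convention); the spread
  coefficient a is the zero-intercept least-squares slope of |d − b| on
  √mean; limits are b ± 1.96·√(π/2)·a·√mean. The √(π/2) factor undoes
  the half-normal shrinkage: |d − b| has mean σ·√(2/π) when
  d ~ N(b, σ²), so the fitted slope times √(π/2) estimates σ per √mean.
  Recovery and ~95% coverage are verified by simulation at n = 10⁴.
* Detection metrics at patient level; undefined quantities (e.g.
  sensitivity with no reference positives) are reported as missing,
  never as 0.
* Linearly weighted kappa, weights w_ij = 1 − |i−j|/(k−1), k = 5, with
  a delta-method asymptotic 95% CI (Fleiss–Cohen–Everitt form). The CI
  method is a package choice.

## Phantoms

Each case is one thin-slice CSCT-like volume (0.4 mm in-plane, 2.5 mm
slices) plus rest and stress CTAC-like volumes (1.17 mm, 5.0 mm)
derived from it. Anatomy is schematic: body at 0 HU, two lungs at
−800 HU, a heart ellipsoid (semi-axes ≈ 26/24/30 mm) of 30–60 HU tissue
with ±20 HU smooth texture — enough contrast for segmentation to be
learnable, with no claim of anatomical realism. Lesions are ellipsoids
(1.5–6 mm extents) with a quadratic radial profile and peak HU in
150–800, placed at 0.55–0.85 of the heart radius (a crude surrogate for
the epicardial course of the coronaries) without overlap. Ground truth
is exact: the inserted-HU field is stored, per-lesion pseudomass is its
voxel sum times voxel volume, and the clean-volume Agatston score is
computed by the scoring module.

The CTAC degradation chain is anisotropic Gaussian blur (motion
surrogate, default σ = 0.8/0.8/1.2 mm), box averaging of 2.5 mm slices
to 5 mm, in-plane resampling to 1.17 mm, then additive Gaussian noise
(σ = 20 HU). The blur severity is a free parameter with no clinical
calibration claim; the default was chosen so that, across cases, the
largest lesions remain above 130 HU after degradation while small ones
fall below — the partial-volume regime the threshold-free method
exists for. Rest and stress differ only in their noise/seed draws.
Because blur and averaging are linear, the inserted-HU field is pushed
through the same (noise-free) chain, giving exact per-slice truth
masses on the degraded grid.

Per-slice truth labels: a slice is CAC-positive when the degraded
inserted field reaches 50 HU, confidently clean below 10 HU; slices in
between are ambiguous and excluded from classifier/decomposition
training and from accuracy counts, mirroring an annotator who labels
only confident slices.

**What passing phantom tests shows** — that the implementation of every
stage is correct and that the decomposition mechanism recovers
additively inserted, spatially coherent bright lesions from degraded
images with quantitative fidelity (map mass vs. truth r ≥ 0.8 at desk
scale). **What it does not show** — performance on real CTAC: real
motion is displacement, not blur; real anatomy has confounders
(aortic/valvular calcium, stents, noise structure); and the published
patient-level agreement numbers live on cohorts this package cannot
reproduce. Those numbers are therefore *not* asserted anywhere in the
test suite.

## Problem sizes and numerics

Toy experiments use phantom cohorts of ~16 training and ~14 held-out
cases (64×64 heart crops, ~100–150 CAC slices and ~300 clean slices),
CycleGAN training of 2–3k iterations at batch 4, and ROI training of a
few hundred steps — sizes chosen so the whole chain, including
training, runs in minutes on a single CPU while leaving the recovery
criteria comfortably attainable. Degenerate inputs are contracts, not
corner cases: empty training sets, single-class labels, all-background
masks, misaligned grids, empty segmentations and non-finite losses all
raise immediately. HU is clipped to [−1024, 3071] at construction and
after interpolation; linear interpolation is used for images and
nearest-neighbour for masks; resampled dimensions follow
round(n·spacing/target).

## Known limitations

* The CycleGAN is trained at toy scale; its map quality ceiling on
  phantoms (r ≈ 0.8–0.9) reflects that scale, not the method's
  large-scale behaviour.
* Pseudomass is uncalibrated; cross-scanner comparability is out of
  scope, as is per-artery lesion labelling.
* The phantom's motion surrogate is a blur, with severity a documented
  free parameter.
* DICOM ingestion is out of scope; NIfTI and MetaImage volumes must
  carry valid spacing (a missing spacing is a hard error, never
  defaulted).
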