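# Methods

This note documents the models, conventions and numerical choices behind
`georadiomics`, and what the synthetic phantom does and does not establish.

## Coordinate and image model

Volumes are scalar Hounsfield-Unit fields on an axis-aligned grid indexed
`[ix, iy, iz]` with spacing `(sx, sy, sz)` mm (`sz` = slice thickness) and
`mm = origin + index · spacing`. Oblique DICOM orientations are rejected:
the target modality is axial planning-CT, and supporting rotated frames
would add risk with no benefit here. DICOM series are converted to HU as
`raw · RescaleSlope + RescaleIntercept` and sorted by z-position; NRRD I/O
goes through SimpleITK and preserves integer HU bit-exactly. A missing NRRD
origin defaults to (0, 0, 0) and is logged — masks and volumes produced by
this package are always co-registered by construction.

Point labels are CSV/JSON rows `(patient_id, x_mm, y_mm, z_mm, label)` with
labels normalized case-insensitively to {BM, HB}. This file format is owned
by this package; the original clinical labeling tool's format is not
publicly specified.

## Geometric ROIs

The default set is 4 spheres (15/20/30/50 mm diameter) and 5 z-axis
cylinders. The cylinder dimensions are not uniquely published, so the
package defaults to CY15/CY20/CY30/CY50 with height = diameter plus
CY50x30 (50 mm × 30 mm), spanning the same 15–50 mm size rationale (large
bone lesion → large vertebra); all sizes are configurable and the "first
four" cylinders used by E4CY are CY15..CY50 in that order.

Rasterization uses the voxel-center-in-shape rule with an inclusive
boundary, evaluated in physical mm, so anisotropic voxels (3 mm slices) are
handled exactly and nothing is resampled. Masks clipped by the image border
are kept and annotated with `clipped_fraction = max(0, 1 − N·v/V_analytic)`;
the cohort extractor drops points whose ROI set includes a mask clipped
beyond a threshold (default 0.5) and logs the exclusion. Note the same
formula absorbs ordinary discretization error on coarse grids, which is why
small nonzero values are not warned about. A lattice-aligned cylinder
center is a known degenerate case: the flat faces pass exactly through a
voxel-center plane and the inclusive boundary adds one slice (~O(spacing)
volume excess); generic centers do not suffer from this.

## Feature set (107)

Families and counts: first-order 18, shape 14, GLCM 24, GLSZM 16, GLRLM 16,
GLDM 14, NGTDM 5. Feature names are `<family>_<feature>`; ensemble features
are prefixed by their ROI (`SP20_glcm_Contrast`). No image filters are
applied anywhere.

**Discretization.** Fixed bin width of 25 HU anchored at the per-ROI
minimum: `level = floor((x − min)/25) + 1`. Anchoring at the ROI minimum
(rather than at absolute multiples of the bin width) makes texture features
exactly invariant under constant HU shifts; a property test asserts this.

**First order** uses raw in-mask values (population moments; percentiles by
linear interpolation; Entropy/Uniformity from the discretized histogram).
Kurtosis is not excess-corrected. On a constant ROI, skewness and kurtosis
are defined as 0 and logged.

**Shape.** Mesh volume and surface area come from a marching-cubes
iso-surface at level 0.5. The indicator is Gaussian-smoothed with σ = 0.8
voxels first: the raw binary iso-surface overestimates curved areas by ~8%
(staircase bias), while the anti-aliased surface reproduces a digitized
sphere's analytic area to ~0.1% and its volume to ~1%. Masks thin enough to
vanish under smoothing fall back to the raw binary surface (logged). A
voxel-face surface approximation is available via
`ExtractionSettings(surface_mode="voxel-face")` and labeled in metadata.
Axis lengths are `4·√λ` from the population covariance of in-mask voxel
centers (mm); elongation/flatness are √(λ_minor/λ_major), √(λ_least/λ_major),
defined as 1 for a single voxel. Maximum diameters are computed over
surface voxels (6-connectivity exposed faces): the 3D diameter via convex
hull (brute-force fallback for degenerate clouds), the 2D diameters as the
largest in-plane distance among surface voxels sharing a slice / column /
row index.

**Texture matrices** are built in index space at distance 1 over the 13
unique ± direction pairs of the 26-neighborhood (no isotropic resampling;
directions are the same in index space for all spacings, which keeps the
matrices well-defined on 3 mm slices at the cost of mixing physical
distances — the standard convention when resampling is not applied). GLCM
is symmetrized per direction and features are averaged over directions with
nonzero pair counts; GLRLM likewise. GLSZM zones use 26-connectivity; GLDM
uses dependence = number of equal-level 26-neighbors + 1 (α = 0); NGTDM
excludes voxels with no in-mask neighbor from both `p` and `s`.

Degenerate single-level ROIs take conventional values (GLCM contrast 0,
correlation 1, MCC 1; NGTDM contrast 0; coarseness capped at 1e6) and are
logged, never silently NaN. Entropies use log2 with a machine-epsilon
guard.

## Synthetic phantom

The phantom emulates the geometry of a planning-CT study: a 128×128×48
grid at (1, 1, 3) mm — an in-plane crop of a 512×512 scan, same slice
thickness — holding a column of vertebra-like bodies (elliptical cylinders,
semi-axes 22×16 mm, 28 mm body height, 3 mm disc gaps, 2 mm cortical
shell) on soft-tissue background. Tissue HU values use standard CT ranges:
soft tissue 40 ± 15, trabecular bone 250 ± 50, cortical shell 1000 ± 100.
Texture is correlated Gaussian noise (Gaussian-filtered white noise
rescaled to unit variance) with a 2 mm correlation length in bone.

Lesions are spheres of 8–16 mm diameter with a −150 ± 30 HU (lytic) offset
and a longer 5 mm texture correlation length, so both first-order and
texture families carry class signal. Placement rejection-samples centers
inside the trabecular compartment using a Euclidean distance transform
(sphere of radius r fits iff EDT ≥ r), keeps centers ≥ 25 mm from the z
faces so the default ROI set is essentially unclipped, and enforces
pairwise separation; failures after bounded retries raise with the number
placed. BM points are exactly the lesion centers; HB points are trabecular
locations farther than one lesion diameter from every lesion center.
Cohorts split patients into a lesioned arm (3 lesions each, matching the
study's ~3.3 labeled lesions per patient) and a lesion-free arm (4 HB
points each, the study's reported average); per-patient seeds derive from
one master seed via `SeedSequence`.

What the phantom does *not* emulate: scanner noise physics, beam hardening,
pathology-accurate lesion morphology (blastic/mixed lesions, cortical
destruction), posterior vertebral elements, patient-to-patient anatomical
variation beyond noise, or class-confounded acquisition differences.
Passing tests therefore demonstrate that the pipeline is implemented
correctly and behaves as expected when class signal exists at realistic
contrast — not that the clinical classification accuracy is reproduced.

## Evaluation grid

Per feature table: 70/30 stratified split; z-score scaling with training
statistics only (population SD; constant columns map to 0 and are
flagged); 5-fold stratified CV on the training set with the scaler and FS
refit inside each fold (a leakage canary test asserts that a feature
informative only on test rows leaves CV AUC at chance); a final model on
the full training set; test AUC from scores, precision/recall/F1 from
`predict()` (the 0.5 probability threshold for probabilistic models), with
the positive class = BM. CV spread is reported as the SD over folds.

FS settings (13 + no-FS): variance thresholds are evaluated on *pre-scaled*
features, because after z-scoring all variances are 1 and VT_0.8 would be
vacuous. LASSO selection keeps nonzero coefficients of an L1-penalized
logistic regression with C = 1/α (liblinear); if a penalty kills every
coefficient the single largest-|coefficient| feature is kept and logged.
RFECV uses a linear-SVM estimator, 10% elimination steps, 3-fold internal
CV and ROC-AUC scoring; TREE keeps features with importance above the mean
importance of a single decision tree. FastICA mirrors the PCA component
counts {20, 24, 30}. Classifier hyperparameters are pinned library
defaults (kNN k=5, RF 100 trees, GP with an RBF kernel, MLPs with one
100-unit ReLU hidden layer); every stochastic element is seeded from the
master seed, and the grid caches fitted preprocessors per (table, FS, fold)
across classifiers — numerically identical to refitting per cell, just
cheaper. A failed cell is recorded with its reason and the grid continues.

The default split stratifies at the sample level; `group_by_patient=True`
switches to a grouped split that keeps all points of a patient on one side
(stratification then becomes approximate). Patient-level grouping is off
by default to match the sample-level protocol, but multiple points per
patient do share a volume, so the grouped option is the conservative choice
for real data.

## Problem sizes used by the packaged checks

The test fixture uses a 24-patient cohort (84 points) and a reduced grid
(6 feature spaces × 4 FS × 3 classifiers); `scripts/acceptance.py` uses 60
patients (~210 points) with the same reduced grid. These sizes were chosen
as the smallest cohorts at which the split/CV machinery and the qualitative
FS/ensemble effects are stable across seeds. The full 13 × 14 × 12 = 2184
cell grid is available through the CLI/config and its dimensionality is
verified arithmetically.

## Known limitations

* Texture directions are index-space; with anisotropic voxels the 13
  directions mix physical distances (shared with the no-resampling
  convention of standard radiomics tooling).
* Maximum-2D-diameter definitions group surface voxels by exact index
  plane; for masks with very few slices these can under-represent oblique
  extents.
* GLCM `DifferenceVariance`/`SumEntropy` etc. are averaged over directions
  after per-direction normalization; directions with zero valid pairs
  (possible for very thin masks) are skipped rather than zero-filled.
* The LASSO α grid follows the published protocol (0.1/0.5/1.0 with
  C = 1/α); it is not tuned.
* The phantom's lesions are purely lytic by default; blastic disease can be
  emulated by setting a positive `lesion_offset_hu`, but no mixed-type
  cohort is generated.
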