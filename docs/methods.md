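# Methods

This note documents the models, conventions and defaults implemented in
`radpipe`, the choices made where the design was genuinely open, and
what the synthetic-data tests do and do not demonstrate.

## Image model and import

A scan is a 3D scalar grid with physical spacing, origin and direction
cosines. Slices of a single-frame DICOM series are ordered by the
projection of `ImagePositionPatient` onto the slice normal (the cross
product of the row and column cosines); this is robust to arbitrary
file order and unreliable `InstanceNumber`s, and duplicate positions
are rejected rather than guessed at. Stored values are mapped to
physical units per slice via `value = stored × RescaleSlope +
RescaleIntercept` (Hounsfield units for CT); no further unit
conversion is applied for PET/MR (no SUV computation). Masks are
accepted only as raster volumes aligned to the parent grid (DICOM
frames or a NumPy array on disk); contour formats are out of scope.
The overlap check used before extraction is numeric: the masked
min/mean/max must fall inside a user-stated plausible intensity window
(e.g. soft-tissue HU for a lung nodule), which catches segmentations
that landed on background.

## Discretization

Fixed bin width, anchored at the ROI minimum:
`b(v) = ⌊(I(v) − min_ROI)/w⌋ + 1`, default `w = 64` grey units. The
dimmest voxel is always in bin 1 and a constant intensity shift leaves
all bins unchanged, which makes every histogram- and texture-derived
feature shift-invariant by construction. "Bin size 64" is interpreted
as a bin *width* of 64, matching the defaults of the common extractor
configuration this package mirrors, not as 64 bins.

## Feature classes (107 defaults)

Counts per class: shape 14, first order 18, GLCM 24, GLRLM 16, GLSZM
16, GLDM 14, NGTDM 5. Conventions that matter for reproducing values:

- **Directions.** GLCM and GLRLM use the 13 unique 3D directions at
  distance 1; the matrix is built per direction (GLCM symmetrized and
  normalized per direction) and the feature value is the mean of the
  per-direction values, skipping directions with no voxel pairs.
  GLSZM zones use 26-connectivity; GLDM uses dependence tolerance
  α = 0 with the dependence size counting the centre voxel (so sizes
  start at 1); NGTDM uses the masked 26-neighbourhood mean, and voxels
  with no masked neighbour are excluded from the table.
- **Grey levels.** Feature formulas consume the actual bin values;
  counts of "distinct levels" (`Ng` in the normalized inverse-
  difference features, `Ngp` in NGTDM) include only levels present in
  the ROI.
- **Entropies** are computed over strictly positive probabilities with
  no epsilon padding.
- **Degenerate ROIs.** A single-grey-level ROI gives 0 for entropy-
  and correlation-type features (Correlation, Imc1/2, MCC) by
  convention, with a warning, so the output is always finite.
- **First order** works on raw intensities except Entropy/Uniformity,
  which use the discretized histogram; moments are population
  (biased) estimators and Kurtosis is not excess-corrected; Energy
  uses no voxel shift; TotalEnergy multiplies by the voxel volume.
- **Shape** uses a marching-cubes triangulation of the zero-padded
  binary mask at level 0.5 with anisotropic spacing honoured. Mesh
  volume (divergence theorem) and voxel-count volume are reported
  separately. Maximum diameters are the largest pairwise distances
  between surface vertices (via the convex hull when the mesh is
  large), the 2D variants dropping one physical axis. Axis lengths
  are `4√λ` of the coordinate covariance eigenvalues. A mask too
  small to triangulate yields NaNs for the surface-derived features
  with a warning.

The whole vectorized texture engine is checked against an independent
pure-Python brute-force implementation on random small ROIs (relative
error ≤ 1e-9), including masks with holes.

## ComBat harmonization

Parametric ComBat only. Features are standardized with the pooled
within-design variance; per-batch location `γ̂` and scale `δ̂²`
estimates are shrunk by empirical Bayes (normal prior on γ,
inverse-gamma on δ², hyperparameters by moment matching) using
iterated conditional updates, converged when the largest change in
`γ*, δ*²` is ≤ 1e-4 (cap 100 iterations). Optional `preserve` columns
(e.g. the outcome label) enter the design as covariates and their
effects are restored after adjustment; by default the label is *not*
preserved. A batch with a single sample has no scale estimate and is
rejected by name — the remedy is to exclude it upstream, which is also
why the default synthetic cohort has five batches rather than six. A
single-batch table is returned unchanged.

The implementation reproduces the Bioconductor reference elementwise
to ~4e-6 (a pytest cross-check runs `sva::ComBat` through `Rscript`).
One consequence worth knowing: when the true batch shift is identical
across features, the cross-feature prior variance τ² reflects only
sampling noise (~1/n), so `nτ²` stays O(1) and the EB estimate retains
roughly half of each feature's batch-mean sampling error; the residual
post-harmonization batch-mean gap therefore shrinks like `1/√n` rather
than vanishing at fixed n. The acceptance suite measures this residual
at n = 200/batch.

Batch diagnostics z-score the features before PCA (feature scales span
orders of magnitude, and volume-like features would otherwise dominate
the components), then apply Kruskal–Wallis to the PC1 and PC2 scores
across batches with threshold 0.05; "no batch effect detected"
requires both p-values above the threshold.

## Feature selection

Ranking sorts by absolute score, descending — a strong negative
point-biserial correlation is as informative as a positive one — with
exact ties broken lexicographically by feature name so the order is
deterministic. Zero-variance features score 0 with a warning. ReliefF
defaults: k = 10 nearest hits/misses, every sample used once,
Manhattan distances on min-max-scaled features, neighbour ties broken
by sample index.

The hybrid selector's "model p-value" is pinned as the likelihood-
ratio test of the logistic model against the intercept-only model
(χ², df = number of features); cycle m is accepted iff its p-value is
strictly below the previous accepted cycle's, the first non-improving
cycle stops the walk, and at least one feature is always kept. On
complete separation at cycle 1 the model is returned with the p-value
recorded as the machine minimum and a warning.

LASSO selection z-standardizes features first (the L1 penalty is scale
sensitive) and reports coefficients on the standardized scale, whereas
the hybrid route fits raw features to stay faithful to the descriptive
ranking. The penalty grid has 100 points, log-spaced over four decades
down from `λ_max = max|Xᵀ(y − ȳ)|/n` (the smallest penalty that zeroes
all coefficients); λ minimizes the mean held-out binomial deviance
over stratified folds.

The radscore is the linear functional `β₀ + Σ βⱼ xⱼ` over the selected
features; the intercept is included by default and flagged in the
result so it can be dropped.

## Modelling and validation

Classifier defaults follow the delegated library: LDA with pooled
covariance, KNN with Euclidean distance (k is the only exposed
hyperparameter anywhere in the modelling stage), SVM with RBF kernel
and C = 1 scored by its margin. The positive class is label 1
(convention: 1 = benign, 0 = malignant); hard classification uses a
0.5 posterior threshold or the sign of the SVM decision value. Folds
come from scikit-learn's (Stratified)KFold with shuffling; note the
stratified and plain splitters do not produce literally identical
partitions on balanced data — they agree in distribution, not in the
realized assignment.

The global ROC is the *vertical average*: each fold's TPR is linearly
interpolated onto the fixed grid FPR ∈ {0, 0.01, …, 1}, averaged
pointwise, and the AUC is the trapezoid of the averaged curve — the
named "average ROC" does not pin an interpolation scheme, so this
concrete choice is recorded here. Repeated evaluation reshuffles the
cohort with seed = base + repeat index and reports mean ± 1.96·sd/√R
per metric (CI omitted for a single repeat). Single-class held-out
sets have a defined accuracy but no AUC.

## Synthetic data

The phantom generator emulates CT geometry: −1000 HU background,
lesions of known intensity and shape, optional Gaussian noise rounded
to integer HU (so DICOM round trips are exact), written through the
same public writers/readers users employ. The table generator emulates
a two-class multi-scanner cohort: i.i.d. Gaussian features, a stated
standardized effect on a chosen subset, and per-batch additive/
multiplicative distortions; the default shape is 91 patients (28 vs
63) over five batches sized (19, 50, 13, 5, 4), mirroring a realistic
imbalanced lung-nodule screening cohort after excluding a singleton
scanner batch.

What the generators do *not* emulate: spatially correlated lung
texture, realistic inter-feature correlation structure (real radiomic
features are strongly collinear), non-Gaussian feature marginals, or
segmentation variability. Passing tests therefore demonstrate
correctness of the computations and calibration of the procedures
under clean, known-truth conditions — not clinical performance on real
images.

Problem sizes were chosen so the full test suite runs in well under a
minute on one core: 32³ phantoms (~500-voxel lesions), tables up to
500 samples, 100-seed calibration loops for the selector, 10×10-fold
repeated CV for the null-AUC check.

## Study metadata

All settings are persisted as canonical JSON (sorted keys, fixed
indentation), so byte equality of `metadata.json` implies setting
equality and studies diff cleanly under version control. Merging an
external study compares only the extraction-relevant subset (modality,
bin width, enabled classes, resampling flag) — classifier settings do
not affect feature compatibility — and rejects duplicate patient ids
by name. Every CLI run appends a timestamped entry with its resolved
options to `log.jsonl`.

## Known limitations

- Original-image features only: no wavelet/LoG filtered features, no
  resampling interpolators, no 2D per-slice extraction mode.
- No DICOM-RT structure-set parsing; masks must be rasterized.
- Binary outcomes only; no multi-class support, no probability
  calibration, no hyperparameter search.
- Non-parametric ComBat is not implemented.
- t-SNE batch visualization is not provided (PCA + Kruskal–Wallis is
  the supported diagnostic).
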