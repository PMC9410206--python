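# radpipe

A scriptable, GUI-free radiomics pipeline for binary-outcome studies on
medical images (CT / PET / MR): DICOM series import → target
segmentation → IBSI-style radiomic feature extraction → ComBat batch
harmonization → feature selection → classifier training with
cross-validated ROC reporting — all settings tracked in JSON study
metadata so an analysis can be shared and reproduced bit-for-bit.

It is aimed at researchers who want the whole radiomics workflow as a
library and a shell tool rather than a point-and-click application, for
example to discriminate benign from malignant lung nodules on screening
CT across several scanner models.

## What it computes

**Features.** From a volume `I` and a binary mask, intensities inside
the mask are discretized with a fixed bin width *w* anchored at the ROI
minimum, `b(v) = ⌊(I(v) − min)/w⌋ + 1`. The default configuration
(`w = 64` grey units, all seven original-image classes, no filters or
resampling) yields exactly **107 named features**: 14 shape
(triangulated-mesh volume/surface, sphericity, axis lengths, …), 18
first-order histogram statistics, and texture features from the five
classical grey-level matrices — GLCM 24, GLRLM 16, GLSZM 16, GLDM 14,
NGTDM 5 — computed over the 13 unique 3D directions at distance 1 and
named `original_<class>_<FeatureName>`.

**Harmonization.** Parametric ComBat models feature `y_gj` in batch `b`
as `α_g + γ_bg + δ_bg ε`, shrinks the per-batch location/scale estimates
by empirical Bayes (normal / inverse-gamma priors, moment-matched), and
back-transforms `y* = σ_g (z − γ*)/δ* + α_g`. Batch-effect screening is
PCA on z-scored features plus a Kruskal–Wallis test of the PC1/PC2
scores across batches at α = 0.05.

**Selection.** Features are ranked by point-biserial correlation,
Welch t, or ReliefF; the hybrid descriptive–inferential selector then
fits logistic models on growing rank prefixes and keeps adding features
while the whole-model likelihood-ratio p-value strictly decreases.
Alternatively, L1-penalized logistic regression picks the penalty by
minimum cross-validated binomial deviance. Either route defines the
radiomics score `radscore(x) = β₀ + Σ βⱼ xⱼ`.

**Modelling.** LDA, KNN (k is the only tunable hyperparameter) and
RBF-SVM are evaluated by (stratified) k-fold cross-validation, with the
global ROC obtained by vertical averaging of the per-fold curves on a
fixed FPR grid, and repeated reshuffled runs summarized as mean ± 95%
confidence interval.

## Worked example

```python
from radpipe import (PhantomSpec, generate_phantom, extract_features,
                     TableSpec, generate_feature_table, score_features,
                     hybrid_select, compute_radscore, ModelSpec,
                     repeat_evaluation)

# 1. extract the default 107 features from a synthetic CT phantom
volume, mask = generate_phantom(PhantomSpec(noise_sd=30.0, seed=0))
feats = extract_features(volume, mask)

# 2. a synthetic 91-patient, five-scanner cohort with one real effect
table, truth = generate_feature_table(TableSpec(effects=((4, 2.0),), seed=0))
scores = score_features(table, "pbc")
selection = hybrid_select(table, scores)
radscore = compute_radscore(selection, table)

# 3. repeated stratified 10-fold cross-validation of an LDA model
report = repeat_evaluation(table, ModelSpec("lda"), k=10, stratified=True,
                           n_repeats=10, base_seed=0,
                           features=selection.selected)
```

This prints (via the obvious `print` statements):

```
extracted 107 features from a 515-voxel lesion
  original_shape_MeshVolume = 504.8333
  original_firstorder_Mean = 99.0757
  original_glcm_JointEntropy = 2.2104
  original_gldm_SmallDependenceHighGrayLevelEmphasis = 0.2649
selected: ['feat_004'] (PBC score 0.697)
radscore range: [-9.49, 6.55]
  auc: 0.930 +/- 0.0127
  accuracy: 0.866 +/- 0.0028
  sensitivity: 0.775 +/- 0.0140
  specificity: 0.905 +/- 0.0024
```

The phantom's 515-voxel sphere (radius 5, 1 mm spacing) has a mesh
volume close to the analytic 523.6 mm³ and a mean intensity near the
injected 100 HU; the selector recovers exactly the one informative
feature planted in the cohort (`feat_004`, standardized effect 2.0),
and the cross-validated LDA on that single feature separates the
classes well above chance with tight confidence intervals over the 10
reshuffled repeats.

The same workflow is available from the shell, operating on a study
folder with JSON metadata and a run log:

```sh
radpipe new studies demo
radpipe simulate studies/demo --n-patients 8
radpipe extract studies/demo --bin-width 64
radpipe select  studies/demo --method pbc
radpipe train   studies/demo --model lda --k 10 --repeats 10
```

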