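# Methods

This note records the models, conventions and numerical choices behind
`radgroup`, in the order the pipeline applies them.

## Image preparation and ROI sets

Volumes are resampled to a target spacing (default 1 × 1 × 5 mm, the
in-plane-fine / thick-slice geometry typical of abdominal CT) by linear
interpolation in 3D. Mask indicators are resampled the same way and
re-binarized at 0.5, which preserves volume better than nearest-neighbour
resampling. Images and masks must share a grid; a mismatch is an error, not
a silent resample.

**Core/rim.** The core is the set of foreground voxels whose Euclidean
distance to the mask boundary exceeds the erosion depth (default 10 mm,
after the observation that aggressive clones concentrate in the outer
10 mm of these tumours). The distance transform uses the physical voxel
spacing, so 10 mm spans ten in-plane voxels but only two 5 mm slices;
structuring-element erosion in voxel units would be badly anisotropic here.
Erosion is 3D. A core emptied by erosion (lesion thinner than twice the
depth) flags the lesion as ineligible for that ROI set — no imputation.

**High/low enhancement.** The published sub-segmentation algorithm for
high/low-enhancing regions is not reproduced here; `radgroup` provides its
own: the intensity image is smoothed inside the mask by normalized
convolution (Gaussian, σ = 2 mm physical; masked smoothing prevents
background HU bleeding across the tumour boundary), split into two classes
by Otsu's threshold (a 2-component 1D k-means is available via config), and
connected components below 0.5 cm³ are reassigned to the other class.
Near-constant tumours (range < 1 HU) degenerate to high = whole,
low = empty, flagged. The high/low labelling is fixed by mean HU ordering.

## Feature extraction

Per region: 14 shape, 18 first-order and 73 texture features (105 total).
The texture roster is 22 co-occurrence, 16 run-length, 16 size-zone, 14
dependence and 5 neighbourhood grey-tone difference features — the common
default roster of IBSI-style extractors minus the two deprecated/duplicative
co-occurrence statistics.

- **Mesh features.** Volume and surface area come from a marching-cubes
  triangulation of the zero-padded indicator at physical spacing. The raw
  binary iso-surface is a staircase that overestimates the area of smooth
  anatomy by ~10%, so the mesh is Taubin-smoothed (λ/μ smoothing, 30
  iterations), which relaxes the staircase without the volume shrinkage of
  plain Laplacian smoothing: voxelized balls then measure within 2% of
  (4/3)πr³ in volume and ~1% in area, and a digital sphere's sphericity
  evaluates to ≈ 0.99 rather than ≈ 0.92. Volume is the signed-tetrahedron
  sum over faces; area the summed triangle areas.
- **Axis features.** Major/minor/least axis lengths are 4√λ of the
  voxel-coordinate covariance eigenvalues (mm²); Elongation and Flatness
  are √(λ_minor/λ_major) and √(λ_least/λ_major).
- **First-order.** Computed on raw HU values; Entropy and Uniformity use
  the same fixed-bin-width discretisation as the texture features.
- **Texture (2D).** Intensities are discretised with a fixed bin width
  (default 25 HU) relative to the region minimum. Matrices are built per
  axial slice; the four in-plane directions of the co-occurrence and
  run-length matrices are merged by summation, and feature values are
  averaged over slices with ≥ 5 foreground pixels (recorded in the config
  hash as `slice_mean`). Slices too small for texture are skipped; a region
  with no eligible slice is an error surfaced to the caller.

Discretisation width, minimum slice size and aggregation are configurable
and hashed into the table metadata so tables from different configurations
cannot be silently mixed.

## Reproducibility filter

Agreement between two independent segmentations is measured per feature by
ICC(2,1) — two-way random effects, absolute agreement, single measurement —
computed from the ANOVA mean squares. The variant is configurable in
principle but ICC(2,1) is the default because it penalizes systematic
offsets between raters, which is the failure mode of interest for
segmentation-derived features. Rejection is strict: a feature with ICC
exactly at the threshold (default 0.75) is retained. Zero-variance features
have undefined ICC and are rejected with a warning.

## Correlation-based feature reduction

Correlations default to Spearman rank correlation (robust to the heavy
tails and monotone nonlinearities of radiomics features); Pearson is
available. The cutoff defaults to |ρ| > 0.90, the usual setting of
iterative correlation filters. Both variants repeatedly take the most
correlated remaining pair above the cutoff (ties broken lexicographically
on the feature key, logged):

- **standard**: drop the member with the higher mean absolute correlation
  to the other remaining features (ties → lexicographic).
- **hierarchical**: if the pair spans two hierarchy levels
  (MeshVolume > shape > first-order > texture), drop the lower-ranked
  member; same-level pairs fall back to the standard rule. MeshVolume sits
  alone at the top and therefore survives every run.

Every discard decision is recorded in a JSON-lines audit log (pair,
correlation, rule, discarded key); the dominance property is asserted over
this log in tests. Inside cross-validation, CFR is refit on each
outer-training set; the inner tuning loop reuses the outer-train CFR
feature set rather than refitting per inner fold — outer-test rows never
reach CFR either way, which is the leakage property that matters for the
reported AUROC. A global-precompute mode exists only for exploratory use.

## Candidate groups and tuning

From k feature classes the grid is: {MeshVolume}, each class (shape
includes MeshVolume), all pairwise class unions, and all features —
2 + k + k(k−1)/2 groups, i.e. eight for the default three classes. Group
membership follows feature class irrespective of ROI, so a "shape" model
may draw shape features from whole, core and rim simultaneously. Classes
emptied by CFR drop out of the grid with a warning.

Tuning is a grid search over (group, λ) scored by mean inner-fold AUROC
(matching the outer metric) with stratified 3-fold inner CV. Exact score
ties prefer the smaller group, then the larger λ — interpretability first,
then sparsity. The λ grid defaults to 20 log-spaced values in [1e-3, 10] on
standardized features.

## Classification and validation

The penalized objective is (1/n)·Σ logloss + λ‖β‖₁ with an unpenalized
intercept, fitted on z-scored features (standardization parameters from
training rows only; zero-variance columns dropped with a warning). The
solver is liblinear with C = 1/(nλ); liblinear folds the intercept into the
penalty via a scaled bias column, so `intercept_scaling = 1000` leaves it
penalized only with weight 1e-3 — coefficients agree with an independent
proximal-gradient solver of the exactly-unpenalized objective to ~1e-4,
which is asserted in tests.

Outer validation is stratified 5-fold CV repeated (default 100×, giving 500
per-split models); repeat r shuffles folds with seed + r. Stratification is
used because several targets have ~10% positive prevalence and unstratified
folds would occasionally be single-class. Per-split AUROC is computed on
each outer-test fold and averaged (not pooled). The conventional mode fixes
the group to "all" and applies standard CFR; the proposed mode applies
hierarchical CFR and tunes the group.

The permutation test reruns the entire nested CV on label-shuffled data;
p = (1 + #{null ≥ observed})/(1 + n_perm), one-sided. The permutation
stream is seeded independently of the fold stream. Default n_perm = 1000
(configurable; tests use 19–49 to stay within minutes). Raw p-values are
reported; a Benjamini–Hochberg column is available but off by default. The
"final model" dispenses with the outer loop: inner-CV tuning on all data,
then one fit on all data.

## Synthetic data

Feature tables are multivariate Gaussian with a compound-symmetric block
correlation (within-class ρ_w = 0.5, cross-class ρ_b = 0.2 by default —
strong within-class redundancy, milder cross-class coupling, the structure
real panels show), at the registry's dimensions (1 + 13 + 18 + 73 features)
and a default cohort of 91 lesions. Labels follow a logistic model whose
nonzero weights sit on `n_signal` features of one informative group;
`effect` is the log-odds per SD of each signal feature, and
`population_auroc` / `effect_for_population_auroc` convert between effect
size and the implied population AUROC by quadrature, so studies can be
specified directly in AUROC units. The redundant-pair preset regenerates
glszm_GrayLevelNonUniformity as 0.979·MeshVolume + noise at n = 500 with
ρ_w = 0.6, sized so the standard-vs-hierarchical CFR contrast is structural
rather than a sampling accident.

Phantoms are voxelized ellipsoids (default semi-axes 18 × 15 × 25 mm on a
1 × 1 × 5 mm grid) with a nested low-enhancing compartment (40 vs 140 HU)
and optional additive Gaussian noise. They exercise geometry, partitioning
and the imaging path end to end; they do not emulate CT physics
(reconstruction kernels, beam hardening, partial volume beyond the grid
resolution), so passing phantom tests demonstrates correctness of the
computational pipeline, not clinical-grade robustness of the enhancement
split.

What the synthetic tables do not model: non-Gaussian marginals, outliers,
site/scanner batch effects, and feature redundancy structure beyond
two-level compound symmetry. Results on them validate the selection and
validation machinery (leakage-freedom, calibration, recovery), not
clinical performance.

## Problem sizes in the test suite

The suite asserts the count law folds × repeats at 5 × 4 and runs one
full-size 5 × 100 smoke at toy dimensions (n = 60, 10 features) to confirm
500 per-split models. Calibration uses 200 null datasets (n = 200, 20
features) with 19 permutations and a single outer repeat — the smallest
design on which the type-I error and the discreteness of the p-value grid
are both visible. Recovery and parity run at n = 200 with effects
calibrated to population AUROC 0.85 and 0.8.

## Known limitations

- Texture values follow standard matrix definitions but are not
  benchmarked against the IBSI digital phantom; counts, determinism and
  degenerate-case behaviour are tested, absolute values are not certified.
- The high/low enhancement split is this package's own algorithm, not a
  reproduction of the published one.
- 2D texture aggregation is slice-mean with merged directions; per-direction
  feature averaging is not implemented.
- Maximum 2D diameters are computed per grid-aligned plane family from
  border voxels, which assumes axis-aligned acquisition geometry.
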