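# Methods

`habitatrad` implements a habitat-radiomics pipeline for predicting
pathologic complete response (pCR) to neoadjuvant immunochemotherapy from a
single pre-treatment contrast-enhanced chest CT.  Two prediction arms are
built and compared on identical cohorts:

* **radiomics arm** — one feature record per patient computed over the
  whole tumor ROI (shape + intensity + texture, 1834 features);
* **habitat arm** — the tumor is first partitioned into K spatially
  coherent subregions ("habitats") by clustering voxel-level feature maps;
  intensity and texture features are then extracted per habitat
  (1820 per habitat; 7280 for K = 4) and fused into one record.

Both arms share one selection cascade (t-test → Pearson pruning →
cross-validated LASSO) and one classifier (unpenalized logistic
regression), so a performance difference is attributable to the feature
representation alone.

## Preprocessing

Images and masks are read from NIfTI (DICOM series directories are
accepted for images).  Geometry agreement between image and mask is
enforced, never assumed.  Optional resampling places both on an isotropic
1 × 1 × 1 mm grid — cubic B-spline interpolation for the image, nearest
neighbour (then re-binarization) for the mask, which conserves foreground
volume within ~5% for smooth masks.  All grids are cropped to the ROI
bounding box plus a 2-voxel margin before extraction.

## The feature engine

**Filter bank (20 image types).**  original; the eight single-level 3D
stationary-wavelet bands (coif1, undecimated so all bands stay on the
source grid); Laplacian-of-Gaussian at σ = 1…6 mm; square; square root
(signed); logarithm — the signed shift `sign(x)·log(|x|+1)` admits the
negative HU range without error; exponential (argument rescaled to [-3, 3]
to bound the dynamic range); gradient magnitude (spacing-aware).

**Discretization.**  Fixed bin width, `level = floor((v − min)/w) + 1`.
The original image uses w = 25 HU; derived images with arbitrary dynamic
range use w = range/32.  A constant region yields a single level — every
texture class has a fixed degenerate convention (e.g. GLCM joint energy 1,
contrast 0, correlation 1) so no NaN ever enters a feature table.

**Feature classes.**  18 first-order statistics (population moments;
entropy/uniformity on the discretization histogram; zero-variance regions
return skewness = kurtosis = 0); 14 mesh-based shape descriptors (whole-ROI
mask only — shape is meaningless for clustered subregions); and five
texture families over the discretized volume:

| class | descriptors | aggregation |
|-------|------------:|-------------|
| GLCM  | 22 | 13 unique directions, distance 1, symmetrized; feature values averaged |
| GLRLM | 16 | runs along the same 13 directions, averaged |
| GLSZM | 16 | zones by 26-connected components |
| NGTDM | 5  | 26-neighbourhood mean differences |
| GLDM  | 14 | dependence counts, 26-neighbourhood, α = 0 |

The GLCM set is the standard 24 minus Sum Average (equal to twice Joint
Average on a symmetric matrix) and Dissimilarity (equal to Difference
Average).  Totals: 20 × (18 + 73) = 1820 non-shape features, 1834 with
shape, and per-class tallies 360/440/320/320/100/280.  Every matrix
builder is verified exactly against an independent triple-loop enumeration
on small grids in the test suite.

Shape meshes are computed by marching cubes at level 0.5 on a 1-voxel
Gaussian-smoothed copy of the mask: the raw binary staircase overestimates
a sphere's surface by ~8%, while the smoothed mesh recovers analytic
volume and area within ~3% (sphericity 0.997 for a 10-mm digital sphere).

## Habitat partitioning

Each tumor is processed independently.  Per in-mask voxel, feature maps
are computed over a 3×3×3 neighbourhood intersected with the ROI and
z-scored across the tumor's voxels.  The default map set is **original
intensity + local mean**.  Richer kernel statistics (variance, energy,
entropy, uniformity) are implemented and selectable, but are not defaults:
on lesions whose subregions are only one or two voxels thick, windows that
straddle a subregion boundary produce variance/entropy outliers that
dominate the z-scored metric, and K-means then clusters the boundary
response instead of the habitats (adjusted Rand index collapses toward 0).

K-means (k-means++ initialization, 10 restarts, 300 iterations, seeded)
runs for K = 2…10 and each solution is scored with the Calinski-Harabasz
index CH = [B/(K−1)]/[W/(n−K)].  On voxel data the CH curve does not
decrease monotonically: it rises steeply until the planted structure is
resolved and then plateaus.  The selection rule therefore extends the
curve with CH(1) ≡ 0 (a single cluster has zero between-cluster
dispersion) and picks the K whose incremental CH gain collapses
immediately after it — the maximum of
`(CH(k) − CH(k−1)) − (CH(k+1) − CH(k))`, ties toward smaller K.  On
phantoms with 2, 3 or 4 planted habitats and mean separation ≥ 5× the
noise SD this recovers the planted count in 10/10 seeded runs, where both
the raw CH maximum and the classical positive-second-difference elbow fail.
A degenerate (all-NaN) curve falls back to k_min with a warning; a
curve containing a perfectly separated solution (CH = ∞) returns the
smallest such K.  `ch_max` is available as an alternative rule.

Cluster indices are arbitrary, so habitats are re-ordered h1…hK by
descending mean original intensity (ties by size, then cluster id), making
the whole pipeline invariant to label permutations of the clusterer.  For
cohort runs the habitat count is fixed cohort-wide: each training lesion
votes via the CH rule and the modal K (ties toward smaller) is applied to
everyone.  Habitats smaller than 10 voxels contribute NaN placeholders,
imputed later by training-cohort medians.

## Selection cascade and classifier

1. **ICC robustness screen** (optional, cohort-level): features are
   re-extracted under a simulated second-rater mask (smooth random
   boundary displacement, sd = jitter/2, hard-bounded by the jitter) and
   kept when ICC(2,1) — two-way random effects, absolute agreement — is
   ≥ 0.75.  Zero-variance features have undefined ICC and are dropped.
2. **z-scoring** fitted on the training cohort only; zero-variance columns
   dropped; validation data transformed with frozen parameters.
3. **Welch t-test**, two-sided; keep p < 0.05.
4. **Pearson pruning**: features visited in decreasing |t| (ties
   lexicographic); a feature is kept only if |r| ≤ 0.9 against every
   feature already kept — the more informative member of each redundant
   pair survives, and no retained pair exceeds the threshold.
5. **LASSO**: L1-penalized logistic regression over a 40-point log-spaced
   λ grid from just above the analytic λ_max down to λ_max·10⁻³;
   λ* minimizes the mean 10-fold (stratified, seeded) cross-validated
   deviance; features with nonzero coefficients at λ* are selected.  An
   empty selection falls back to the single top-|t| feature, flagged.

The retained sets are strictly nested across stages.  The final model is
maximum-likelihood logistic regression on the selected standardized
features; quasi-separation (|w| > 10³) triggers a logged ridge-stabilized
refit (C = 100).  The composite Rad/habitat score is
`intercept + Σ βᵢ·zᵢ`.

## Evaluation

AUC uses the Mann-Whitney rank construction (ties half-credit) with a
DeLong 95% CI.  The decision threshold maximizes Youden's J on the
training ROC and is frozen for validation; accuracy, sensitivity,
specificity, PPV and NPV are reported with NaN for zero-denominator
ratios.  Decision-curve analysis reports
NB(pt) = TP/n − FP/n·pt/(1−pt) against treat-all and treat-none
references.  Calibration uses deciles of predicted risk; the
Hosmer-Lemeshow statistic Σ (O−E)²/(E(1−E/n_b)) is referred to a χ²
with (bins − 2) degrees of freedom; empty or tied bins are merged with
the df adjusted and the merge logged.

## The synthetic cohort

No public cohort exists for this problem (the source data are private
multicenter scans), so the generator emulates the study conditions:

* ellipsoidal lesions, default semi-axes ~15×13×12 mm (clinical range
  1–6 cm), isotropic 1-mm grid, aerated-lung background (−780 HU);
* K planted habitats as concentric equal-volume shells (perfusion-driven
  core/rim heterogeneity; an angular-wedge layout is available), with
  per-habitat mean attenuation, per-habitat correlated texture
  (Gaussian-filtered white noise at the habitat's correlation length,
  sd 15 HU by default) and global acquisition noise (sd 10 HU);
* two-class cohorts at the clinical pCR prevalence 0.36 with exactly
  `round(n·prevalence)` positives;
* the class effect, scaled by one `effect` parameter, has three
  configurable components: a volume-fraction tilt toward the innermost
  habitat (`composition_tilt`, log-weight units), a focal attenuation
  shift of the second habitat (`focal_shift_hu`), and a change of the
  second habitat's texture correlation length (`texture_scale_shift`,
  log units);
* subject-level variability: lesion size jitter (15% sd), log-normal
  composition jitter (0.3 sd), habitat-mean jitter (5 HU sd), log-normal
  texture-scale jitter (0.25 sd), independent noise seeds.  Without it,
  the planted effect is deterministic per class and any model saturates
  at AUC 1.

A design fact drives the choice of condition for the two-arm comparison:
whenever planted habitats are separable in the intensity histogram, the
whole-ROI feature set is (close to) a sufficient statistic for habitat
composition and attenuation shifts — in paired experiments the whole-ROI
arm then matches or beats the habitat arm, which carries a 4× larger
feature space into the same selection cascade.  A texture-correlation-
length change inside one habitat is the cleanest signal with the opposite
character: it leaves the marginal intensity distribution untouched, so
whole-ROI texture features see it only volume-diluted, while per-habitat
features measure it directly.  The paired-arm test therefore plants a
composition tilt plus a focal texture-scale change and asserts that the
habitat arm's validation AUC exceeds the whole-ROI arm's on a seeded
cohort generated under that condition.

What the phantom does **not** model: scanner physics, contrast kinetics,
partial-volume blur at habitat boundaries, irregular lesion shapes, or
inter-center acquisition shifts.  Passing tests on phantoms therefore
demonstrate the *machinery* (feature correctness, recovery of planted
structure, absence of leakage, ordering of the two arms under a localized
effect), not clinical performance.

## Problem sizes and numerical choices

Tests and the acceptance script run lesions of ~4 000–10 000 voxels on
32–36³ grids and cohorts of 12–60 subjects — sizes chosen so the whole
suite replays in minutes while leaving every statistical check
well-powered.  Random seeds thread from one root through
`numpy.random.SeedSequence`; k-means, CV folds and liblinear are all
explicitly seeded, so cohort runs are bit-reproducible (the liblinear
coordinate-descent RNG is pinned — with correlated columns the L1 optimum
is not unique and an unseeded solver returns different, equally optimal
splits).

## Known limitations

* The published pipeline's exact filter bank, wavelet basis, bin settings,
  per-voxel feature list and resampling spacing live in an inaccessible
  supplement; only the 20-type count, per-class tallies and the K = 2…10
  CH procedure are constrained.  The choices above are this package's
  documented substitutes, and the cohort-specific metric values printed in
  the source study are treated as plausibility context, not targets.
* ICC here models intra-rater re-segmentation via a synthetic boundary
  perturbation, not true inter-observer variability.
* Per-patient clustering with intensity-based ordering is the only
  habitat-matching mechanism across patients; no cross-patient habitat
  alignment is attempted.
* The 2D slice-wise pathway, GPU acceleration, and IBSI certification
  beyond the built-in brute-force oracles are out of scope.
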