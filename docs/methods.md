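# Methods

## The measurement model

NM-MRI volumetry treats a brainstem nucleus as "the set of voxels that are
implausibly bright relative to a reference tissue". Per subject:

1. The 7 repeated measurements are rigidly realigned to the first and
   averaged. Averaging n independent measurements reduces voxel noise by
   √n; realignment prevents head motion from blurring the small nuclei out
   of existence.
2. A reference ROI in the cerebral peduncle — crus cerebri white matter,
   close to the SNc and homogeneous on NM-MRI — yields μ_ref and σ_ref
   (sample SD, n−1 denominator; unspecified in the source method, fixed
   here for reproducibility; with hundreds of reference voxels the choice
   is numerically immaterial).
3. Each structure's probabilistic atlas, already mapped to native space, is
   cut at probability 0.05 and binary-dilated (6-connected element, default
   2 iterations) into a search region; the dilation guarantees the whole
   structure is inside the searched neighbourhood even with imperfect
   spatial normalization.
4. Voxels in the search region with intensity strictly greater than
   μ_ref + k·σ_ref are the structure: k = 2.8 for SNc and k = 3.9 for LC
   (the higher LC cut guards against hyperintense artefact near the fourth
   ventricle). Ties at exactly the threshold are excluded. Both hemispheres
   are summed into one bilateral volume, voxel count × 0.39·0.39·3 mm³.
   No connected-component or minimum-cluster filtering is applied (an
   optional component count can be reported post hoc).

The statistical layer mirrors how such cohorts are analysed: Shapiro–Wilk
per group; two-tailed Welch's t (also computable directly from printed
mean ± SE ± n summaries, which is how the worked example against the
published table is run); ANCOVA as OLS of volume on group + covariates with
the partial F of the group term (for a two-level factor, F = t² of the
group coefficient); Pearson correlation between residuals after regressing
both variables on age, p from t = r√((n−3)/(1−r²)); empirical ROC with
trapezoidal AUC, oriented so that lower volume counts as disease-like,
Hanley–McNeil SE by default (DeLong optional), CI = AUC ± 1.96·SE truncated
to [0, 1]. The combined SNc+LC marker is the fitted probability of a
two-predictor logistic regression (the combination rule is not specified in
the source description; logistic regression is the standard choice and is
recorded in the output metadata). Under perfect separation the ML logit
diverges; the code warns and falls back to an L2-penalized fit, whose score
ranking — all the ROC needs — is well defined. α = 0.05 per test, no
multiple-testing correction; every test performed is listed in the report.

## Registration

Rigid estimation is intensity-based realignment: 6 parameters (3 Euler
angles, 3 translations, pivot at the fixed image's world center), masked
mean-squared-error cost, trilinear sampling on an in-plane-decimated grid,
a fixed coarse grid over translations (±2 mm) for capture range, then
Levenberg–Marquardt with an analytic Jacobian built from the moving image's
spatial gradient. Three numerical details matter on thick-slice data:

- **Pre-smoothing is anisotropic** (FWHM 1.2 mm in-plane, 4 mm
  through-plane, registration only). With 3 mm slices, trilinear
  interpolation along z is rough and its interaction with voxel-wise noise
  biases estimates toward lattice-aligned offsets; smoothing both images
  symmetrically suppresses this without shifting the optimum.
- **A 2.5 mm rim of both fields of view is excluded** from the cost: motion
  carries unseen tissue into the edge of the grid, and comparing it against
  fill values drags the fit.
- **Determinism**: no random restarts anywhere. Scan-rescan reproducibility
  is the point of the method, so the estimator must be a pure function of
  its inputs. Bounds are ±5° / ±5 mm.

Accuracy is quantified as the mean displacement discrepancy between the
estimated and true transforms in per-axis voxel units, evaluated over the
structure + reference voxels — the region whose alignment the volumetry
actually depends on. On default phantoms this is ≈ 0.09 voxel (injected
jitter 0.5° / 0.5 mm per axis).

Standard-space → native mapping is applied, never fitted: chains of
rigid/affine links (JSON-serialized, space-labelled) are composed into a
single matrix and resampled in one interpolation pass — trilinear for
images and atlases, nearest-neighbour for masks, zero fill outside the
source grid. Brain extraction and nonlinear warp estimation are out of
scope; a precomputed warp can be expressed upstream of the supplied chain.

## The phantom

The simulator emulates what the analysis assumes about the data, not the
MR physics (no T1/T2*/MT simulation; contrast is parametric):

- **Grid**: 96 × 96 × 15 voxels at 0.39 × 0.39 × 3 mm, RAS affine centered
  on the origin. 7 measurements per subject.
- **Structures**: schematic bilateral geometry — SNc as medial-facing
  crescents (arc radius 6 mm, half-thickness 1.6 mm) in the upper slices,
  LC as vertical rods (2 mm diameter, ≤15 mm long) below, and two lateral
  reference cylinders at the SNc slice level. Ground-truth masks take the
  round(V/voxel-volume) best voxels of an analytic shape score, split
  across hemispheres, so the voxelized mask volume matches the requested
  volume to within one voxel (8 mm³ of LC is only ~18 voxels — the printed
  LC volumes really are that small on this grid).
- **Intensities**: background 100, structures at background + contrast,
  Gaussian blur FWHM 0.5 mm for partial-volume softness. Contrast defaults
  (SNc 21, LC 29) put each threshold at ≈ half the structure's blurred peak
  given noise SD 10 per measurement (σ_ref ≈ 10/√7 ≈ 3.78 on the average,
  thresholds ≈ 10.6 and 14.7): the half-maximum criterion makes the
  recovered boundary sit at the true edge, so recovery is approximately
  unbiased. The source method reports no CNR values; these are simulator
  design choices, exposed as parameters.
- **Texture**: a subject-fixed smooth "anatomy" field (amplitude 10, FWHM
  4 mm) rides on the background. It moves with the head, giving motion
  correction the kind of large-scale gradient real brainstem anatomy
  provides; it is tapered to zero over the neighbourhood the atlas search
  regions can reach (including adjacent thick slices), so the homogeneous-
  reference and flat-search-background assumptions of the threshold rule
  are preserved.
- **Motion and noise**: measurements 2..7 get independent rigid jitter
  (0.5° / 0.5 mm SD per axis, about the grid center; measurement 1 is the
  reference) applied by resampling, with background — not zero — filling
  the vacated field-of-view edge, since the phantom's surround is
  homogeneous tissue. Noise is added after motion (receiver noise), iid per
  voxel and measurement: Gaussian by default, Rician optionally (magnitude
  MRI noise is Rician at low SNR). The reference region has its own noise
  SD so that "noise-free" validation phantoms can keep a nominal reference
  noise floor (σ_ref = 0 would make the threshold undefined) while
  structures stay exactly clean.
- **Atlases**: smoothed (FWHM 1.5 mm), peak-normalized versions of the
  canonical control-mean masks serve as the simulator's standard-space
  atlas pair and reference ROI, with identity transform chains — the
  pipeline runs end-to-end with no external downloads.
- **Cohorts**: per-subject true volumes are normal draws per group,
  truncated by rejection at 5% of the group mean (the published PD LC mean
  is close enough to zero that untruncated draws can go negative).
  Defaults reproduce the published cohort-2 summaries with per-subject SD
  recovered as SE·√n: SNc 429 ± 114.9 vs 329 ± 106.2 mm³, LC 8.0 ± 3.45 vs
  5.2 ± 3.75 mm³, ages ≈ 63.5 vs 63.8, n = 33/39. Clinical scores
  (UPDRS-III, MoCA, LEDD, NMSQ, RBD-SQ, disease duration, sex ratios) are
  drawn from the same table's group summaries, independent of volume —
  the published volume–clinical correlations are weak to null, and
  independence is the honest default. Everything is reproducible
  byte-for-byte from the seeds.

What passing tests on these phantoms shows: that the implementation of
realignment, averaging, thresholding and statistics is correct, calibrated
(type-I error ≈ 5%) and powerful at the published effect sizes. What it
does not show: robustness to field inhomogeneity, imperfect nonlinear
normalization, reference-ROI placement error, susceptibility artefact near
the fourth ventricle, or biological variation in nucleus shape — real-data
properties the schematic phantom does not contain.

## Numerical choices and degenerate inputs

- Strict ">" at thresholds; sample SD with n−1; reference regions need ≥2
  voxels and nonzero spread (zero spread raises a degenerate-reference
  error rather than silently segmenting everything).
- Resampling composes any transform chain into one map before a single
  trilinear (images/atlases) or nearest-neighbour (masks) pass; the
  identity transform on an identical grid is an exact copy.
- An empty segmentation is a valid result (volume 0), e.g. when a
  structure's contrast sits below its threshold; an empty *search region*
  is an error.
- With motion and realignment in play, interpolation slightly smooths the
  resampled measurements, which lowers σ_ref measured on the average and
  with it the thresholds; recovered volumes then run some 15–20% above the
  voxelized truth at default contrast. This is a property of the threshold
  rule under resampling itself, shared with the real pipeline, and is why
  volume-recovery validation is quoted for motion-free acquisition while
  the with-motion path is held to a wider documented bound.
- Welch's t from summaries uses t = Δm/√(se₁²+se₂²) with
  Welch–Satterthwaite df; the sample form delegates to it. ANCOVA raises on
  rank-deficient designs instead of silently dropping columns.
- The acceptance script derives all sub-seeds from `--seed` and touches
  nothing outside the repository.

## Problem sizes

Validation runs use one default phantom subject (6 registrations) for
registration recovery, three subjects for volume recovery, 1000 random
16×16×8 images for the brute-force equivalence, 2000 volumes-only null
cohorts for type-I calibration, 200 for effect detection, and 50 for the
replicate cohort statistics — sizes at which every stochastic check has
comfortable Monte-Carlo margins while the whole suite stays fast.

## Known limitations

- The crescent/rod geometry is schematic; no nigrosome substructure, no
  left/right asymmetry, no age effect on true volume.
- No DICOM ingestion; NIfTI-1 only. 4D support is limited to the
  measurement-series reader.
- Nonlinear warps are applied only as precomputed chains; dense
  displacement-field links are not implemented in the chain composer.
- The logistic combined marker is fit and evaluated in-sample, as in the
  source analysis; its AUC is optimistically biased and should be
  cross-validated before any clinical claim.
- Demographic χ² comparisons (sex, race) are intentionally not implemented.
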