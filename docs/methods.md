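# Methods

This note documents the models, conventions and numerical choices behind
`metgrade`, in the order the pipeline runs them.

## Scope and assumptions

Input volumes are assumed already calibrated to SUV; no dose/body-weight
normalization, DICOM handling or reconstruction simulation is performed.
All voxel indices are 0-based `(x, y, z)` with `x` fastest on disk; voxel
spacing may be anisotropic and is carried in millimetres. Volumes and masks
are exchanged as NIfTI-1; masks are persisted in the geometry of their
source volume with pass-through affines.

## Segmentation

Both segmentations are seeded from the SUVmax voxel inside an operator
bounding box (the minimal reproducible surrogate for a rough contour drawn
around the target; masks depend on the box only through which voxels it
contains and which attains the maximum). Ties for the maximum, and all
distance ties, break lexicographically on (z, y, x).

* **Threshold VOI**: voxels in the box with SUV ≥ 0.40 × SUVmax(box). The
  comparison is inclusive so the mask can never be empty, and the mask is
  restricted to the 26-connected component containing the SUVmax voxel so
  that disjoint hot spots inside the box cannot leak in. The threshold is
  applied to raw SUV; grey-level resampling is a feature-extraction step.
* **Fixed ROI**: the 81 voxels nearest the SUVmax voxel by physical
  Euclidean distance. 81 is neither a cube nor a standard sphere count; the
  nearest-81 ball is spacing-aware, approximately spherical, and guarantees
  the exact count. On strongly anisotropic grids (3 mm slices, sub-mm
  pixels) it degenerates naturally to an in-plane disc. A 9×9×1 square
  alternative is available (`roi_shape="square2d"`).

Raising the threshold fraction can only shrink the VOI (monotonicity), and
both masks always contain the SUVmax voxel; the test suite asserts both.

## Grey-level discretization

Absolute resampling with 64 levels over [0, 20] SUV. The bin width uses the
`(max − min)/(n_bins − 1)` convention — 20/63 ≈ 0.317 SUV — rather than
dividing by `n_bins`, matching the arithmetic that produces the canonical
0.317 figure. Mapping: `level = floor((SUV − min)/width) + 1`, clipped to
[1, 64]; out-of-range values are clipped rather than excluded so a region
has the same voxel count before and after resampling. The edge-assignment
convention (closed lower edges, final level absorbing the upper bound) is a
documented choice; monotonicity and level bounds are property-tested.

## The 44-feature panel

Order is frozen (conventional, histogram, shape, GLCM, NGLDM, GLRLM, GLZLM)
because downstream selection breaks ranking ties by column order.
Conventional and shape features are computed on raw SUV and physical
geometry, histogram and texture on the discretized levels.

* **Conventional**: min/mean/max SUV; TLG = mean SUV × volume (mL); the ROI
  intensity mean (RIM) is by construction equal to the mean but kept as a
  separately named column — the duplication is part of the panel's
  definition, not an accident of this implementation.
* **Histogram**: central moments of the discrete level distribution;
  kurtosis is non-excess (m₄/m₂²). A constant region returns skewness =
  kurtosis = 0 by convention so no cell of the cohort matrix is ever
  missing (the selection stage cannot handle missing cells).
* **Shape**: surface area from a marching-cubes mesh at iso-level 0.5 of
  the binary mask after Gaussian anti-aliasing with sigma 0.8 voxels. The
  anti-aliasing removes the staircase bias of meshing a binary grid, which
  otherwise overestimates a smooth surface's area by ~10% (a digital ball
  of radius 10 then measures sphericity ≈ 1.01 instead of 0.91). Thin
  regions that vanish under smoothing fall back to the raw binary mesh,
  and single-voxel masks to exposed voxel-face area. Sphericity
  π^{1/3}(6V)^{2/3}/A; compacity A^{3/2}/V (dimensionless, larger = less
  compact).
* **GLCM** (7 indices): symmetric co-occurrence matrices at Chebyshev
  distance 1, one per direction, averaged over the 13 unique 3-D
  directions (the field's usual convention, rather than summing matrices);
  directions with no in-mask pair are skipped. A zero-variance direction
  contributes Correlation = 1.
* **NGLDM** (coarseness, contrast, busyness): the Amadasun–King
  formulation on the 26-neighbourhood; neighbourhood averages use only
  in-mask neighbours, and voxels with no in-mask neighbour are excluded.
  On a constant region the literal coarseness formula diverges, so it is
  capped at 10⁶; busyness and contrast are 0 there.
* **GLRLM** (10 indices): maximal equal-level runs along each of the 13
  directions, Galloway/Chu formulas, direction-averaged. Run percentage is
  excluded so the texture families count 7 + 3 + 10 + 11 = 31.
* **GLZLM** (11 indices, including zone percentage = zones/voxels):
  26-connected equal-level zones, Thibault formulas.

All four texture engines are verified against independent brute-force
literal-formula oracles (per-voxel loops, grid-line run scanning,
breadth-first flood fill) on 100 random small regions to 1e-10 relative
tolerance, plus hand-enumerated examples and 90° rotation invariance.

## Feature selection

Stage 1 ranks features by |point-biserial correlation| with the 0/1 grade —
the absolute value, because a strong negative correlate is equally
predictive. Near-constant columns (standard deviation ≤ 1e-12 relative)
are assigned r = 0 and rank last: a shape index of identically shaped
regions is constant up to float rounding, and its last bits must not win
the ranking.

Stage 2 walks the ranking: at step k a logistic regression of the label on
the top-k features is fitted and the likelihood-ratio p-value against the
intercept-only model recorded; the loop stops at the first step whose
p-value does not *strictly* decrease, keeping the features accumulated
before it (minimum one). The cumulative (nested) variant is the default:
only nested models give the p-value sequence a monotone interpretation. A
univariate per-feature variant is provided (`mode="univariate"`) since the
verbal description of the procedure admits both readings. Fits use Newton
with a BFGS retry for rank-deficient designs (a duplicated column then
leaves the likelihood and the rank-based degrees of freedom unchanged, so
the loop stops); perfectly separated fits count as p = 0 with a logged
warning, and the loop then stops one step later by the non-decrease rule.
No post-hoc p < 0.05 filter is applied — features selected with larger
p-values stay selected.

## Classifier and evaluation

Linear discriminant analysis with shared covariance and empirical class
priors, chosen for its tolerance of the ~70/30 class imbalance; a singular
pooled covariance triggers a shrinkage (`lsqr`) refit. The continuous score
is the posterior probability of low grade.

Cross-validation is stratified (every fold within one sample of the global
grade proportion), seeded and reproducible. k defaults to 5 — small enough
that the smallest subgroup's minority class (7–8 low-grade) still populates
every fold; k is configurable and validated against the minority count.
Per convention, *sensitivity* is the low-grade recall and *specificity* the
high-grade recall; fold metrics are averaged, and pooled-confusion variants
are reported alongside. AUC is computed once on the pooled out-of-fold
scores (per-fold ROC with 3–4 positives is too coarse) with a 95% Wald
interval AUC ± 1.96·SE from the Hanley–McNeil standard error, reported
unclipped — near-perfect AUCs on small cohorts legitimately produce upper
bounds above 100%, and clipping would misrepresent the interval's width.

By default feature selection is re-run inside every training fold
(leak-free); a mode that selects once on the full table before CV is
available (`--mode paper` on the CLI) and the report labels which was used.
Per-group analyses (all patients, each scanner) are independent runs over
manifest subsets, mirroring the fact that different scanners select
different features.

## Phantom cohort generator

The generator emulates the statistical structure the analysis assumes, not
PET physics. Defaults define the study conditions:

| parameter | default | rationale |
|---|---|---|
| n_patients / high fraction | 56 / 0.70 | cohort size and imbalance of the clinical setting |
| scanner split | 24 / 32 | two geometries: 0.4821×0.4821×3 mm (PSF 4 mm FWHM) and 1.17×1.17×3.27 mm (PSF 5 mm) |
| background | 1.0 SUV constant | lesions must sit well above it; variability enters via additive noise (sd 0.08 SUV) |
| peak SUV | U(6,12) high, U(4,9) low | overlapping ranges inside the 0–20 SUV window; higher uptake in high grade |
| lesion profile | plateau, edge_power 4 | `bg + (peak−bg)(1 − r^8)`: near-uniform interior with a fast rim fall-off, so a homogeneous lesion is genuinely homogeneous inside its segmented volume rather than dominated by its own radial gradient |
| semi-axes | 9 mm × U(0.8, 1.3) | realistic tumour size; also keeps the coarse-scanner lesion many voxels across, so the VOI is not all partial-volume rim |
| heterogeneity | amp 0.60 (high) vs 0.05 (low), correlation length 3 mm | multiplicative unit-variance Gaussian random field; the length sits above the PSF half-widths (so blur attenuates but does not erase it) and well below the lesion size (so it is texture, not a whole-lesion offset) |
| necrotic core | 35% volume fraction, ×0.35 uptake, high grade only | the low-uptake center typical of aggressive tumours; adds a scanner-robust histogram signature |

Everything is a pure function of (spec, seed); identical specs reproduce
bit-identical volumes and manifests. The *null* variant
(`null_cohort_spec`) equalizes every per-grade setting, producing labels
that carry no image information — the pipeline's pooled AUC on it must sit
at chance, which the acceptance suite asserts.

What the phantoms do **not** emulate: reconstruction artefacts, anatomical
background structure, spatially varying noise, multi-focal or infiltrative
lesion geometry, and inter-scanner feature shifts beyond geometry/PSF/noise.
Passing the end-to-end tests therefore demonstrates that the pipeline
recovers a planted, strongly separable texture signal under realistic
geometry and imbalance — it does not certify clinical performance on real
tumours.

## Problem sizes and numerics

Default grids are 64×64×20 voxels — large enough for a two-voxel margin
around the biggest lesions on the fine in-plane grid, small enough that a
full 56-patient run (segmentation, 112 feature extractions, six
select+evaluate analyses) completes in well under a minute. Random-number
streams derive from a single cohort seed via `SeedSequence`; the evaluation
and selection stages take their own seeds so results are reproducible
per-stage. Degenerate cases (constant regions, single-voxel masks,
rank-deficient designs, singular covariances) all have documented finite
conventions rather than NaNs, because the cohort matrix must never contain
missing cells.

## Known limitations

* The 81-voxel ROI's 3-D ball shape is one reading of a fixed-size ROI;
  the in-plane square alternative is provided but not the default.
* Whether selection should be nested in CV is genuinely ambiguous in the
  verbal description of the procedure; both modes exist and reports label
  which ran. The non-nested mode is optimistic on small cohorts.
* The Hanley–McNeil interval is a normal approximation; it is reported
  unclipped by design and can exceed [0, 1].
* The per-patient logistic fits in the selector assume independent rows;
  applying it to a table holding both segmentations of each patient mixes
  dependent rows, so selection is always run per segmentation kind.
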