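# Methods

This note documents the models, parameter choices and numerical decisions
behind `petseg`, and what the phantom-based validation does and does not
demonstrate.

## Problem setting

Quantitative whole-body FDG-PET analysis of multi-lesion disease
(lymphoma being the archetype) needs every avid lesion delineated before
features such as MTV, TLG or dissemination distances can be computed.
Fully manual slice-by-slice contouring is slow and observer-dependent;
the semiautomatic alternative implemented here asks the observer only for
a generous 3D ROI enclosing each lesion plus surrounding background, and
delineates the lesion automatically inside it. All segmentation operates
on the PET grid in body-weight SUV; CT is not used.

## Segmentation models

**Thresholds.** The absolute rule keeps ROI voxels with SUV ≥ 2.5 (a
widely used baseline-MTV cut-off in lymphoma); the relative rule keeps
voxels ≥ 41% of the ROI's SUVmax (the EANM-recommended fraction for solid
tumours). Comparisons are boundary-inclusive (≥), so at fraction 1.0 the
SUVmax voxel itself survives. Thresholds are strictly per-ROI.

**1D k-means.** Lloyd iteration on the ROI's intensity sample. Initial
centroid *i* of *k* is the 100·(2i−1)/(2k)-th linear-interpolation
percentile of the sample — symmetric, spreads the centroids over the
distribution and makes empty initial classes unlikely. Iteration stops
when no assignment changes (or after 300 sweeps). Ties in the nearest-
centroid assignment go to the lower class index; classes are relabelled
ascending by mean. If two fitted means coincide the duplicates are merged
and the fit retried with k−1; a sample with fewer distinct values than
classes is reported as degenerate.

**Bayesian (Gaussian mixture + MAP).** A k-component univariate Gaussian
mixture fitted by EM, initialised deterministically from the k-means
solution (means; class proportions as weights; within-class variances).
Convergence: mean log-likelihood gain per sample < 1e-6, at most 500
iterations (non-convergence returns the best iterate with a warning
flag). Variances are floored at 1e-8 × the overall sample variance so
point-mass classes survive; the E-step runs in the log domain. Voxels are
assigned to the class with maximal posterior probability. Because the
initialisation is deterministic, no randomness enters segmentation at
all.

**Self-adaptive configuration (SAC).** Fit three classes (background /
border / lesion, means m₁ ≤ m₂ ≤ m₃), compute
coef = (m₃ − m₁)/(m₃ + m₁) — an asymmetry index of the ROI's intensity
extremes, in [0, 1] since SUV ≥ 0 — and branch:
coef < 0.90 → lesion = top class only (border → background);
coef ≥ 0.94 → lesion = upper two classes (border → lesion);
otherwise → refit with two classes, lesion = upper class. The 0.90/0.94
cut-offs are configurable defaults. A ROI that cannot support the 3-class
fit (too few voxels or distinct intensities, e.g. a noise-free phantom
ROI with exactly two grey levels) falls back to the 41% relative
threshold for that ROI with a logged warning — batch runs never die on a
degenerate ROI.

**Lesion splitting.** The union mask is decomposed into connected
components under 26-connectivity (configurable to 6/18), labelled in
descending size order.

### Known behaviour of the SAC branches

At moderate lesion-to-background contrast (roughly 3–15:1 over a
soft-tissue background, which covers most clinical lesions) the
coefficient sits well below 0.90, so the border class is assigned to
background and the mask is the top intensity class alone. On volumes
degraded by a scanner-class point-spread function this is a *tight*
delineation: the partial-volume ramp is excluded, and against the true
(pre-blur) geometry the volume is underestimated by roughly a third to a
half for lesions large enough to have an intensity plateau. The method
was designed to reproduce expert manual delineation, not the true
geometry; its reproducibility advantage (below) and its stability are the
properties the phantom validation can meaningfully probe. Validation runs
that compare against true phantom geometry show exactly this designed
bias, and the test suite records it openly rather than masking it.

## Feature definitions

31 default features in a registry (swappable without code change):

* **First-order intensity (13):** SUVmax/min/mean/median, SD, variance,
  range, mean absolute deviation, population skewness and excess
  kurtosis (defined as 0 for constant regions), energy (Σv²), entropy
  and uniformity on a 64-bin fixed-width histogram over [0, region
  SUVmax].
* **SUVpeak:** maximum over mask voxels of the mean SUV in the 3×3×3
  neighbourhood centred on the voxel. Neighbourhoods may extend beyond
  the mask (they sample surrounding tissue) but are truncated at volume
  borders — the mean is over existing voxels, never zero padding, which
  would bias edge peaks downward.
* **TLG:** MTV × SUVmean of the same mask, in cm³.
* **Geometry (8):** MTV (voxel count × voxel volume), surface area,
  surface-to-volume ratio, sphericity π^(1/3)(6V)^(2/3)/A, two
  compactness variants, spherical disproportion, maximum 3D diameter
  (largest pairwise distance between voxel centres, computed on the
  convex hull for large masks). Surface area defaults to the
  marching-cubes 0.5-iso-surface mesh; the binary mask is anti-aliased
  with a 0.7-voxel Gaussian first, because meshing the raw staircase
  overestimates smooth surfaces by 6–9% (a digital sphere then meshes to
  within ~1–2% of 4πr²; lesions too small to survive the smoothing fall
  back to the raw mesh). A face-counting estimator (`surface="voxel"`),
  exact for axis-aligned boxes, is available for geometric sanity checks.
* **Dissemination (8, patient scope):** lesion count; largest pairwise
  centroid distance (Dmax); largest distance from the highest-TLG
  lesion's centroid to any other ("bulk" Dmax); mean and SD of pairwise
  centroid distances; largest surface-to-surface distance between
  distinct lesions; SD of per-lesion MTVs; mean centroid distance from
  the MTV-weighted burden centroid. All distances use voxel-centre
  coordinates in physical mm; centroids are unweighted except the burden
  centroid. Published dissemination panels vary in their exact
  definitions; this set is one literature-consistent choice and should
  be treated as such when comparing against other software.

Representative-lesion selection maximises TLG or SUVmax, ties broken by
larger MTV then smaller lesion id. Whether a conglomerate counts as one
lesion is controlled by the connectivity option.

## Agreement metrics

Dice is computed on the union of all per-ROI masks (patient basis /
total tumour burden); a per-lesion-mean variant is deliberately not the
default since the pooled union is the common reporting convention. Two
empty masks score 1.0 (agreement on absence, logged), one empty mask 0 —
needed for degenerate phantoms, unstated in the usual definition.

Feature agreement uses ICC(2,1) — two-way random effects, single
measure, absolute agreement — computed from the ANOVA closed form
(MSR − MSE)/(MSR + (m−1)MSE + m(MSC − MSE)/n). Absolute agreement is the
appropriate form when two raters are meant to report the same number: a
systematic offset between raters lowers it, while shared rescaling of
all raters leaves it invariant. A zero-variance matrix has no defined
ICC and returns NaN with a warning. Hypothesis testing on paired values
is intentionally out of scope; the report exposes the raw pairs.

## Phantom design

A phantom is a uniform background (default SUV 1.0) carrying ellipsoidal
lesions of configurable uptake, blurred with a Gaussian point-spread
function (default FWHM 7 mm, the clinical time-of-flight scanner class)
and degraded with additive zero-mean Gaussian noise clipped at 0
(default SD 0.1 = 10% of background) — a standard desk-scale
approximation of post-reconstruction PET noise; Poisson/reconstruction
modelling is deliberately omitted. Grids default to 64³ voxels at 2 mm
isotropic. The enclosing ROI of each lesion is its ground truth dilated
by 3 voxels, mirroring the instruction that an ROI contain the whole
lesion plus surrounding background. Observer variability is simulated by
dilating/eroding each ROI by a seeded random amount up to ±1 voxel with
a random structuring element; an erosion never empties a ROI.

Cohort sampling draws per-patient lesion counts (1–3), per-axis radii
(7–13 mm with 0.8–1.25 axis ratios) and uptakes (4.5–10 SUV) uniformly,
placing lesions by rejection sampling so they do not collide. The uptake
and size ranges emulate the staging-lymphoma population statistics the
toolbox targets (SUVmax ≈ 4.5–10, MTV ≈ 1.3–10 cm³). A `low_contrast`
preset samples uptakes at 1.5–2.4 over background 1.0: below contrast
1/0.41 ≈ 2.44 a 41%-of-SUVmax cut-off falls at or below the background
level, which is the regime where relative thresholding degenerates and
the reproducibility comparison between clustering and thresholding is
informative. Lesion `suv` is the pre-blur uptake; observed SUVmax is
lower after the point-spread blur. All randomness flows from a single
integer seed; identical seeds give bit-identical cohorts.

**What the phantoms do not model:** heterogeneous background (liver,
mediastinum, brain, bladder), nearby non-tumour hot tissue, intra-lesion
uptake heterogeneity, respiratory motion, and reconstruction artefacts.
Consequently phantom results overstate the stability of relative
thresholds at high contrast (the uniform background is far below the
cut-off, so threshold masks are insensitive to ROI placement there) and
say nothing about ROI-drawing difficulty near hot organs. Passing tests
demonstrate algorithmic correctness and the documented comparative
properties under these idealised conditions, not clinical performance.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use 20-patient cohorts
on 64³ grids for recovery and reproducibility runs, 100 seeded instances
(n ≤ 500) for the k-means/Lloyd equivalence, 20 replicates of 800 points
for mixture recovery, and 1,000/100/50 random instances for the
Dice/ICC/SUVpeak oracles — sizes chosen so the whole suite runs in well
under a minute on one CPU while keeping every statistic stable across
seeds.

## Numerical and degenerate-input conventions

* Grids are (x, y, z) voxel-major with strictly positive spacing in mm;
  masks/label maps are stored as uint8/uint16 NIfTI on the PET grid, no
  resampling is performed, and alignment is checked to 1e-3 mm.
* SUV conversion: SUV = activity [Bq/mL] × body weight [g] / injected
  activity [Bq]; images are assumed decay-corrected by the scanner.
* Threshold comparisons are ≥; argmin/argmax ties resolve to the lower
  index; component-size ties keep scan order.
* Empty per-ROI masks are retained (with a warning) rather than dropped,
  so per-ROI bookkeeping stays aligned with the ROI set.
* ICC requires n ≥ 3 targets, m ≥ 2 raters, no missing cells.

## Limitations

Beyond the phantom realism caveats above: the feature registry's
dissemination definitions are one defensible choice among several (see
above); no DICOM or
RT-STRUCT I/O (NIfTI only); body-weight SUV only; no deep-learning or
CT-guided segmentation; ROIs cannot overlap by construction of the
label-map representation, so conglomerate lesions sharing voxels must be
enclosed by a single ROI.
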