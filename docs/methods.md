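# Methods

## Scope and model

`phmribold` analyses pharmacological-challenge BOLD series acquired
without a task: each subject contributes one 4D volume whose time axis
splits into a pre-injection control window and a post-injection window.
The method treats the acquisitions inside each window as independent
samples — no hemodynamic convolution, no autocorrelation correction —
which mirrors the classic awake-rodent phMRI analysis the package
implements. Whether that independence assumption is defensible is a
property of the acquisition (6 s repetition time, slow drifts removed by
the magnitude threshold), not of this code; the statistics are computed
exactly as documented.

## Voxelwise detection

* Percent change is always relative to the control-window mean of the
  same voxel; voxels with a non-positive baseline mean are flagged
  invalid and excluded from the voxel count V.
* The per-voxel test is Welch's two-tailed unequal-variance t-test
  (Welch–Satterthwaite degrees of freedom). Degenerate voxels follow a
  fixed convention: both windows constant and equal → p = 1; constant
  but different → p = 0.
* The false-positive filter is the rank-based step-up rule
  `P(i) ≤ (i/V)·(q/cV)` with defaults q = 0.2 and cV = 1 (the
  Benjamini–Hochberg form; cV > 1 gives the dependence-robust variant).
  One implementation serves both the voxel filter and the region-list
  cutoff. Ties in p are handled by a stable sort; step-up semantics make
  the retained set tie-invariant.
* The ROI for the voxel-level filter is the whole per-subject brain
  mask (~15 000 voxels at full scale); no per-structure filtering
  happens at this stage.
* The ±2% magnitude threshold applies to the post-injection mean
  percent change, two-sided, and is required *in addition to*
  significance (the alternative reading — magnitude as a fallback — is
  not implemented). Sign assignment happens at the same step, so the
  positive and negative components are disjoint by construction.

## Motion exclusion

Displacement is measured relative to the first acquisition (the
alternative, framewise scan-to-scan displacement, is not used; with
random-walk-like motion the from-reference maximum is the stricter of
the two). The exclusion threshold is half the in-plane voxel edge,
93.75 µm = 187.5/2, derived from the stated in-plane resolution rather
than a rounded figure; only in-plane axes (X, Y) trigger exclusion, and
the rule is strictly-greater, so motion of exactly half a voxel keeps
the subject. SD uses the population (ddof = 0) formula.

## Registration

A nine-parameter affine (3 translations mm, 3 rotations rad, 3 per-axis
scales, applied about the template foreground centroid) maximises the
normalised cross-correlation between the warped subject and the
template. Choices worth knowing:

* Similarity is evaluated at template foreground voxels subsampled at
  the configured separation (default 0.50 mm) after Gaussian
  pre-smoothing (default FWHM 0.35 mm); the `quality` knob (default
  0.97) sets the fraction of candidate sample points kept.
* Optimisation is Powell's derivative-free method over scaled
  parameters, coarse level (doubled smoothing and separation) seeding a
  fine level. Deterministic for fixed inputs.
* Inside the cost, the subject volume is sampled with cubic B-splines,
  not trilinearly: trilinear interpolation attenuates structure in a
  position-dependent way and measurably displaces the NCC optimum
  (~0.5% in scale on our synthetic fields), while spline sampling
  recovers synthetic ground-truth parameters to ~1e-4. Trilinear
  interpolation is used where the method prescribes it — composite
  reconstruction — and nowhere inside the optimiser.
* A mild penalty on the out-of-bounds sample fraction keeps the
  optimiser from shrinking the overlap; total loss of overlap raises a
  registration error.
* The similarity metric is NCC because subject and template are
  same-modality anatomies; no mutual-information option is provided.

Composites map every atlas voxel through each subject's inverse
transform and average trilinearly sampled contributions. The default
averages over all in-bounds subjects, counting non-retained voxels as
zeros; `include_zeros=False` averages nonzero contributors only.
Per-subject maps can be smoothed (default FWHM 0.8 mm) before
compositing; the smoothing is applied at the compositing step, not
before voxel counting. Coordinates are 0-based voxel indices with
physical mm positions at `index · voxel_size`; transforms act on mm.

## Regional statistics

* The group-level statistic is the per-subject voxel-count vector;
  group medians are reporting only.
* Kruskal–Wallis uses mid-ranks with tie correction and the chi-square
  approximation (identical-everything inputs short-circuit to H = 0,
  p = 1, where the rank test is undefined). Post-hoc Wilcoxon rank-sum
  tests are exact for untied samples with n ≤ 8 per side, otherwise
  normal-approximated with tie correction, and are reported at p ≤ .05
  without further multiplicity correction — the region-list step-up rule
  applies to the omnibus p-values only.
* The effect size reported as ω² is the chance-corrected rank
  estimator `(H − k + 1)/(n − k)`, clipped to [0, 1]; it is zero at the
  null expectation E[H] = k − 1. The uncorrected `H/(n − 1)` variant is
  available (`effect_size_uncorrected`). No closed-form "omega squared"
  exists for a rank test, so which variant a given published table used
  is generally not recoverable; both land within a few percent of each
  other at cohort sizes of ~29.
* The dose-profile classifier uses strict inequalities with a
  configurable tolerance (default 0): flat when all four medians agree
  within tolerance, then descending/ascending, then U-shaped (middle
  dose smallest), then single-dose-max — which additionally requires the
  top dose to clear the runners-up by more than the tolerance, so
  one-voxel edges do not count as maxima under a nonzero tolerance.
  Ties fall through to flat.

## Time series and ANOVA

Region-set time courses average, per acquisition, the percent change of
the set's voxels — by default only voxels retained in the subject's
activation map of the requested sign, with an explicit `voxels="all"`
fallback (the pipeline falls back automatically when a subject has no
retained voxels in the set, as vehicle subjects typically do not). The
treatment comparison is a two-factor fixed-effects ANOVA on
treatment × time-bin cells (default 10 bins over the post-injection
window; the baseline window is excluded), subjects being the replicates
within cells. Published F statistics from this design depend on the
time-binning of the original analysis, which is not recoverable from a
printed F alone; the implementation makes the binning explicit and
configurable instead.

## Synthetic data

The generator emulates the acquisition the pipeline targets: 96×96×18
grids of 0.1875×0.1875×0.75 mm voxels, 150 acquisitions with a
50-acquisition control window, four treatment groups of eight (with the
attrition pattern 7/8/6/8 available in configs), ~15 000-voxel brain
masks, and 134 Voronoi-parcel regions (convex, hence connected, and
never empty).

* **Anatomy** is an analytic field: a smooth ellipsoidal envelope
  modulated by one Gaussian bump per region (the smooth analogue of
  per-region mean intensity) plus ~60 finer texture blobs. Because the
  field is evaluable at any physical point, subject volumes are exact
  evaluations in the subject frame rather than resampled grids — ground
  truth for registration tests carries no interpolation bias. Real
  anatomy differs in having tissue boundaries and partial-volume
  structure; passing registration tests therefore demonstrate optimiser
  and objective correctness, not robustness to real-contrast conditions.
* **Effects** are region-confined signed percent-change steps (optional
  5-acquisition linear ramp) applied to a seeded fraction of the
  region's voxels from the injection acquisition onward; the default
  library includes descending, U-shaped and low-dose-maximal profiles.
  Positive and negative truth masks are disjoint by construction and
  recorded per subject.
* **Noise** is independent Gaussian per voxel and acquisition
  (default SD 2% of baseline — chosen so that effect-free runs stay
  comfortably inside the 2% fluctuation threshold, the only calibration
  anchor the protocol states) plus an optional global linear drift
  (default 0.005%/acquisition). No physiological or k-space noise; the
  false-positive calibration consequently tests the filter's behaviour
  under the noise model the threshold was designed to absorb, not under
  structured physiological confounds.
* **Motion** is a zero-mean per-axis random walk scaled to a 10 µm RMS
  end-of-run displacement (typical observed awake-mouse magnitudes),
  with an optional injected spike for exclusion testing.
* Determinism: a cohort's root seed is expanded per subject and stage
  via a seed sequence; identical config + seed reproduce every file
  byte-for-byte.

## Problem sizes used in validation

The automated suites run on reduced grids chosen to exercise every code
path at interactive scale: 48×48×9 (doubled voxel size) for null
calibration — 8 subjects × 50 Monte-Carlo replicates of full-length
150-acquisition series — and 48×48×18 with 12 regions for registration
recovery and the end-to-end low-dose-effect experiment (4 groups × 5
subjects, real registration throughout). Full-scale geometry is checked
where cheap (atlas mask size, region count).

## Known limitations

* No motion correction or realignment — excluded subjects are dropped,
  matching the protocol being implemented.
* No cluster-extent or permutation inference at the voxel level.
* Regions are analysed marginally; no spatial or hierarchical model
  links neighbouring regions.
* The affine registration is translation/rotation/scale only (no shear,
  no nonlinear warp) by design.
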