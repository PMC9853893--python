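# Methods

This note documents the models, parameter choices, and numerical
conventions behind `gmprog`, and what the synthetic experiments do and do
not establish about real data.

## Study design and data model

The pipeline targets a longitudinal two-group VBM design: controls (HC)
with one scan, patients (AD) with a baseline (T1) and a one-year follow-up
(T2) scan. Inputs are modulated, spatially normalized grey-matter volume
maps on a single common grid plus a phenotype table (group, timepoint,
sex, age, CDR, MMSE, MoCA). No resampling is implemented: mismatched grids
are a hard error, because the intended inputs are already template-space
maps. Values must be finite and non-negative (modulation preserves local
tissue volume).

## Cortical skeleton

GMV is measured on the skeleton — the one-voxel-thick medial surface of
the cortical plate of the *cohort-mean* map (all scans weighted equally).
The default extraction is a ridge criterion: after Gaussian smoothing
(σ = 2 mm), a voxel in the thresholded mask (mean GM ≥ 0.2) is kept when
it is a local maximum of the smoothed map along the eigenvector of its
local Hessian with the most negative eigenvalue, compared against
trilinearly interpolated values one voxel away on either side. This
matches the "center of the plate" semantics of skeletonization on graded
maps; a morphological-thinning fallback (`method="thinning"`) exists for
maps whose ridge is flat. The 0.2 threshold and 2 mm smoothing are
conventional tract/grey-matter-skeleton defaults; both are exposed in the
config. Per-subject values are sampled directly at skeleton voxels in a
fixed lexicographic order; no projection of individual local maxima onto
the skeleton is performed (a deliberate simplification — projection rules
are tool-specific and add a free parameter the rest of the pipeline does
not need).

## Voxelwise statistics and region groups

Voxelwise maps use the pooled-variance Student t (the common VBM
convention); demographic comparisons use Welch's t, which is also
computable from printed summary statistics, plus a Yates-corrected
chi-squared for sex. No covariates enter the voxelwise models. Zero-
variance voxels yield t = 0, p = 1 and are counted, not NaN-ed. FDR is
Benjamini–Hochberg (statsmodels) at α = 0.05; the test suite holds it to
exact agreement with the brute-force step-up rule. Clusters are
26-connected components; the extent filter is strict ("> 30 voxels" keeps
size ≥ 31). Region groups:

* **overlapped** = significant decrease in both AD-vs-HC maps
  (voxelwise intersection, then cluster filter);
* **continuing** = significant decrease at T2 vs HC AND in the paired
  map, minus overlapped voxels (default rule; an alternative
  "significant at T2 but not T1" rule is selectable via
  `continuing_rule="t2_not_t1"` since the verbal definition of
  "continuing decrease" admits both readings);
* **progressive** = paired-map decrease minus the other two categories.

Subtraction uses the *filtered* region masks, so the three categories are
disjoint by construction. Anatomical names for discovered clusters are a
ground-truth-manifest lookup (best Dice on the skeleton), not an atlas
query. Because between-subject sampling noise moves whole regions'
statistics together, a region planted as "progressive" occasionally
crosses the cross-sectional threshold and is captured by the continuing
rule instead; the pipeline still names and uses such a cluster as the
corresponding anatomical feature, and recovery is scored per planted
region over all derived clusters.

## Covariance network and cross-lagged effects

An SCN edge is the across-subject Pearson r of two regions' mean GMVs
within a group. The group-difference test pools the two groups, permutes
labels preserving group sizes, and recomputes r_A − r_B (default 10,000
permutations); significance is the observed difference falling outside the
null's central 95% (two-tailed), and the reported p uses the add-one
estimator (never exactly 0). Edge tests are reported uncorrected; a BH
option exists at the caller's level since the edge family is small.

With only two timepoints a time-series causality model is not
identifiable, so the "causal" effect is defined as the two-wave
cross-lagged standardized coefficient: the coefficient of x(T1) in
OLS of y(T2) on {y(T1), x(T1)} across patients (only patients have two
scans). Stability is assessed by bootstrap over subjects (default 10,000
resamples, percentile 95% interval); the two-sided p compares the
bootstrap distribution against zero with add-one correction. Near-
collinearity of x(T1) with y(T1) (|r| > 0.999) is an error. This pair of
choices (cross-lagged regression + subject bootstrap) is the minimal
well-defined reading of "causal covariance with resampling" for two-wave
data and is isolated behind the module interface.

## Classification

Linear SVM (LIBSVM via scikit-learn), cost C = 1, on the five fixed
region-mean features. LOOCV standardizes features on each fold's training
rows only. For AD-T1 vs AD-T2 the fold unit is the *subject*: both scans
of the held-out patient leave the training set together, preventing
within-subject leakage (scan-level holdout is available via
`paired=False`). Sensitivity takes the patient class (or the later
timepoint) as positive.

## The synthetic cohort

The generator emits `n_hc + 2·n_ad` volumes: a "cortical slab" — a sheet
with a parabolic through-thickness profile peaking (value 0.7) at its
medial plane, 5 voxels thick above the 0.2 threshold — plus six spherical
regions (radius 4 voxels) centered on the medial plane of the default
48×48×24 grid at 2 mm. The slab's analytic medial plane makes the true
skeleton known exactly for skeleton tests. At a medial-plane voxel inside
region R the value decomposes as

    μ·(1 − δ[g,t,R]) + l[g,R]·f_s + κ·g_s·[R source] + γ·g_s·[R target, T2]
      + b[s,R] + η[s,R,t] + ε[voxel]

with per-subject latents f (covariance factor) and g (causal trait) shared
across the subject's two scans, a stable subject-region effect b
(sd 0.14), per-scan region scatter η (sd 0.02), and iid voxel noise ε
(sd 0.04). Off-plane voxels scale the whole column by the same factor, so
the model holds exactly where sampling happens. Three noise scales are
needed (not one): the stable effect b dominates *between-subject*
variance, the scan-level η and voxel-level ε dominate *within-subject*
variance, and that separation is what lets a 10% progressive decline be
detected by the paired test (within-subject d ≈ 0.9) while remaining
invisible cross-sectionally (between-group d ≈ 0.4), as in the design
being emulated.

Planted conditions (defaults):

* atrophy δ (T1, T2): frontal/hippocampus (0.45, 0.48) → overlapped;
  cingulate (0, 0.28) → continuing; bilateral STG and left caudate
  (0, 0.10) → progressive. Regions intended for cross-sectional detection
  have voxel-level Cohen's d ≥ 1.2.
* covariance: loadings on f for STG-right and caudate-left in HC only,
  sized to give an edge correlation of 0.7 in controls and ~0 in patients.
* cross-lagged effect: κ = 0.07 on the source (overlapped) regions at both
  timepoints, γ = 0.05 on target regions at T2 only, giving a true
  standardized cross-lagged coefficient ≈ 0.19 (recorded in the manifest).
* behavior: the patients' MoCA change is generated as a correlated mixture
  with the standardized planted GMV-change signal of the right-STG region,
  correlation 0.44; MoCA missing at both timepoints for 2 of 40 patients
  (38 complete), and for 2 of 45 controls.
* phenotypes: group-specific truncated normals parameterized by the
  published means/SDs/ranges (ages, CDR, MMSE, MoCA at baseline), sex
  counts fixed at 22/18 (AD) and 27/18 (HC), CDR ≡ 0 for controls,
  follow-up age = baseline + 1.07 y. Scores are treated as independent
  given group; their mutual correlation structure is not modeled.

What the generator does **not** emulate: scanner artifacts, multi-site
effects, segmentation error, spatially correlated noise, anatomical
geometry (gyrification), or partial-volume mixing at region borders.
Passing tests therefore demonstrate the *statistical* correctness of the
pipeline under the planted model — calibration, power, recovery — not its
robustness to real acquisition physics.

## Validation experiments and problem sizes

Calibration and recovery studies (`gmprog.experiments`) use the design
scaled to a 24×24×12 grid (radius-2 spheres) so that hundreds of cohorts
run in seconds each: 800 null cohorts for the edge-test type-I error
(nominal 5%), 100 planted cohorts for its power, 500 cohorts for the
behavior-coupling recovery (region means over the planted masks, isolating
the coupling model from detection), 500 direct simulations for the
cross-lagged closed-form recovery, and 120+ null cohorts through the full
skeleton + paired-map + FDR chain for voxel-level false positives. The
replication run itself uses the full default grid. Measured sample
correlations recover the planted 0.44 coupling at ≈ 0.42 on average — the
small shortfall is the expected attenuation from integer rounding of MoCA
scores, voxel noise in region means, and the small-n bias of Pearson's r.

## Numerical conventions and degenerate inputs

Seeds: every stochastic stage takes an explicit seed; the pipeline derives
per-stage seeds from one master seed and records them in the report, and
reruns are exactly reproducible (stage timings aside). Empty thresholded
masks, empty regions, broken longitudinal pairing, orphan volumes or
phenotype rows, non-finite or negative map values, and degenerate
variances all raise typed errors naming the offender rather than
propagating NaNs. Permutation and bootstrap p-values use add-one
estimators and cannot be zero. Cluster peak voxels are the maximum |t|
voxel; ties resolve to the first in lexicographic order.

## Known limitations

* Direct skeleton sampling (no per-subject projection) slightly blurs the
  measurement when an individual's plate center is off the group skeleton;
  with the synthetic slab this effect is absent by construction.
* The cross-lagged coefficient is a descriptive two-wave quantity; it does
  not identify causal direction under unmeasured confounding.
* The permutation edge test assumes exchangeability of subjects across
  groups under the null; covariate imbalance (not modeled here) would
  violate it.
* Region features assume the five canonical regions were detected; on
  data without a ground-truth manifest the classifier falls back to all
  derived region columns.
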