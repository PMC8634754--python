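# Methods

## The ALPS index

At the level of the lateral-ventricle body, the perivascular spaces around
the medullary veins run right–left (the image x axis), perpendicular both to
the projection fibers (inferior–superior, z) and to the association fibers
(anterior–posterior, y). Water movement along the perivascular spaces
therefore contributes to x-axis diffusivity in both fiber areas, while the
perpendicular diffusivities (Dyy in the projection area, Dzz in the
association area) are unaffected by it. The index is the ratio

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

computed from the mean diagonal tensor components inside two 5-mm spherical
ROIs placed on a color-FA map in the left hemisphere. A value near 1 means no
preferential diffusion along the perivascular direction; higher values mean
more.

Two interpretation choices are deliberate and documented rather than
inferred silently:

* "Diffusivity along x/y/z" means the diagonal elements of the fitted tensor
  in the image frame — exactly what a tensor-derived diffusivity map yields —
  not eigenvalues and not separately acquired per-axis ADCs.
* ROI voxel membership is center-in-sphere (a voxel belongs to the ROI iff
  its center lies within diameter/2 of the ROI center, in world mm). This
  makes ROI contents exactly enumerable by lattice counting, at the price of
  ignoring partial-volume weights; for 5-mm spheres on ~2–3 mm grids the
  difference is a few boundary voxels.

## Tensor estimation

The monoexponential model S = S0·exp(−b·gᵀDg) is log-linearized and solved
per voxel by linear least squares over seven parameters: the six unique
tensor components and ln S0. Weighted least squares (one reweighting pass,
weights equal to the squared predicted signal) is available for noisy data
and coincides with OLS on noiseless data. Numerical choices:

* Non-positive signals (possible under magnitude noise) are clamped to
  10⁻⁶ of the voxel's mean b0 signal before the log; voxels with more than
  25% clamped volumes, or with no b0 signal at all, are flagged and excluded
  from ROI means.
* Negative fitted eigenvalues are kept (the ALPS index uses diagonal
  components, not eigenvalues) but recorded in a QC mask. A non-positive ROI
  denominator aborts the index computation with an error rather than
  returning a sign-flipped value.
* b-vectors are interpreted in the image coordinate frame; no reorientation
  is performed, and a warning is raised if the affine's rotation deviates
  more than 5° from axis-aligned. This matches axial acquisitions aligned to
  the AC–PC line, the intended use.
* Eigenvalues are sorted descending; eigenvector signs are fixed by making
  the first nonzero component nonnegative. FA is clipped to [0, 1] and
  defined as 0 for all-zero tensors.

## The synthetic phantom

Since no public DWI from the source cohort exists, correctness is
established on a phantom whose ALPS index has a closed form. The phantom is
mirror-symmetric about the midline: an isotropic free-water ventricle slab
(3.0×10⁻³ mm²/s), then — moving laterally — a projection-fiber band
(diag(0.60, 0.45, 1.40)×10⁻³, principal axis z), an association-fiber band
(diag(0.55, 1.30, 0.40)×10⁻³, axis y), a subcortical band
(diag(1.40, 0.45, 0.45)×10⁻³, axis x), and isotropic background
(0.8×10⁻³). No published per-region diffusivities exist for this geometry;
these defaults were chosen so the principal axes match the color-FA
conventions and the analytic index (0.575/0.425 ≈ 1.353) sits inside the
range reported for human cohorts (~1.4–1.5). The default grid is 64×64×40
at 1.875×1.875×3 mm — the acquisition's 24 cm field of view and 3 mm
slices at half the in-plane matrix, which keeps a full tensor fit of the
volume under a few seconds on one core; the full 128×128 matrix is a
configuration switch. The gradient scheme is 1 b=0 volume plus 31
directions at b = 1000 s/mm², spread by seeded electrostatic repulsion.

Noise is Rician — the magnitude of a complex Gaussian perturbation,
sqrt((S+n₁)² + n₂²) — with σ defined as S0/SNR on the b0 signal and SNR 30
as the noisy default. Off-diagonal ground-truth components are zero by
default (regions aligned with the axes); an in-plane rotation of all region
tensors is available to exercise the rotation-equivariance of the fit.

What the phantom does **not** emulate: anatomy (bands are slabs, not
tracts), partial-volume mixtures at region borders, motion or
eddy-current artifacts, and spatially varying noise. Passing recovery tests
therefore demonstrates the correctness of the estimator and ROI machinery,
not robustness to those real-data effects.

ROI auto-placement has two modes that must agree on the phantom: label mode
(centroid of the generating region label on the designated
ventricle-body slice, per hemisphere) and heuristic mode, which mimics a
human on the color-FA map: the largest connected component of blue-dominant
voxels (FA > 0.1) gives the projection ROI and the largest green-dominant
component the association ROI, which must lie lateral to it. Placement is
left-hemisphere by default, matching standard practice; a bilateral-average
mode exists but is off by default.

## The cohort simulator

Three groups are drawn — normal controls (n = 36), early Parkinson's
disease (Hoehn–Yahr 1–2, n = 35) and late Parkinson's disease (HY 2.5–4,
n = 36) — with group ALPS calibrations 1.53 ± 0.16, 1.46 ± 0.15 and
1.42 ± 0.18 and the published demographic moments (age, education, MMSE,
disease duration, UPDRS subscores). Distribution choices:

* Unbounded covariates (age) are Gaussian. Bounded scores use
  moment-matched gamma distributions — right-skewed above 0 for duration and
  UPDRS parts, reflected below the ceiling of 30 for MMSE — because a
  truncated normal cannot attain some of the published moment pairs (e.g.
  MMSE 27.86 ± 2.20 with a ceiling 2.14 points away) while the gamma family
  attains any feasible mean/SD exactly, with the skew direction real scores
  show.
* UPDRS total is the sum of the five part scores, so its mean is exactly the
  sum of the part means; its SD is the independence-implied value, which is
  smaller than a real cohort's (parts correlate in patients).
* EPVS (0–4) discretizes a latent Gaussian, latent slope 0.056 per year of
  age, with fixed thresholds (−0.5, 0.8, 1.8, 2.6) chosen so the marginal
  mode and median are 1. Because of the binning, the regression slope of the
  observed ordinal score on age is attenuated relative to the latent slope.
* ALPS is the group intercept plus conditional effects applied around the
  group covariate means — +0.021 per MMSE point and −0.050 per EPVS grade in
  early disease, −0.012 per year of age in late disease — plus Gaussian
  noise whose variance is shrunk by the variance of the linear part, so the
  marginal group SD stays at its calibration. If the slopes alone imply more
  variance than the target, the simulator refuses with a diagnostic rather
  than producing an inconsistent cohort.
* HY-stage and white-matter-hyperintensity distributions within groups are
  schematic categoricals (the source table reports only medians/ranges).

These generator values are the study conditions for every downstream check:
regression-recovery tests ask whether the analysis pipeline returns the
slopes the generator used, within sampling error.

## Statistical analysis

Group comparisons follow the standard clinical-report pattern: two-sample
t-tests for continuous variables, Pearson chi-square for sex, one-way ANOVA
with Tukey HSD post hoc across the three groups, Wilcoxon rank-sum with
median (range) presentation for the ordinal imaging scores, and
multivariate OLS of the ALPS index on age, sex (coded M=1/F=0), duration,
MMSE, EPVS, UPDRS-III, UPDRS total and HY stage within each patient
subgroup. The default t-test is Welch's: on the published age summaries the
Welch p (0.062) matches the reported value where the pooled variant (0.085)
does not. Tukey HSD is the post hoc default. No multiple-testing correction
is applied anywhere, mirroring the reporting convention the pipeline
reproduces. The design-matrix condition number is reported and a warning
issued above 10³ (the motor-subscore/total-score pair is near-collinear).

## Determinism and problem sizes

All randomness flows from one top-level seed through named substreams
(gradients, noise, cohort), so any stage can be re-run in isolation and a
full pipeline re-run is bit-identical, including the gzipped NIfTI outputs.
Default verification sizes — chosen to make sampling error small relative to
the tolerances while keeping a laptop run comfortable — are: full 64×64×40
phantom for the noiseless end-to-end check; 20 noise seeds at SNR 30 for the
Monte-Carlo bias check (fits restricted to the ROI slice); 10⁴ subjects per
group for calibration checks; 5×10³ per group for slope recovery; 10³
replicates for null-calibration of the t-test.

## Known limitations

* The heuristic ROI placer assumes the slice shows coherent, well-separated
  blue- and green-dominant components; it is validated on the phantom, not
  on real anatomy, where manual placement remains the reference.
* The tensor estimator is linear least squares only — no robust (RESTORE),
  free-water-eliminated, or kurtosis variants.
* The cohort simulator draws covariates independently within groups (apart
  from the modeled EPVS–age and ALPS effects); real clinical covariates
  correlate, so regression standard errors in simulated data are mildly
  optimistic.
* No head-motion or eddy-current correction is modeled or applied.
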