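# Methods

This note documents the models, numerical conventions and design choices of
`ctradiomics`, and what the synthetic-data tests do and do not establish
about real data.

## Volumes, masks and discretization

A volume is a 3D scalar array indexed `(x, y, z)` with voxel spacing carried
separately in mm (default CT-like geometry 0.8 × 0.8 × 3.0 mm); the ROI is a
congruent binary mask, binarized at > 0 so probabilistic or integer-label
masks are accepted.  Loading validates congruence (shapes exact, spacings to
1e-3 relative), non-emptiness and finiteness.

Texture matrices operate on integer gray levels.  The default is
equal-width binning of the in-mask min–max range into **Ng = 64** levels
(the in-mask maximum falls in bin Ng); an absolute mode bins caller-supplied
bounds and clamps out-of-range intensities into the end bins.  A
constant-intensity ROI is legal: all voxels get level 1 and a degeneracy
flag propagates to the features that are undefined there.  Discretization is
monotone and preserves the voxel count; both properties are tested.  There
is no canonical bin count for CT radiomics and results depend on it; 64 is a
common middle ground and the setting is echoed into output metadata.

## Feature panel

36 scalars: 2 shape, 4 histogram, 6 GLCM, 2 NGLDM, 11 GLRLM, 11 GLZLM.
(The complete standard run-length and zone families each contain 11
features; quoted panel sizes of 35 for this family set typically drop or
merge one of the non-uniformity entries, which we decline to do — dropping
a standard feature would be arbitrary.)

Conventions that matter:

- **Directions.** GLCM and GLRLM use the 13 unique 3D offsets at Chebyshev
  distance 1, pooled into a single matrix *before* feature computation
  (pooling is robust to rotation and avoids averaging features that are
  nonlinear in the matrix).  Offsets are in voxel units; spatial anisotropy
  is deliberately not compensated for texture — only shape features see the
  mm spacing.  This is a documented limitation shared with much of the 3D
  radiomics literature.
- **GLCM** is symmetrized (each unordered pair counted in both orders) and
  normalized; correlation uses the symmetric marginal and is flagged
  undefined at zero marginal variance.
- **GLRLM/GLZLM** use the Galloway weighting (1/l², l², 1/i², i² and the
  four joint variants, plus the two non-uniformities).  Run percentage is
  normalized per direction, `RP = Nr / (Nd · Nv)`, so it lies in (0, 1] for
  any pooled direction set and reduces to `Nr/Nv` for a single direction;
  zone percentage is `ZP = Nz / Nv`.  Zone connectivity defaults to 26
  (6 available).
- **NGLDM** follows Amadasun–King with the full 26-neighborhood; voxels with
  no in-mask neighbor are excluded from the normalization.  Coarseness
  saturates at `1/ε` (ε = 1e-6) for a single occupied level and is then
  flagged rather than reported as infinite; contrast is 0 by convention in
  that case.
- **Histogram** moments are population moments (kurtosis `m₄/σ⁴`, normal →
  3; an excess option subtracts 3); entropy and energy use an Ng-bin
  histogram of the raw in-mask intensities.  Entropies default to log base 2.
- **Shape.** Volume is voxel count × voxel volume.  Surface comes from a
  marching-cubes iso-surface at level 0.5 of the zero-padded mask after a
  small Gaussian anti-aliasing (σ = 0.7 voxel).  The raw binary iso-surface
  overestimates the area of smooth shapes by ≈ 9% (stair-stepping), which
  distorts sphericity and compacity; σ = 0.7 was fixed once against analytic
  limits — digitized radius-20 ball: sphericity −0.8%, compacity −1.2% from
  `1/(6π)`; 40×20×20 box: area −4.7% from `2(ab+bc+ca)` — and is not a tuning
  parameter of the statistical pipeline.
- Undefined features (moments of a constant ROI, correlation at zero
  variance, single-voxel shape) are emitted as NaN with `valid=False`;
  downstream stages drop incomplete cases rather than imputing.

Every matrix-based and histogram feature is verified to ≈ 1e-12 against
independently coded brute-force references (pair enumeration, lattice-line
walking, flood fill, per-voxel neighborhood averaging, hand-binned moments)
on random small ROIs, and against closed forms on analytic fixtures.

## Screening

The mobile-threshold scan considers every midpoint of consecutive sorted
distinct covariate values whose induced split leaves at least
`min_frac = 0.10` of cases on each side (without a minimum the minimal-p
scan degenerates to extreme splits; the value is a package default, not an
estimate).  The scan is exhaustive and deterministic; p-ties break toward
the smaller threshold.  For binary response the test is the Pearson
correlation test between the dichotomized covariate and the 0/1 outcome
(equivalently the φ coefficient / 1-df chi-square); a Mann–Whitney variant
is selectable.  For survival the criterion is the two-group log-rank test
(observed − expected over distinct event times, hypergeometric variance,
χ²₁), implemented vectorized here for the inner loop of the scan and
cross-checked against lifelines.

Reported p-values are *selected minima* and carry no correction for the
threshold search; this matches the analysis style the package reproduces
and inflates type-I error under the null.  A permutation-based
selection-adjusted p (`screening.permutation_adjusted_p`) is provided as a
clearly labelled extension and is not used by the pipeline.

Cross-correlation pruning computes pairwise Pearson (r, p) on complete
cases, declares an edge when p < α = 0.05, and enumerates maximal mutually
uncorrelated groups greedily, seeding each group by ascending univariate p
and discarding duplicate or subset groups.  Groups are internally edge-free
by construction (asserted in tests).  Constant covariates are excluded with
a warning.  Missing data are handled throughout by omitting cases that lack
any variable needed for the given computation, and every omission is logged.

## Models

**Logistic (response).** Maximum-likelihood fit; backward elimination drops
the largest Wald p above `alpha_stay = 0.05` and refits until all retained
covariates are significant (intercept-only allowed).  Complete or
quasi-complete separation is detected (non-finite SEs or |β| > 15) and the
model is refitted with a small ridge (λ = 1e-3, intercept unpenalized) via
Newton-IRLS, flagged.  The model-level test is the likelihood ratio against
the intercept-only model.  The pipeline fits one such model per
uncorrelated group, on covariates dichotomized at their screening
thresholds ("dealt as factors").

**Cox (survival).** Partial likelihood with Efron tie handling (lifelines).
Zero-variance covariates are excluded with a warning; monotone-likelihood
geometry is flagged from convergence diagnostics.

**Elastic-net Cox path.** Covariates are standardized to unit variance
internally; coefficients are reported on the original scale.  Mixing
defaults to 0.5; the lambda grid is 100 log-spaced values down to
`0.01·λ_max` (the solver's early path stop is overridden at the grid minimum
so the small-lambda limit is computable — it agrees with the unpenalized
fit to < 1%).  Cross-validation uses k = 10 event-stratified folds with a
recorded seed and the Verweij–van Houwelingen deviance
`D_k = −2(ll_full(β_k) − ll_train(β_k))` with the Breslow partial
likelihood; `λ_min` minimizes the mean, and `λ_1SE` is the *largest*
(sparsest) lambda within one standard error (sd over folds / √k) of that
minimum — the conventional reading of a "one standard deviation" rule.
Covariates with nonzero coefficients at `λ_1SE` feed a backward stepwise
Cox fit, which produces the reported model.

**Evaluation.** AUC is the Mann–Whitney pair-counting probability with ties
at ½; the default CI is DeLong via midrank structural components, with a
seeded stratified bootstrap option.  For the Cox model the ROC label is
vital status at last follow-up and the score is the linear predictor — the
only labelling under which a single AUC for a survival model is
well-defined without a horizon; a horizon-restricted variant can be
computed from the same outputs.  Hosmer–Lemeshow uses deciles of predicted
risk, merging tied-quantile groups (df adjusted and flagged; fewer than 3
groups is degenerate) and χ² with df = G − 2.  That reference distribution
is exact for in-sample fitted logistic probabilities — the only way the
pipeline uses the test — and anti-conservative for externally supplied
probabilities, which is why the calibration null in the test suite fits a
correctly specified model per replicate.  Cox calibration splits cases into
linear-predictor tertiles and compares mean predicted survival (Breslow
baseline) with the group Kaplan–Meier estimate at 12 and 24 months,
flagging horizons beyond follow-up as extrapolation.

## Synthetic data

The generator exists so the pipeline can be exercised against known ground
truth; it emulates the *structure* of a 138-patient HCC radiotherapy
cohort, not its images.

*Lesion phantoms*: digitized ellipsoids (default semi-axes 14/12/16 mm on a
0.8 × 0.8 × 3 mm grid), optionally radially perturbed by a random low-order
spherical-harmonic field (lobulation amplitude ∈ [0, 1) lowers sphericity
and compacity); interior intensities are a stationary correlated Gaussian
field (smoothed white noise; the correlation length in voxels raises GLCM
homogeneity and lowers contrast) with an optional skewed exponential
component.  Deterministic given the seed.

*Cohorts*: clinical covariates are drawn to match the emulated marginals
(54% portal-vein thrombosis, 70% Child–Pugh A, 72% BCLC C, age ≈ N(64, 11)
clipped to 30–87, heavy-tailed AFP, dose 54/60/66 Gy at 12/83/6%, …).  The
feature panel comes either from per-patient phantoms through the extractor,
or (default, for speed) from a Gaussian surrogate: latent standard normals
with within-family correlation 0.6 and cross-family 0.1, mapped to
plausible per-feature scales, with the two planted drivers decorrelated
from the rest so selection sees a clean signal.  Binary response follows a
logistic model (intercept 0.6 ≈ 65% response; planted log-OR +1.2 on
histogram energy) and is observed only in a random subset (default
106/138).  Survival is exponential with planted log-HRs (−1.5 on compacity,
+0.3 on BCLC stage) on standardized covariates; the baseline rate is
calibrated by quadrature + bisection so the *marginal* median event time is
10.1 months.  Censoring is administrative, uniform on [1, 28] months
(uniform accrual with a fixed analysis date).  Across 50 seeds the mean KM
median OS comes out ≈ 11 months — slightly above the marginal-median target
because frailty heterogeneity plus censoring shift the KM estimate — inside
the intended 8–12-month band.  All generating parameters and the seed are
written to a ground-truth sidecar from which the cohort can be regenerated
bit for bit.

What passing tests show: the pipeline recovers planted effects of realistic
size at the study's sample size, its tests are calibrated under their
nulls, and every deterministic contract holds.  What they do not show:
robustness to segmentation variability, scanner and reconstruction effects,
non-Gaussian feature distributions, non-proportional hazards, or
informative censoring — none of which the surrogate generates.

## Problem sizes and determinism

Test and acceptance workloads use deliberately modest sizes chosen as the
smallest that make the statistical assertions stable: oracle checks on
≤ 6×6×3 ROIs, threshold-scan equivalence at n ≤ 60, 500/200 replicates for
test calibration, n = 1000 for hazard-ratio recovery, 10–20 seeds for
selection frequencies, and the n = 138 cohort for end-to-end runs.  All
randomness flows through explicit integer seeds; pipeline artifacts are
written with canonical JSON/CSV formatting so config-identical reruns are
byte-identical.

## Known limitations

- Texture offsets ignore voxel anisotropy (see above).
- The LifeX-style discretization actually used upstream of published tables
  is not recoverable; bin count and bounds are configurable but defaults
  are our own.
- Hazard ratios are reported per covariate unit, not per SD; for
  small-scale features (e.g. compacity ≈ 0.05 ± 0.01) the per-unit HR is
  far from 1 and should be read accordingly.
- The selected-minimum p-values of the mobile-threshold scan are biased low
  by construction; use the permutation-adjusted extension for honest
  univariate inference.
- The two response models of a typical run can overlap in membership when
  the correlation graph admits many maximal independent sets; groups are
  deduplicated but not forced disjoint.
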