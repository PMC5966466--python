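# Methods

## The analysis problem

When many subjects experience one identical, extended naturalistic stimulus
(here: listening to an ambiguous social narrative), regions that process the
stimulus in a stereotyped way show correlated time courses *across*
subjects. Inter-subject correlation (ISC) quantifies this as the Pearson
correlation of two subjects' time courses at each unit (voxel or ROI),
giving n(n−1)/2 pair values per unit. The scientific question this package
operationalizes is whether a personality trait measured on a 16–80
instrument scale modulates that synchrony: do pairs of high-trait subjects
synchronize more than pairs of low-trait subjects ("all alike"), while
low-trait subjects remain idiosyncratic — the Anna Karenina pattern?

## Crossed random-effects model on pair data

Pair values are not independent: every subject appears in n−1 pairs. The
inference model treats each Fisher-z pair correlation as

    z_ij = x_ij' b + ξ_i + ξ_j + ε_ij,   ξ_k ~ N(0, τ²),  ε_ij ~ N(0, σ²),

with *crossed* random effects: both members of a pair contribute their own
subject effect. The one-group model has x_ij' b = b0 (population ISC); the
two-group model codes pair type (both-low, both-high, mixed) as cell means,
so the fixed effects are directly the population ISC levels G11, G22, G12
and the scientific contrasts are G11−G22, G11−G12, G22−G12.

Estimation is REML. Writing V0 = I + λ Z Z' with λ = τ²/σ² and Z the
pair-incidence matrix, the restricted likelihood is profiled over b and σ²,
leaving a one-dimensional criterion in log λ:

    (N−p)·log σ̂²(λ) + log|V0(λ)| + log|X' V0(λ)⁻¹ X|.

Z Z' depends only on n, so it is eigendecomposed once per sample size and
every λ evaluation is a cheap diagonal reweighting. The scalar search is a
41-point log-grid on λ ∈ [e⁻²⁰, e⁸] followed by bounded refinement to
1e−12 in log λ, with the τ² = 0 boundary checked explicitly. Tests compare
this route against an independent dense two-parameter Nelder–Mead REML
optimizer; agreement is ~1e−9 in all parameters.

Wald tests use t with denominator df = n_subjects − p (p = number of fixed
effects). No df formula is exact for this design; this choice is
simulation-calibrated — the G11 vs G22 contrast rejects a true null at
0.043–0.047 at nominal α = 0.05 (n = 20, 1000 simulations) — and the
acceptance checks rely on that calibration, not on the formula.

A vectorized variant fits many units at once on a shared λ grid (argmin per
unit, no refinement). It is deliberately the single code path used for both
observed and permuted statistics in cluster calibration, so label
exchangeability holds exactly; its estimates agree with the scalar fitter
to ~5e−3, which is ample for cluster-forming p-maps.

## Multiplicity control

One-group maps are thresholded by Benjamini–Hochberg FDR (default
q = 0.001). Group-contrast maps use cluster-extent correction: voxels with
p below an initial threshold (default 0.002) are grouped by face adjacency
(6-connectivity; 18/26 available) and clusters at or above the extent
threshold survive. The extent is either the conventional 50 voxels or
calibrated from a group-label permutation null: labels are shuffled over
subjects, pair types recomputed, the same map fit re-run, and the extent
set to the smallest k with P_null(max cluster ≥ k) ≤ α. On 200 spatially
independent null lattices (5×5×5, n = 16, 100 permutations) the measured
family-wise error is at or below the nominal 0.05.

## Median split, median ISC, and rank post-hocs

Groups come from a median split of the trait score; subjects at the
threshold go to the low group (matching the ≤median / >median convention),
configurable. Dichotomization is needed because covariates must live at the
pair level. The continuous post-hoc summarizes each subject as the median
of their n−1 pair correlations and rank-correlates it with the trait
*rank*; ranks blunt the leverage of the few extreme scorers a right-skewed
trait produces. Spearman p-values use exact permutation enumeration for
n ≤ 9 and the t approximation above that.

## Synthetic-data generator

The generator is the package's ground-truth instrument; it emulates the
structure of the target data, not its biophysics.

* **Trait scores**: 16 + round(Exponential(scale = `skew`)), clipped to 80.
  Default `skew` = 4.6 reproduces a healthy-sample mean ≈ 20.6 and a
  right-skewed shape with occasional extreme scorers. Covariates (age, sex,
  motion, censored-frame counts) are drawn independently of the trait, so
  the confound screen has a true null.
* **Time series**: per unit, two independent unit-variance shared processes
  c (stimulus-driven, weight `shared_amp` for everyone) and d
  (interpretation-driven, weight w_i = coupling_fn(trait_i) ∈ [0,1]), plus
  i.i.d. subject noise. The analytic pair correlation is
  ρ_ij = (a² + w_i w_j) / √((a² + w_i² + s²)(a² + w_j² + s²)) and is
  returned as ground truth.
* **Coupling default**: the trait's population CDF,
  w = 1 − exp(−(score−16)/4.6). A linear-in-score map leaves the skewed
  bulk of the sample with near-zero coupling, and under the additive model
  a subject's median ISC is only monotone in w_i while w_i < w_med·(1 +
  s²/a²); the quantile map spreads couplings uniformly over [0,1]
  (w_med ≈ ½), which keeps the whole sample inside the monotone regime and
  produces the rank-linear synchrony gradient the analysis is designed to
  detect. `linear_coupling` remains available.
* **Autocorrelation**: all three components are convolved with the same
  moving-average kernel (default window 5 TRs) normalized to unit ℓ2 norm.
  Identical-kernel smoothing leaves every lag-0 cross-subject correlation
  at its white-noise analytic value — the ground truth stays exact — while
  reducing the effective temporal degrees of freedom, which is the property
  that matters for exercising the estimators. Set `smooth_window=1` for
  analytic checks.
* **Censoring**: i.i.d. Bernoulli per TR (default 2%), censored frames set
  to exactly zero and *included* in correlations, preserving temporal
  alignment. The analytic ground truth ignores censoring; at the default
  rate the attenuation is negligible, at high rates it is visible.
* **Annotations**: per-sentence latent truth at `base_rate`; each rater
  reports it with probability `agreement`, else flips. Sentences are
  contiguous in TR space, so offsets strictly increase.
* **Features**: column offsets + outer(z-scored trait, loading vector) +
  Gaussian noise — a planted rank-one trait component in a matrix whose
  columns live on different scales.

What the generator does **not** emulate: scanner drift, physiological
noise, spatial autocorrelation, hemodynamic variability across regions, or
any linguistic content. Passing tests therefore demonstrate that the
estimators and decision procedures recover known structure under the
model's assumptions — not that they would behave identically on real
acquisitions.

## Event-locked encoding model

Sentences labeled positive by at least 3 of 5 raters form the consensus
event set; the complement is the inverse (control) regressor. Events are
unit impulses at the sentence's last-word offset TR (integration at
sentence boundaries), or unit boxcars over the sentence in block mode;
both are convolved with a canonical double-gamma HRF (peak 5 s, undershoot
~15 s, ratio 6, 32 s support, unit peak; all parameters exposed). Offset
timestamps arriving in seconds round up (ceil) to the containing TR. ROI
series are unweighted voxel means (spheres of configurable radius on an
arbitrary affine grid, or explicit voxel lists); each subject's series is
regressed on [intercept, regressor] by OLS. The two regressors are fit in
*separate* models because jointly they are near-complementary; a joint fit
is a configuration away. Group comparisons are equal-variance two-sample
t-tests (df = n1+n2−2) with BH adjustment across the ROI family per
regressor, plus uncorrected one-sample t-tests of pooled betas for
designated control ROIs.

The pattern study plants three response profiles — gain rising linearly
with trait rank (0 → 2), uniform gain 1, and gain 0 — with subject-level
gain jitter (s.d. 0.25) and series noise (s.d. 2, giving a per-subject beta
standard error near 0.3). At these planted effect sizes each of the six
Fig.-style decisions (two group differences, pooled-only response, three
null retentions) is reported as its own accuracy across replicates; each
must hold in ≥90% of runs. The null-retention decisions are reported
separately rather than conjoined because a conjunction of two independent
5%-level retentions has expected accuracy (1−α)² ≈ 0.90 by construction,
irrespective of effect size.

## PLS regression of behavioral features

Features are z-scored columnwise (sample s.d.; constant columns dropped
with a warning). The PLSR is SIMPLS with y centered but not scaled; scores
are orthonormal, so the percent of centered-y sum of squares per component
is q_a² / y'y and shares add. For a univariate response SIMPLS and NIPALS
coincide; tests verify coefficient agreement with an independent NIPALS
implementation to 1e−8. `component_loadings` reports the X-loading vector
normalized to unit length (a direction), sorted descending, with the
maximum-magnitude entry forced positive — PLS components are
sign-indeterminate and raw loading norms scale with √(n−1), so the
direction is the comparable object. Questionnaire-style matrices reuse the
same fit; Likert items are treated as numeric after standardization and
forced-choice items should be one-hot encoded before standardization.

## Confound screen

Continuous covariates: equal-variance two-sample t (reported low − high)
and Spearman correlation against the raw trait score. Binary covariates:
Pearson chi-squared on the 2×2 table, df = 1, no continuity correction.
P-values are reported raw. Covariates with one observed level are skipped
with a warning.

## Numerical and degenerate-input choices

* Pair correlations of a constant series are NaN with a warning and are
  excluded downstream; |r| = 1 is clipped to 1 − 1e−7 before atanh (or
  raises, naming the pair, when clipping is disabled).
* Saturated pair data (zero residual for every λ) short-circuits the REML
  search: exact cell means, σ̂² = τ̂² = 0, zero standard errors.
* Contrasts with zero standard error report t = ±∞, p = 0 (or t = 0, p = 1
  for a zero estimate).
* Degenerate pipeline runs (a group smaller than 2, or n < 5 for rank
  post-hocs) skip the affected stage with a warning instead of aborting.
* All generators and studies are deterministic given their seed; pipeline
  runs with identical config and seed are byte-identical.

## Study sizes

The validation studies use: 1000 simulations for type-I error (n = 20),
200 for contrast bias (n = 22), 100 replicates for the rank post-hoc, 200
for the encoding-model pattern, 200 for PLSR recovery, and 200 null
lattices × 100 permutations for cluster FWE. The default pipeline run uses
12 units × 1310 TRs; the synthetic lattice for cluster calibration is
5×5×5 with n = 16 subjects. These sizes give Monte Carlo standard errors
comfortably inside every decision band while keeping a full validation
pass to a few minutes on one core.

## Known limitations

* The Wald df convention is a calibrated choice, not a derivation; p-values
  from other df conventions will differ slightly at small n.
* Cluster calibration assumes exchangeability of group labels under the
  null; covariate-dependent nulls are out of scope.
* The vectorized map fitter's grid argmin introduces ~5e−3 estimate error;
  use the scalar fitter for per-unit reporting.
* Ground-truth correlations neglect censoring-induced attenuation.
* No spatial smoothness is simulated, so calibrated extents on synthetic
  lattices are smaller than on real, smooth maps.
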