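# narrsync

Trait-stratified inter-subject correlation (ISC) analysis for naturalistic
neuroimaging experiments, with a fully synthetic test bed.

When a sample of subjects experiences the *same* extended naturalistic
stimulus (a story, a movie), brain regions that process it stereotypically
show correlated time courses across subjects. `narrsync` asks whether a
personality trait modulates that synchrony — do pairs of high-trait
individuals synchronize with each other while low-trait individuals remain
idiosyncratic? — and whether the same trait leaves a signature in
event-locked responses and in free-recall behavior. It is written for
researchers analyzing multi-subject stimulus-locked time series who need
pairwise-correlation inference done correctly, plus reviewers who want
every stage of such a pipeline exercisable against known ground truth
without any data download.

## What it computes

**Pairwise ISC.** For each unit v (voxel or ROI) and each of the
n(n−1)/2 subject pairs (i, j), the Pearson correlation r_ij^v of the two
full time courses (censored frames zeroed, not removed). Fisher
z = atanh(r) stabilizes variance for modeling.

**Crossed random-effects inference.** Pair values are non-independent:
subject k appears in n−1 pairs. The model

  z_ij = x_ij′b + ξ_i + ξ_j + ε_ij,  ξ_k ~ N(0, τ²),  ε_ij ~ N(0, σ²)

gives each pair *both* members' random effects. The one-group version
estimates the population ISC b0; the two-group version (after a median
split of the trait) estimates the population ISC among low-low pairs
(G11), high-high pairs (G22), and mixed pairs (G12), with Wald tests of
the contrasts G11−G22, G11−G12, G22−G12. Estimation is REML, profiled to
one dimension via an eigendecomposition of the pair-incidence structure.
Multiplicity control: Benjamini–Hochberg FDR voxelwise, and cluster-extent
correction (fixed extent or calibrated from a group-label permutation
null).

**Rank post-hocs.** Each subject's median ISC (row median of the pair
matrix) against their trait rank, by Spearman correlation (exact
permutation p for n ≤ 9).

**Event encoding model.** Consensus events (sentences labeled by ≥3 of 5
raters) become impulse- or block-regressors convolved with a canonical
double-gamma HRF; per-subject OLS betas from ROI-mean time courses are
compared across trait groups (equal-variance t, FDR across the ROI family)
and rank-correlated with the trait.

**Behavioral PLSR.** A subjects × features matrix (z-scored columnwise) is
regressed on the trait score by SIMPLS partial least squares; reported are
per-component percent of trait variance explained and the sorted, sign-
fixed component loadings, plus a covariate confound screen (t, chi-squared,
Spearman).

**Synthetic data.** Every input above can be generated with planted ground
truth: a right-skewed 16–80 trait cohort, time series whose cross-subject
coupling rises with trait quantile (the "Anna Karenina" structure), frame
censoring, noisy rater annotations, and feature matrices with a planted
rank-one trait component. See `docs/methods.md` for the generative model.

## Worked example

The numbered drivers under `analysis/` run the full study on synthetic
data (each reads the run directory the previous one wrote):

```
python analysis/01_simulate.py --seed 0
python analysis/02_isc.py
python analysis/03_group_inference.py
python analysis/04_event_model.py
python analysis/05_behavior_pls.py
python analysis/06_validation.py
```

With seed 0 the inference stage prints:

```
median split at 19.0: low n=12, high n=10
one-group population ISC (z scale): mean b0=0.638; 12/12 units significant at q<0.001
group means (z): G11(low)=0.534, G22(high)=0.994, G12(mixed)=0.563
G11 vs G22 contrast p<0.05 in 12/12 units
median-ISC vs trait-rank Spearman rho: mean=0.93 across units (min p=4.3e-13)
```

Read: the whole sample is strongly synchronized (b0 is the population ISC
on the z scale), but high-trait pairs are far more synchronized than
low-trait pairs (G22 > G11 ≈ G12, exactly the planted structure), and each
subject's median synchrony rises monotonically with trait rank. The event
stage then shows the planted encoding pattern — group differences in the
two trait-scaled ROIs, a pooled-only response in the uniform ROI, nothing
in the non-responder:

```
  tmp_pole_like: t(20)=+5.48, q=0.000 [SIG]
      mpfc_like: t(20)=+5.66, q=0.000 [SIG]
       tpj_like: t(20)=-0.37, q=0.712 [n.s.]
    heschl_like: t(20)=-2.12, q=0.062 [n.s.]
pooled     tpj_like: t(21)=+15.17, p=8.7e-13 [SIG]
pooled  heschl_like: t(21)=-0.41, p=0.68 [n.s.]
```

and the behavior stage reports the planted speech-feature component
(`PLSR: component 1 explains 96.4% of trait variance`).

The same machinery is scriptable (`narrsync run-all --seed 0 --outdir
results/run`) and usable as a library:

```python
from narrsync import synthetic as syn, isc, inference as inf

traits = syn.gen_trait_scores(22, seed=0)
dataset, truth = syn.gen_timeseries(traits, syn.SynthDesign(n_subjects=22))
z = isc.fisher_z(isc.pairwise_isc(dataset))
groups = inf.median_split(traits)
fit = inf.fit_two_group_lme(z[0], groups["group"].to_numpy())
print(fit.contrasts)
```

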