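# Methods

## Polygenic model and likelihood

A trait `y` measured on `n` members of a twin/sibling cohort is modelled as
multivariate normal with mean `Xβ` (fixed effects) and covariance

    Ω = σp² · (h² K + (1 − h²) I),

where `K` is the expected additive-genetic relatedness on the 2Φ scale:
1 between MZ co-twins, 0.5 between DZ co-twins and labelled full siblings,
0 otherwise (including unlabelled members of the same household — shared
environment is deliberately not modelled; the residual therefore absorbs it
together with measurement error). Relatedness is a pedigree expectation, not
a genotype estimate: that choice makes heritability analytically verifiable
against closed forms (MZ correlation → h², DZ correlation → h²/2) and lets
the whole pipeline run on synthetic data.

Because `K` is block diagonal by family, the likelihood factorizes over
families. Each family block is eigendecomposed once (`K_b = U Λ Uᵀ`);
rotating the data into the eigenbasis diagonalizes `Ω` for *every* `h²`
simultaneously, so a likelihood evaluation is O(n) after the one-time
transform. This blockwise path is checked against dense multivariate-normal
evaluation to 1e-8 in the tests.

### Univariate fitting

At fixed `h²`, `β` (GLS) and `σp²` (ML) have closed forms, leaving a
one-dimensional profile likelihood over `h² ∈ [0, 1 − 1e−6]` (the cap keeps
MZ blocks nonsingular at the upper boundary). A 21-point coarse grid guards
against local optima; bounded scalar minimization (tolerance 1e−8) refines
the best bracket, and both boundaries are checked explicitly. The standard
error comes from the curvature of the profile log-likelihood (central
differences, step 1e−3) and is reported as NaN within 0.01 of a boundary,
where curvature is meaningless. The null `h² = 0` is tested with the
boundary LRT: p = ½·P(χ²₁ ≥ T), with p = 0.5 at T = 0. The estimator is
validated against an exhaustive grid search (step 0.001, dense linear
algebra) and its type-I error is calibrated by simulation to [0.03, 0.07]
at nominal 0.05.

### Bivariate fitting

Two traits jointly follow a model with 2×2 genetic and environmental
covariance components, `cov = G ⊗ K-structure + E ⊗ I-structure`. In the
family eigenbasis the likelihood factorizes over eigencomponents `j` with
2×2 covariance `λⱼ G + E`, so evaluation stays O(n). `G` is parameterized
by a free lower-triangular factor (it may degenerate to zero genetic
variance); `E`'s diagonal factor entries go through `exp` so `E` stays
positive definite — needed because MZ blocks contribute eigencomponents
with `λ = 0` whose covariance is `E` alone. Fixed effects for both traits
are profiled out exactly by GLS inside every evaluation. Optimization is
quasi-Newton (L-BFGS-B) from a smart start (univariate fits + residual
correlation) plus four seeded random restarts. `ρg` and `ρe` are read off
`G` and `E`; each is tested by refitting with its off-diagonal pinned to
zero and referring 2Δll to χ²₁ (interior parameter, no boundary mixture).
SEs use the delta method on the numerical Hessian and are NaN near
boundaries. The model-implied phenotypic correlation

    ρp = ρg √(h₁²h₂²) + ρe √((1−h₁²)(1−h₂²))

is computed from the fitted components, so the identity holds to machine
precision by construction. Reported `ρe` includes measurement error; the
output metadata says so.

## Preprocessing

- Inverse normal transform: ranks (average for ties) mapped through normal
  quantiles of Blom plotting positions `(r − 3/8)/(n + 1/4)`. Blom is the
  common default in variance-components software; the offset choice only
  shifts quantiles by O(1/n) and none of the downstream conclusions depend
  on it. Applied to parcel thickness by default; behavioral traits are
  transformed only on request (their simulated distributions are already
  Gaussian).
- Parcel summaries use a 10% trimmed mean per tail (floor(0.1·n) values
  dropped from each side).
- The covariate design is `[1, age, sex, age·sex, age², age²·sex]` plus
  optional extras (global thickness for whole-brain analyses; BMI/IQ/
  depression for sensitivity runs). Age is not pre-centered: residuals
  depend only on the span of the polynomial design, which is asserted
  numerically rather than enforced by centering.
- Missingness: listwise deletion per analysis (trait + covariates +
  pedigree intersection), so each result reports its own n.

## Association mapping

"Partial Spearman" is residualize-then-rank: both variables are
residualized on the covariate design, then ranked and Pearson-correlated.
p-values use the t approximation `t = r√((n−2)/(1−r²))`; simulation shows
type-I error 0.051 at nominal 0.05 (n = 150, five covariates). CIs are
percentile bootstrap over individuals (default 1000 resamples, seeded),
resampling the residualized pairs. FDR uses Benjamini–Hochberg step-up, one
family per analysis (e.g. the 200 parcels of one map), never pooled across
analyses. Subgroup analyses are row filters applied before mapping.

## PLS correlation

Brain and behavior matrices are residualized column-wise on the design and
z-scored; the cross-covariance `R = YᵀX/(n−1)` is decomposed by SVD. The
number of components equals the number of behavior traits (5 in the default
trait set). Explained covariance is `sᵢ²/Σsⱼ²` by definition, from singular
values only. Component signs are fixed deterministically: the
largest-magnitude behavior-salience entry is made positive and the paired
brain salience flips with it.

Permutation p-values shuffle individual labels of Y jointly and compare the
i-th permuted singular value to the i-th observed, with the add-one
estimator `p = (1 + #exceed)/(n_perm + 1)`; no Procrustes realignment in
the permutation step. Bootstrap resamples individuals with replacement,
realigns each resample's saliences to the original by orthogonal Procrustes
(rotation computed on the behavior saliences, applied to both sides), and
reports bootstrap ratios = original weight / bootstrap SE; |BSR| > 2 marks
stable parcels. A minimum of 50 bootstrap resamples is enforced — below
that the SE itself is too noisy to be a denominator. Resampling treats
individuals as exchangeable by default (appropriate for samples of
unrelated individuals); a family-block mode permutes/resamples whole
families for twin cohorts. Network summaries report per-network mean BSR
and supra-threshold fractions normalized by network size and renormalized
to sum to one across networks. Out-of-sample projection applies the trained
saliences to a new sample prepared with its *own* design, and reports
Spearman correlations of the paired composite scores.

## Synthetic cohorts

The generator is the exact generative inverse of the polygenic model:
per family block, genetic deviations are drawn with covariance
`K_block ⊗ G_traits` via the Kronecker product of the block's relatedness
factor and the trait-level genetic covariance factor (eigenfactorization,
so singular MZ blocks are handled exactly); environmental deviations are
family-independent with the trait-level `ρe` structure. Defaults mirror an
HCP-scale cohort: 143 MZ pairs, 85 DZ pairs, 650 singletons (n = 1106),
ages uniform on 22–37, sex Bernoulli(½), five traits named and scaled after
the analyzed phenotype set (sleep duration h² = 0.24, global sleep quality
h² = 0.12, BMI h² = 0.68, IQ h² = 0.66, depression h² = 0.24). No shared-
environment component is generated, matching the genes+environment model
the estimators fit. Parcel matrices are iid Gaussian noise plus planted
rank-one components: a unit-variance score (a standardized behavioral mix,
optionally blended 50:50 with a heritable latent of chosen h²) times a
brain loading, scaled by a strength parameter.

What the simulator does *not* emulate: spatial autocorrelation between
parcels, age curves of cortical thickness, non-Gaussian trait
distributions, assortative mating, and shared household effects. Passing
tests therefore demonstrate estimator correctness under the stated model,
not robustness to those real-data features.

## Problem sizes and numerical choices

Recovery experiments use 50 replicate cohorts at the default n = 1106
pedigree; oracle-equivalence checks use 100 random cohorts of n ≤ 30;
LRT calibration uses 1000 replicates of 100 MZ + 100 DZ pairs; PLS planted
recovery uses n = 500 with 200 parcels, 1000 permutations, 200 bootstraps.
These sizes give Monte Carlo error comfortably below the tolerances they
are tested against. Convergence tolerances: profile-likelihood bracket
1e−8; L-BFGS ftol 1e−12/gtol 1e−8; PSD checks at −1e−10. Degenerate
inputs (constant traits, all-singleton pedigrees, rank-deficient designs,
h² = 1 with MZ pairs) raise informative errors rather than returning
garbage.

## Known limitations

- Expected (pedigree) relatedness, not empirical genotype kinship; no
  half-sibs, parent links, dominance, or X-linkage.
- The bivariate optimizer can in principle find local optima; the smart
  start plus restarts made this unobserved in testing, but pathological
  likelihood surfaces (tiny n, near-singular components) may still need
  more restarts.
- Environmental correlations absorb correlated measurement error.
- Bootstrap CIs are percentile, not BCa; skipped-correlation estimators
  are out of scope.
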