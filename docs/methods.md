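# Methods

## Model family

Every model treats the line-level phenotype (a BLUE per line, each line
observed in exactly one environment/year) as

y = 1μ + Σ_k u_k + e,  u_k ~ N(0, K_k σ²_k),  e ~ N(0, I σ²),

where each K_k is an observation-level covariance kernel. Main-effect
kernels: environment membership Z_E Z_E′ (iid year effects), pedigree
Z_g A Z_g′, genomic Z_g G Z_g′. Interaction kernels are Hadamard (element-
by-element) products of the expanded main-effect kernels; by the Schur
product theorem they remain PSD. Because every line is observed once, Z_g is
a permutation-like incidence and the expanded A/G kernels are reorderings of
the entity matrices; the G×A kernel can equivalently be built entity-level
as G∘A and expanded (both constructions are supported and tested for
equality). Any interaction kernel containing the environment factor is
block-diagonal once observations are sorted by environment; the canonical
observation order (sort by environment, then line id) makes this literal.

The eight registered models are M1 {E,A}, M2 {E,A,AE}, M3 {E,G}, M4
{E,G,GE}, M5 {E,G,A}, M6 {E,G,A,GE,AE}, M7 {E,G,A,GA}, M8 {E,G,A,GA,GAE},
each with an implicit flat-prior intercept and iid residual.

## Kernels

**A** is built by the tabular recursion a(i,i) = 1 + 0.5·a(s,d),
a(i,j) = 0.5·(a(j,s)+a(j,d)), parents before offspring, unknown-parent terms
zero. Inbreeding is accumulated (diagonal 1+F), since selfed or line-bred
records are common in breeding pedigrees; no pedigree truncation is applied
— depth is a property of the input file. Metadata note: whether a given
analysis's A should include inbreeding is a data question; this
implementation always computes the full Wright/Henderson matrix.

**G = XX′/p** from the column-standardized marker matrix. QC first: markers
with more than 30 % missing calls or observed-call MAF below 0.05 are
discarded (boundaries are kept: exactly 30 % / exactly 0.05 survive).
Missing codes are then mean-imputed per marker — the simplest choice that is
unbiased in the mean — before centering/scaling. G is never bent; a 1e−8
ridge may be added at factorization time only.

**Normalization.** At dataset assembly every observation kernel is scaled to
mean diagonal 1. The expected per-observation variance contributed by term k
is σ²_k·mean diag K_k, so this puts all variance components on one scale and
makes percent-of-variance tables comparable across terms; the same
normalization is used when generating synthetic data and when fitting, so
recovery comparisons are like-for-like. The raw builders (`build_A`,
`build_G`) are untouched.

## Inference

Gibbs sampling after an eigen-reparameterization: K = BB′ with
B = U Λ^(1/2) (eigenvalues below `eigen_tol`·max dropped), u_k = B_k δ_k,
δ_k ~ N(0, I σ²_k). Since B′B is diagonal, the δ_k full conditional
factorizes into univariate normals and one update costs two matrix–vector
products. Per iteration: (1) μ from its Gaussian full conditional (flat
prior); (2) each δ_k; (3) each σ²_k and σ² from scaled-inverse-chi-square
full conditionals; (4) missing phenotypes from N(η, σ²) (data
augmentation). Held-out observations in both validation schemes are simply
rows with missing y, so prediction is the same machinery; for an entirely
unobserved year, the year effect and every interaction involving it shrink
to the prior mean 0 and the prediction reduces to μ̂ plus the genetic main
effects carried by relatives.

**Priors** are weakly informative, BGLR-style: σ²_k scaled-inv-χ²(df = 5,
S_k = var(y)·R²/K·(df+2)) with R² = 0.5 split equally over the K random
terms, and the residual with the complementary share. **Defaults**: 12,000
iterations, 2,000 burn-in, thinning 5; all configurable. Chains are
bit-reproducible from the seed. Convergence is not auto-diagnosed; retained
samples are stored in `mcmc_meta` for trace/ESS inspection by the user.

Tests and the acceptance script use shorter chains (≈1,200–3,000 iterations)
and moderate problem sizes (n ≈ 250–1,600 lines, p ≈ 100–1,000 markers),
chosen as the package's working sizes for simulation studies; point
predictions stabilize long before variance components, which is why
validation runs use the shortest chains.

`blup_fixed_variances` provides the closed-form mixed-model solution
(V = Σ σ²_k K_k + σ² I, GLS intercept, kernel cross-covariance prediction)
as an independent oracle; `fit_ridge_markers` is an explicit ridge-on-
markers sampler (joint Cholesky update of the p marker effects) used to
verify the duality σ²_g = p·σ²_b and the equivalence of marker-space and
kernel-space prediction.

## Validation schemes and score

**CV1**: per replicate, a seeded random fivefold partition of the lines
(fold sizes differ by ≤1, remainder to the earliest folds); each fold's
phenotypes are masked in turn, the model refit, and the five test-fold
prediction vectors joined before computing the Pearson correlation within
each year. Default 20 replicates; replicate r uses seed `seed + r`. Kernel
eigen-factorizations are computed once and shared across all refits — only
the mask changes. **V00**: each year is held out once (no random partition
exists, single run). The summary score is the weighted mean Σ r_e·n_e/Σn.
Reported SDs are across replicates of the per-year correlation; the weighted
mean's SD is the SD of per-replicate weighted means (the alternative —
across folds — is not used; the choice is recorded in the output JSON).
Years with fewer than two scorable observations or zero variance are
skipped, with their weight removed.

**A caveat on null behavior.** When predictions carry (almost) no genetic
signal, the joined-folds CV1 score is not centered at zero: each test
observation is excluded from its own fold's training set, so the fold's
estimated year effect couples negatively with the test phenotypes, an
O(1/√n_year) artifact that dominates the prediction variance only at zero
signal. With realistic signal the artifact is negligible, but weak CV1
correlations near −0.1 to −0.3 on small null data are expected behavior of
the scheme, not a bug.

## Synthetic data generator

Emulates the statistical structure the analysis assumes: founders,
`generation_depth − 2` intermediate crossing generations, then full-sib
families with capped-geometric sizes (defaults: mean 5, cap 116, echoing the
1–116 range of real pipelines); unlinked biallelic markers gene-dropped
down the pedigree (founders Hardy–Weinberg at MAF ~ U(0.05, 0.5), one allele
per parent per locus — full sibs share identical pedigree relationships
while realized relatedness varies by Mendelian sampling); each line assigned
to exactly one year with ~15 % of families split across two years; phenotype
components drawn as u_k = B_k z from the same normalized kernels the models
fit, plus iid residual, with variance fractions specified by the user
(default preset shaped like a grain-yield full-model partition:
E .35/A .12/G .07/AE .20/GE .07/Res .19). Components sum to the phenotype
exactly and are returned as ground truth.

What it does **not** emulate: linkage/recombination maps (the models only
consume relationship matrices), selection across cycles, trait-specific
error structures, or field-trial design effects (the inputs are line-level
BLUEs by construction). Passing recovery tests therefore show that the
estimator inverts its own data-generating process at realistic sizes, not
that real wheat data satisfy the model.

## Numerical and design notes

- PSD tolerance: min eigenvalue ≥ −1e−8·max, everywhere; factorization drops
  eigenvalues < 1e−8·max.
- The environment term has only n_years effective replicates (4 by
  default), so its realized simulated variance — and its fitted share — is
  intrinsically noisy regardless of the number of lines; recovery checks
  for E rely on medians over seeds.
- Variance partitions among non-orthogonal kernels (A vs G vs G∘A) are
  weakly identified: even with phenotype = pedigree effect exactly, the
  profile likelihood over σ² is nearly flat because the within-family
  Mendelian part of A is identity-like. Fitted shares should be read as a
  descriptive partition, not as orthogonal decomposition.
- Fold remainder lines go to the earliest folds; replicate and fold seeds
  are derived deterministically from the master seed; all file outputs carry
  a JSON sidecar with the config hash and package version.
- Degenerate inputs error early: constant phenotypes, fewer than 2
  observations, non-finite values, cycles or undefined parents in
  pedigrees (undefined parents can optionally be auto-inserted as
  founders), zero-variance markers reaching standardization.

## Limitations

- REML/EM estimation, multi-trait models, and non-Gaussian likelihoods are
  out of scope (ordinal scores are treated as Gaussian).
- Kernels are stored dense; the intended scale is ≤ ~5,000 observations.
- No dominance or single-step (H-matrix) extensions; no environmental
  covariates — environments are exchangeable year labels.
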