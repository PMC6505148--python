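# Methods

## Model

The package fits the multi-trait multi-environment mixed model

    Y = X β + Z1 b1 + Z2 b2 + E,           Y ∈ R^{n×L}, n = records

with matrix-variate normal random effects: line-by-trait effects
`b1 ~ MN(0, G, Σt)`, line-by-environment-by-trait effects
`b2 ~ MN(0, ΣE ⊗ G, Σt)` and residuals `E ~ MN(0, Iₙ, Re)`.  `G` is the
genomic relationship matrix among the J lines; `Σt` (L×L), `ΣE` (I×I) and
`Re` (L×L) are unstructured covariance matrices.  Assumptions: Gaussian
traits, homogeneous residual covariance across environments, additive
genomic effects (GBLUP parameterization), and a separable (Kronecker)
covariance for the interaction term.

All fitting happens in a whitened parameterization.  `build_design` factors
`G = L·Lᵀ` and uses `Z1 = ZG·L`, `Z2 = ZEG·(I_I ⊗ L)`, after which the prior
row covariances of the whitened `b1` and `b2` are `I_J` and `ΣE ⊗ I_J`.
The BME model is the same object without the `Z2 b2` term and with a single
intercept column (or any fixed-effect design) in `X`.

## Gibbs sampler

One sweep updates, in order: `β` (flat prior, matrix-normal conditional
`MN((XᵀX)⁻¹XᵀE*, (XᵀX)⁻¹, Re)`), `b1`, `b2`, `Σt`, `ΣE`, `Re`, and the
masked response cells.

**Blocked effect updates.**  The joint conditional of an effect matrix has
vec-precision `Σ⁻¹ ⊗ Ω⁻¹ + Re⁻¹ ⊗ ZᵀZ` — a sum of two Kronecker products
that is not itself matrix-normal, so effects are sampled in row blocks of
`block_size` (default 50, accepted range [50, 1000)).  Within a block with
isotropic conditional prior `MN(m, (1/s)I_b, Σt)`, rotating rows into the
eigenbasis of `Z_bᵀZ_b` (precomputed once per fit) decouples them into b
independent L-variate normals with precision `s·Σt⁻¹ + d_j·Re⁻¹`.  For `b2`
blocks are constrained to lie within one environment, which keeps the
conditional prior isotropic: with `Ω⁻¹ = ΣE⁻¹ ⊗ I_J`, the block conditional
given the other environments' rows has precision `ΣE⁻¹[i,i]·I` and mean
`−(1/ΣE⁻¹[i,i]) Σ_{i'≠i} ΣE⁻¹[i,i'] b2[i', same lines]`.

**Covariance updates.**  Conjugate inverse-Wishart conditionals:

* `Σt | · ~ IW(ν_t + J + I·J, S_t + b1ᵀb1 + Σ_{i,i'} ΣE⁻¹[i,i'] B_iᵀB_{i'})`
  where `B_i` is the i-th environment's J×L slice of `b2`;
* `ΣE | · ~ IW(ν_E + J·L, S_E + M)`, `M[i,k] = tr(B_i Σt⁻¹ B_kᵀ)` — derived
  by viewing the I×(J·L) rearrangement of `b2` as matrix-normal with row
  covariance `ΣE` and column covariance `Σt ⊗ I_J`;
* `Re | · ~ IW(ν_e + n, S_e + EᵀE)` with `E = Y − Xβ − Z1b1 − Z2b2`.

Because the Gibbs details of this model family are scattered across the
primary literature, the full conditionals above were validated directly by
joint-distribution ("getting it right") tests: the marginal-conditional
simulator (draw parameters from the prior, then data) and the
successive-conditional simulator (alternate one Gibbs sweep with redrawing
the data from the likelihood) must produce the same distribution for every
parameter.  The test suite checks first and second moments of `Σt`, `ΣE`,
`Re` entries (and `σ²` for the univariate engine) at z < 4, and additionally
checks that with all covariances fixed the posterior means of `(β, b1, b2)`
match a dense GLS solve of the vectorized model.

**Identifiability.**  Only the Kronecker product `ΣE ⊗ Σt` (up to scale) is
identified in the `b2` prior; the overall scale split between `ΣE` and `Σt`
is not.  No constraint is imposed; correlations derived from either matrix
are identified and are what the recovery tests check.

**Priors.**  `ν_t = ν_e = L + 2`, `ν_E = I + 2`, identity scale matrices:
proper and weakly informative at toy sizes.  All prior df/scales are
injectable (`MatrixPriors`); the joint-distribution tests use heavier df
(dim + 10) because the defaults have infinite prior variance, which breaks
moment comparison but not the sampler itself.

**Masked cells and prediction.**  Testing sets (record indices, or
(record, trait) cells) are masked before fitting.  Each sweep the masked
cells are redrawn from their conditional normal given the observed traits of
the same record (data augmentation), and the per-sweep predictive surface —
linear predictor at observed cells, conditional predictive mean at masked
cells — is averaged over retained (post burn-in, thinned) sweeps into
`yHat`.  Masked values stored in the input are never read; predictions are
bitwise invariant to them.  `dfe` and `Se` expose the residual
inverse-Wishart update: `dfe = ν_e + n` and `Se` is the posterior mean of
the update scale `S_e + EᵀE`.

## Univariate engine (stage-1 GBLUP and stacking meta-models)

`fit_univariate` fits `y = μ + Σ_c X_c u_c + e` by Gibbs sampling with two
effect priors:

* **BRR** — `u_c ~ N(0, σ_c² I)`; `σ_c²` and `σ²` carry scaled-inverse-χ²
  priors with `df0 = 5` and scale set so the prior mode equals half the
  sample variance of the observed response, split equally across components.
  Effects are drawn jointly through a precomputed eigendecomposition of
  `X_cᵀX_c` (exact, O(q²) per sweep).
* **BayesB** — per-effect spike-and-slab: point mass at zero with
  probability π (prior `Beta(p0·π0, p0(1−π0))`, `π0 = 0.5`, `p0 = 10`) and a
  scaled-t slab (df 5, scale set so the expected variance contributed by
  included effects is the component's share of half the response variance).
  Single-site updates with the standard marginal-likelihood inclusion odds.

BayesA, BayesC and the Bayesian Lasso are recognized labels that raise a
clear "not implemented" error.  Missing responses are augmented each sweep,
which is also the testing-set prediction mechanism.  A single seeded
`numpy.random.Generator` drives every draw: identical seeds give
bitwise-identical chains.

## BMORS (two-stage stacking)

Per partition: (1) each trait is fit univariately with the caller's full
component list and the testing records masked; (2) the L prediction vectors
are standardized per trait (sample SD, n−1); (3) each trait is regressed on
all L standardized predictions (plus an intercept) with the `cov_model`
prior (BRR default, BayesB available), again with testing cells masked.

Stage-1 covariates at *training* cells are computed out-of-fold (an inner
5-fold split of the training records; testing cells use the full-training
fit).  In-sample training covariates leak the training residual into the
meta-model: the own-trait covariate's apparent strength is inflated and the
correlated traits' coefficients shrink or sign-flip, which measurably erases
the accuracy gain stacking should extract from genetically correlated
traits.  `stage1_folds=0` restores in-sample behavior.  The
whole-environment hold-out variant (`fit_bmors_env`) defaults to in-sample
covariates: under environment masking an inner fold removes a line's only
remaining records, making out-of-fold covariates relatives-only and sharply
mismatched with the testing environment's, which miscalibrates the
meta-model.  Stage 1 is refit within every partition, so no information
from a partition's testing cells ever reaches its stage-2 covariates.

## Cross-validation designs

* **Random CV** — per partition, `m = round(p_testing · N)` lines are drawn
  (half-up rounding; with replacement iff J < m) and one observed
  environment is picked per drawn line; the distinct cells form the testing
  set (duplicates within a partition collapse).
* **K-fold (CV2)** — each line's records are shuffled and dealt round-robin
  onto a shuffled fold order with a pointer shared across lines: folds are
  disjoint, exhaustive, sizes differ by at most one, and a line's records
  land in distinct folds whenever it has ≤ k records, so a line tested in
  some environments is trained in others.

Both are pure functions of (table, parameters, seed).

## Metrics

Pearson's product-moment correlation (NaN on zero variance, propagated, not
raised) and MAAPE = mean of `arctan|(y − ŷ)/y|`: an exact match contributes
0 even at y = 0; y = 0 with ŷ ≠ y contributes π/2.  Summaries report the
mean over partitions per (environment, trait) and the standard error
`SD/√m`; with one partition the SE is NaN.  Pearson values are averaged
directly (no Fisher-z transform).

## Synthetic data

The generator draws from the model above exactly, on a complete J×I layout,
and returns the realized (whitened) effect matrices for oracle comparisons.
Markers are Binomial(2, f) dosages; with `n_families` set, family allele
frequencies are Balding–Nichols draws (default divergence `fst = 0.25`)
around the base frequency, giving the within-family relatedness real
breeding panels have.  This matters for testability: with unrelated lines
and one record per line, genetic and residual covariances are essentially
non-identifiable (the uncentered cross-product GRM is nearly
compound-symmetric), and no sampler can recover them.  `grm_vanraden` is the
plain cross-product `W Wᵀ/p` with no centering; the generator and the
recovery tests use the caller-side centered, frequency-scaled GRM
(`grm_centered`, near-unit diagonal) so simulated genetic variances are on
the scale of `Σt`.

Presets `mada_like` (30 lines × 6 traits × 1 environment, wheat-style
schema) and `maize_like` (30 lines × 3 traits × 3 environments, maize-style
schema) use unit trait variances with exchangeable genetic correlation
0.3/0.5, environment correlation 0.6, residual correlation 0.1/0.2, six
families, and trait means chosen so the tables look like field data.  The
generator does not emulate real trait scales or distributions, linkage
disequilibrium, selection, or heterogeneous residual variance — passing
tests demonstrate sampler correctness and recovery under the stated model,
not robustness to model misspecification.

## Problem sizes and tolerances used by the test suite

Joint-distribution tests run at n ≤ 8 with 15–20k sweeps; oracle-equivalence
at J=4, I=2, L=2 with 20k sweeps (agreement within 0.06 absolute, a few
Monte-Carlo SEs); BMTME correlation recovery at J=100, I=3, L=3 with 4000
iterations over 10 seeds (≥ 8 within 0.25 absolute); BME recovery on a
replicated trial (3 replicates, J=40) because a single unreplicated
environment cannot separate `Σt` from `Re` at that size; stacking's
correlation-exploitation check at J=60, I=2 with 10 partitions and traits of
unequal heritability (0.2 vs 0.8), where the borrowing channel is strongest.
PSD-safe Cholesky clips eigenvalues below `1e-10·λmax` (deterministic, no
jitter) and returns non-negative-diagonal factors; marker QC drops markers
with > 20 % missing calls, imputes the rest by Binomial(2, f̂) draws, and
drops MAF < 0.05 with the frequency computed after imputation.

## Known limitations

Gaussian traits only; homogeneous `Re` across environments; no structured
(FA/AR1) environment covariances; BayesA/BayesC/BL not implemented; the
`ΣE`–`Σt` scale split is reported as-is (document, don't constrain); MCMC
convergence is not auto-diagnosed — chain lengths are the caller's
responsibility.
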