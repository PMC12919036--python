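# Methods

## Model and procedure

### Data model

A panel is a dense tensor `Y[j, v, m]` — subject *j*, feature *v* (e.g. a
cortical region), metric *m* (e.g. thickness, surface area) — with one
batch label per subject and a table of subject-level covariates. Feature
and metric identifiers are sorted lexicographically and all tensors follow
that order; missing cells are rejected rather than imputed, since the
model has no missingness mechanism.

### Fixed effects

Biological covariate effects are estimated per (feature, metric) slice and
preserved through harmonization. The default is ordinary least squares on
a shared design matrix (all `p*M` slices solved in one call). Covariates
flagged with an `_s` suffix in the formula are fitted as penalized cubic
B-splines (basis dimension 10, second-difference ridge penalty, penalty
weight chosen by generalized cross-validation over a log-spaced grid).
The batch label is never part of this design — it would absorb the effect
harmonization is supposed to remove.

### Standardization

Residuals are standardized per slice by the pooled (across-batch) mean and
the pooled sample SD (ddof = 1), mirroring original ComBat. This choice —
pooled rather than per-batch, sample rather than population SD — puts the
batch covariance `Sigma_iv` on a correlation-like scale that is comparable
across metrics; the transform is inverted after adjustment.

### MV-ComBat

On standardized residuals, for each batch *i* and feature *v*:

```
Z_ijv ~ N(gamma_iv, Sigma_iv),   gamma_iv ~ N(gamma_i, T_i),
Sigma_iv ~ Inv-Wishart(Psi_i, nu_i)
```

**Method-of-moments hyperparameters** (per batch): `gamma_i` and `T_i` are
the across-feature mean and covariance of the per-feature batch means.
The IW degrees of freedom solve the diagonal-moment identity
`Var_v(S_iv[mm]) = 2 (mean_v S_iv[mm])^2 / (nu - M - 3)` averaged over
metrics and floored at `M + 4` (the scalar M = 1 case reduces exactly to
inverse-gamma moment matching); `Psi_i = (nu_i - M - 1) * mean_v(S_iv)`,
so the prior mean equals the average empirical covariance.

**EB posteriors.** The two conditional posterior means

```
gamma* = (n Sigma*^-1 + T^-1)^-1 (n Sigma*^-1 zbar + T^-1 gamma_i)
Sigma* = (sum_j (Z_j - gamma*)(Z_j - gamma*)' + Psi) / (n + nu - M - 1)
```

are mutually dependent; they are iterated jointly from `(zbar, S + ridge)`
until the maximum elementwise change falls below 1e-6 (at most 100
iterations; non-convergence is flagged, and the fixed-point residual is
checked in the test suite at 1e-8). A ridge of 1e-8·I is added to any
sample covariance before inversion.

**Adjustment.** `Z* = Sigma*^{-1/2} (Z - gamma*)` with the *symmetric*
(spectral) inverse square root, eigenvalues floored at 1e-10. The
symmetric root makes whitening basis-independent and invariant to metric
reordering, unlike a Cholesky factor. The literal reading — whiten to the
identity on the standardized scale — is the default; `recolor="pooled"`
optionally re-colors by the pooled across-batch covariance square root for
users who prefer a pooled residual target. Fixed effects are restored
afterwards. Single-batch input is returned unchanged with a warning.

**MCMC estimator.** The fully Bayesian variant keeps the two-stage design
(fixed effects removed first) and replaces the IW prior with a separation
prior: `sigma_ivm ~ half-t(3, pooled SD)` on marginal scales and an
LKJ(2) prior on the correlation matrix, parameterized by unconstrained
C-vine partial correlations (tanh-transformed independent Betas, which
induce the LKJ density). Location effects are partially pooled across
features, `gamma_iv ~ N(mu_i, tau_i^2 I)`, with `(mu_i, tau_i)` plugged in
from the across-feature moments — the same quantities the EB route uses —
so per-feature posteriors stay independent and can be sampled separately.
Sampling uses an affine-invariant ensemble sampler with
differential-evolution moves (default 3000 draws after 1000 warmup,
2·dim+2 walkers); evenly spaced walkers serve as chains for rank-based
split-Rhat and ESS, and a run is flagged failed when any Rhat ≥ 1.01.
This sampler explores the same posterior an HMC implementation would; it
simply trades gradient information for ensemble moves, which is adequate
at the per-feature dimensionality (2M + M(M-1)/2).

### MV-CovBat

Stage 1 is MV-ComBat. Stage 2 targets cross-feature covariance: each
metric's de-standardized residual matrix is column-centered and decomposed
by SVD, keeping the smallest component count reaching 95% variance; scores
carry the singular-value scale (`F = U D`), so the shared-subspace
objective weights directions by explained variance. The shared matrix `G`
(orthonormal columns) maximizes `Tr(G' S G)`, `S = sum_m F^(m) F^(m)'` —
by Rayleigh–Ritz the top eigenvectors of S, with dimension chosen by the
same 95% cumulative-eigenvalue rule (override: integer `r_s`). Univariate
EB ComBat is applied to the columns of `G` (intercept-only: fixed effects
are already out; a covariate-protecting option exists), and
`F* = G* A + H`, `R* = F* L' + remainder` reconstructs. The discarded-PC
remainder is re-added so that skipping the score harmonization reproduces
Stage 1 exactly. PC and eigenvector signs are fixed by making each
vector's largest-magnitude loading positive.

### Univariate baselines

`uv_combat` is standard EB ComBat per (feature, metric) slice with priors
pooled across features *within each metric* (normal/inverse-gamma,
method-of-moments, the classic alternating update to 1e-6). `uv_covbat`
adds per-metric PC-score harmonization of the pooled Stage-1 residual
covariance. Score columns are standardized before and rescaled after
their ComBat pass so eigenvalue scale survives.

## Synthetic-data generator

The generator emulates a three-site, 70-feature, six-metric panel study.
Baseline (gold-standard) data are unit Gaussian noise plus linear
covariate effects: age ~ N(50, 10²) at 0.05/year, sex ~ Bernoulli(0.5) at
0.5, diagnosis ~ Bernoulli(0.3) affecting a random 60% biomarker subset —
weakly (0.2) on the first two metrics, strongly (0.6, or as configured) on
the rest.

Feature-wise batch effects: location shifts `gamma_iv ~ N(gamma_i, T_i)`
with per-metric offsets `gamma_i ~ N(0, 1.0²)` and `T_i = 0.4·I`;
covariances `Sigma_iv` drawn from an inverse-Wishart with mean `0.5·I` at
`nu = M + 3` (model-concordant) or from the weighted mixture
IW/LKJ/FA/AR/CS with weights (0.20, 0.30, 0.20, 0.20, 0.10)
(model-misspecified). Two heterogeneity fractions reflect that not every
region is equally scanner-sensitive: 73% of features carry covariance
batch effects at all, and 66% of those also differ in cross-metric
*correlation* (the rest differ in marginal scales only, which per-metric
harmonization can fix). The stress condition triples the location offsets
and doubles the covariance scale at n = 100. These magnitudes were chosen
once, as the package's study conditions, to land the evaluation battery on
the reference landscape (about 60% / 25% / 30% Box's M-significant
features unharmonized in the three conditions, ~37% after univariate
ComBat at n = 500, near-perfect unharmonized RF batch AUC at n = 500);
they are all overridable in `SimulationConfig`.

Latent-space batch effects: the gold noise is decomposed per metric, a
shared `G` is estimated exactly as in MV-CovBat, and each batch's rows of
`G` are transformed by `G R_i + mu_i + E_i` — `R_i` an orthogonal matrix
blending the identity with a random rotation (polar projection, blend 0.5),
`mu_i` and `E_i` scaled relative to the 1/sqrt(n) magnitude of orthonormal
score entries (scales 1.0 and 0.5) — then propagated back through the
`A^(m)` and loading matrices. The generators record the injected term
exactly (`observed - gold` is bit-identical to it), the drawn parameters,
and the biomarker set.

What the generator does *not* emulate: heavy-tailed or outlier-contaminated
residuals, site-by-covariate confounding (covariates are balanced across
batches by construction), hierarchical batch structure, and missingness.
Passing tests therefore demonstrate correctness of the estimators under
the stated Gaussian conditions, not robustness to those real-data
pathologies.

## Evaluation battery

Univariate tests (ANOVA, Kruskal–Wallis, Levene, Bartlett,
Fligner–Killeen) run on residuals per slice, Bonferroni-corrected over all
`p·M` slices per test family. MANOVA (Pillai's trace, standard F
approximation from the SSCP matrices) and Box's M (chi-square
approximation with the usual small-sample correction factor) run per
feature on the M-metric residual vectors, Bonferroni over features; both
are cross-checked in the test suite against independent implementations
(statsmodels, pingouin). Random-forest batch prediction uses stratified
10-fold CV, 100 trees, macro one-vs-rest AUC per metric with per-(metric,
fold) seeds. Correlation distances (Frobenius, elementwise MSE, mean
absolute difference of sorted eigenvalues, spectral norm) compare
per-batch correlation matrices pairwise or against the gold panel; the
cross-metric variant uses the pooled `(pM)×(pM)` correlation restricted to
between-metric blocks. Signal preservation fits the linear covariate
model to every slice at once, applies Benjamini–Hochberg at q = 0.05, and
with simulator truth reports true positives and empirical FDR
(`FP / max(1, discoveries)`). EB prior checks compare standardized
location discrepancies with N(gamma_i, T_i) and empirical covariance
distances with IW prior draws via a histogram overlap coefficient.

## Numerical choices and degenerate inputs

* Ridge 1e-8·I before any covariance inversion; eigenvalue floor 1e-10 in
  matrix square roots.
* Eigenvalue ties in the shared-subspace problem are broken by index
  order (warning logged).
* Multivariate covariance estimation requires `n_i >= M + 2` per batch;
  violations raise before any computation.
* Zero-variance slices: standardization raises (harmonization), the test
  battery emits NA p-values with a warning.
* Constant MCMC chains yield Rhat = 1 and are flagged as degenerate
  rather than failed.
* All randomness flows through explicit seeds; replicate seeds derive
  from a master seed via `numpy.random.SeedSequence` and stay below 2^31.

## Known limitations and observed behaviour

* **Overcorrection leakage in CV batch prediction.** The EB posteriors
  track per-batch sample moments closely at large n, so after whitening,
  residual batch means are almost exactly equalized on the *full* data.
  Cross-validated classifiers trained on such data see a slight
  *anti*-predictive signal (held-out subjects deviate from their batch's
  training mean in the opposite direction), which can push the batch AUC
  below 0.5 (≈ 0.37–0.40 at n = 500 in the regular condition) instead of
  slightly above it. This indicates less residual batch signal, not more;
  the unharmonized AUC (≈ 0.998) is unaffected.
* **Stress-condition univariate ComBat.** With Gaussian residuals, the
  per-slice monotone variance adjustment of univariate ComBat can only
  *reduce* cross-batch covariance differences, so the implemented stress
  condition shows UV-ComBat lowering the Box's M-significant fraction
  (~30% → ~13%) rather than raising it. An inflation would require a
  mechanism outside this generator's families — e.g. heavy-tailed
  contamination interacting with the EB scale shrinkage.
* The MCMC estimator is expensive at full panel size (it samples each
  (batch, feature) posterior separately) and is excluded from the default
  benchmark grid; enable it with `--with-mcmc` or `estimator="mcmc"`.
* Only one batch variable is modelled; hierarchical or crossed batch
  structures are out of scope, as are subject-level random effects
  (longitudinal designs) and reference-batch or nonparametric ComBat
  variants.
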