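# mvharmonize

Multivariate batch-effect harmonization for multi-metric panel data.

## The problem

Multi-site studies that derive several correlated *metrics* (e.g. cortical
thickness, surface area, curvature) for each of many *features* (regions of
interest) suffer batch effects: systematic, non-biological differences
between sites or scanners. Classical ComBat removes batch differences in
the mean and variance of each feature separately, but it cannot touch the
*covariance* between metrics — and cross-metric covariance is exactly what
multimodal analyses and machine-learning pipelines consume.

`mvharmonize` implements joint, multivariate harmonization:

* **MV-ComBat** — for each feature *v*, the M metric residuals of subject
  *j* in batch *i* are modelled jointly:

  ```
  Y_ijvm = alpha_vm + X_ij' beta_vm + Z_ijvm,
  Z_ijv ~ N(gamma_iv, Sigma_iv),
  gamma_iv ~ N(gamma_i, T_i),    Sigma_iv ~ Inv-Wishart(Psi_i, nu_i)
  ```

  Conjugate empirical-Bayes posterior means (method-of-moments
  hyperparameters, closed-form fixed-point iteration) — or a fully
  Bayesian ensemble-MCMC estimator with an LKJ prior on correlations and
  half-t priors on scales — give `(gamma*_iv, Sigma*_iv)`. Residuals are
  then whitened, `Z* = Sigma*^{-1/2} (Z - gamma*)`, and the covariate
  effects restored.

* **MV-CovBat** — a second stage for batch effects living in the
  cross-*feature* covariance: per-metric PCA `R^(m) = F^(m) L^(m)'`, a
  shared orthonormal score matrix `G` maximizing `Tr(G' S G)` with
  `S = sum_m F^(m) F^(m)'` (Rayleigh–Ritz: top eigenvectors of S),
  univariate ComBat on the columns of `G`, and reconstruction.

* Univariate **ComBat** and **CovBat** baselines, a synthetic-data module
  generating the study conditions (model-concordant, model-misspecified
  covariance mixtures, and latent-space batch effects), and an evaluation
  battery: ANOVA/Kruskal–Wallis/Levene/Bartlett/Fligner tests, MANOVA and
  Box's M, stratified-CV random-forest batch prediction (macro AUC), four
  correlation-matrix distances, BH-controlled signal preservation, and EB
  prior checks.

## Worked example

```python
from mvharmonize import SimulationConfig, mv_combat, simulate_dataset
from mvharmonize.evaluate import boxm_feature_fraction

FORMULA = "age + sex + diagnosis"
sim = simulate_dataset(SimulationConfig(n=150, p=20, M=4, seed=1))
harmonized, posteriors = mv_combat(sim.observed, formula=FORMULA)
print(boxm_feature_fraction(sim.observed, FORMULA),
      boxm_feature_fraction(harmonized, FORMULA))
```

Running `python examples/01_harmonize_panel.py` (the same computation from
a CSV round trip) prints:

```
panel: 150 subjects x 20 features x 4 metrics, batches ['site1', 'site2', 'site3']
features with significant cross-metric covariance batch effects (Box's M, Bonferroni): 30% before -> 0% after
example location effect gamma* for batch 'site1', feature 0: [ 0.943 -0.742 -0.811 -0.163]
```

30% of features had significantly different cross-metric covariance across
the three sites before harmonization; none after. The printed `gamma*` is
the estimated per-metric location shift of site 1 for the first feature on
the standardized residual scale. The other scripts in `examples/` walk
through the simulation landscape, latent-space MV-CovBat, and the MCMC
estimator; `mvharmonize --help` exposes the same capabilities as a CLI
(`simulate`, `harmonize`, `evaluate`, `benchmark`).

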