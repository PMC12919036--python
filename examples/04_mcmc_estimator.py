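"""Fully Bayesian batch-effect estimation with the ensemble MCMC sampler.

Fits the hierarchical model (LKJ prior on cross-metric correlations,
half-t priors on scales, partial pooling of location effects across
features) on a small panel and reports posterior means and convergence
diagnostics. The closed-form EB estimator is the fast default; the MCMC
route quantifies the same posteriors without the plug-in approximation.
"""

import numpy as np

from mvharmonize import MCMCConfig, SimulationConfig, mv_combat, simulate_dataset

sim = simulate_dataset(SimulationConfig(n=120, p=3, M=2, seed=3))

cfg = MCMCConfig(draws=6000, warmup=1500, seed=1)
panel_mcmc, post_mcmc = mv_combat(sim.observed, formula="age + sex + diagnosis",
                                  estimator="mcmc", mcmc_config=cfg)
panel_eb, post_eb = mv_combat(sim.observed, formula="age + sex + diagnosis",
                              estimator="eb")

b = sim.observed.batches[0]
print("feature 0 location effect gamma* (standardized residual scale):")
print("  MCMC:", np.round(post_mcmc.gamma_star[b][0], 3))
print("  EB:  ", np.round(post_eb.gamma_star[b][0], 3))
diag = post_mcmc.diagnostics[b]
print(f"convergence: max Rhat = {diag['rhat_max'].max():.3f} "
      f"(criterion < 1.01 -> passed={diag['passed']}), "
      f"min ESS = {diag['ess_min'].min():.0f}")
# Agreement between the two estimators on mild batch effects is expected;
# the MCMC variant matters most when the IW prior's tying of variances and
# correlations misfits the data.
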