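"""Reproduce the covariance batch-effect landscape on simulated data.

Simulates the model-concordant regular condition at two sample sizes,
harmonizes with univariate and multivariate ComBat, and tabulates the
fraction of features showing Box's M-significant covariance differences
across batches.
"""

import numpy as np

from mvharmonize import SimulationConfig, mv_combat, simulate_dataset, uv_combat
from mvharmonize.evaluate import boxm_feature_fraction

FORMULA = "age + sex + diagnosis"
R = 3  # replicates per cell; increase for tighter estimates

print(f"{'condition':<16}{'unharmonized':>14}{'UV-ComBat':>12}{'MV-ComBat':>12}")
for n in (500, 150):
    cells = {"unharm": [], "uv": [], "mv": []}
    for r in range(R):
        sim = simulate_dataset(SimulationConfig(n=n, seed=100 + r))
        cells["unharm"].append(boxm_feature_fraction(sim.observed, FORMULA))
        cells["uv"].append(
            boxm_feature_fraction(uv_combat(sim.observed, formula=FORMULA)[0], FORMULA))
        cells["mv"].append(
            boxm_feature_fraction(mv_combat(sim.observed, formula=FORMULA)[0], FORMULA))
    print(f"regular n={n:<6}"
          f"{100 * np.mean(cells['unharm']):>13.1f}%"
          f"{100 * np.mean(cells['uv']):>11.1f}%"
          f"{100 * np.mean(cells['mv']):>11.1f}%")
# Per-metric (univariate) ComBat removes marginal scale effects but leaves
# cross-metric correlation differences; joint (multivariate) harmonization
# drives the covariance batch-effect fraction to zero.
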