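"""Harmonize a multi-metric panel CSV with MV-ComBat (EB).

Builds a small simulated panel, writes it to CSV the way a user's data
would arrive, reads it back, harmonizes it while preserving age, sex and
diagnosis effects, and shows the batch-effect reduction.
"""

import tempfile
from pathlib import Path

import numpy as np

from mvharmonize import SimulationConfig, mv_combat, read_panel, simulate_dataset, write_panel
from mvharmonize.evaluate import boxm_feature_fraction

FORMULA = "age + sex + diagnosis"

sim = simulate_dataset(SimulationConfig(n=150, p=20, M=4, seed=1))
tmp = Path(tempfile.mkdtemp())
write_panel(sim.observed, tmp / "panel.csv", layout="long")

panel = read_panel(tmp / "panel.csv", layout="long",
                   covariates=["age", "sex", "diagnosis"])
print(f"panel: {panel.n_subjects} subjects x {panel.n_features} features "
      f"x {panel.n_metrics} metrics, batches {panel.batches}")

harmonized, posteriors = mv_combat(panel, formula=FORMULA, estimator="eb")

before = boxm_feature_fraction(panel, FORMULA)
after = boxm_feature_fraction(harmonized, FORMULA)
print(f"features with significant cross-metric covariance batch effects "
      f"(Box's M, Bonferroni): {before:.0%} before -> {after:.0%} after")
# Near-zero afterwards means the batch-specific covariance structure was
# equalized while the covariate effects stayed in place.

b = panel.batches[0]
print(f"example location effect gamma* for batch {b!r}, feature 0:",
      np.round(posteriors.gamma_star[b][0], 3))
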