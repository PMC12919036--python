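"""MV-CovBat on latent-space batch effects.

Injects batch effects through a shared low-rank latent representation
(rotations + shifts of the shared scores) and compares MV-ComBat with
MV-CovBat on cross-metric correlation recovery and diagnosis-signal FDR.
"""

from mvharmonize import SimulationConfig, mv_combat, mv_covbat, simulate_dataset
from mvharmonize.evaluate import correlation_distances, signal_preservation

FORMULA = "age + sex + diagnosis"

cfg = SimulationConfig(n=500, p=40, M=4, scenario="latent", seed=7,
                       beta_diag_strong=0.9, beta_diag_weak=0.3)
sim = simulate_dataset(cfg)

mv_panel, _ = mv_combat(sim.observed, formula=FORMULA)
cov_panel, _, latent = mv_covbat(sim.observed, formula=FORMULA)
print(f"shared latent dimension r_s = {latent.r_s}")

for name, panel in (("MV-ComBat", mv_panel), ("MV-CovBat", cov_panel)):
    d = correlation_distances(panel, FORMULA, scope="cross_metric")
    s = signal_preservation(panel, "diagnosis", FORMULA, truth=sim.truth)
    print(f"{name:>10}: cross-metric corr. distance (Frobenius, across batches) "
          f"= {d['frobenius']:.3f}; diagnosis TP = {s['tp']}, FDR = {s['fdr']:.3f}")
# Lower distance = batch-specific correlation structure better equalized;
# FDR below 0.05 means harmonization did not manufacture false diagnosis
# associations.
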