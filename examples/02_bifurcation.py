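"""Recover a lineage bifurcation with the two-lineage mixture model.

Simulates a symmetric bifurcation (each gene's second attractor is the
mirror of the first about the progenitor mean — the geometry of the
sign-inverted pseudogene construction), fits a K=2 mixture, and scores the
soft lineage calls against the hidden labels with precision-recall AUC.
Cells early on the trajectory have responsibilities near 0.5: the model
quantifies fate uncertainty instead of forcing a hard call.
"""

import numpy as np

from oudiff import FitConfig, SimulationSpec, fit_mixture, simulate_dataset
from oudiff.evaluation import lineage_pr_auc
from oudiff.inference import assign_lineage
from oudiff.pseudotime import sp_pseudotime

sim = simulate_dataset(SimulationSpec(C=200, G=50, K=2, mirror_attractors=True,
                                      seed=7))
t_init = sp_pseudotime(sim.expression, sim.init)
fit = fit_mixture(sim.expression, sim.init, K=2, t_init=t_init,
                  cfg=FitConfig(seed=7))

labels = sim.lineage == 1
auc = max(lineage_pr_auc(fit.cells.gamma[:, k], labels) for k in range(2))
calls = assign_lineage(fit.cells.gamma, threshold=0.9)
n_uncertain = sum(1 for c in calls if c == "uncertain")
print(f"mixture weights pi = {np.round(fit.pi, 3)}")
print(f"lineage PR-AUC against hidden labels = {auc:.3f}")
print(f"cells with max gamma below 0.9 (fate still uncertain): {n_uncertain}")
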