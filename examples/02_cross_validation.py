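"""Cross-validated AUPR and the dual-Laplacian ablation.

Runs 10-fold cross-validation with whole target columns blinded (the
new-target, cold-start scenario) on a synthetic dataset, comparing the
grid-tuned Laplacian weight against the lambda = 0 ablation.  Without
the graph term a blinded column receives no signal at all, so the AUPR
gap measures what the similarity graphs contribute.
"""

import warnings

from dlgrmc import HyperParams, SyntheticSpec, recovery_experiment
from dlgrmc.solver import PARAM_GRID

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    res = recovery_experiment(
        SyntheticSpec(seed=0), HyperParams(), cv_setting="cv3",
        n_folds=10, n_reps=1, lam_grid=PARAM_GRID,
    )

print(f"tuned Laplacian weight: lambda = {res.lam}")
print(f"AUPR with dual Laplacian regularization: {res.with_laplacian.mean_aupr:.4f}")
print(f"AUPR with lambda = 0 (ablation):        {res.without_laplacian.mean_aupr:.4f}")
print(f"difference: {res.delta_mean_aupr:+.4f}")
print("\nA positive difference means the similarity graphs successfully "
      "propagate\ninteraction signal to targets with no training data "
      "(AUPR of a random\nranking here would be about the positive "
      "prevalence, 0.064).")
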