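"""Fit competing models to simulated agents and compare them.

Simulates a small cohort from the winning model (2-level context-specific
HGF + task-specific responder), fits a subset of the model space by MAP with
Laplace evidence, and runs random-effects Bayesian model selection.  A full
10-model, 17-agent recovery is what `scripts/acceptance.py` runs; this demo
uses 5 agents and 4 models to finish in under a minute.
"""

import numpy as np

import hgfcue as hc

models = [
    hc.ModelSpec("hgf2_ctx", "task_specific"),
    hc.ModelSpec("hgf2_nonctx", "task_specific"),
    hc.ModelSpec("hgf2_ctx", "task_general"),
    hc.ModelSpec("rw", "task_specific"),
]
cohort, _ = hc.simulate_cohort(n_agents=5, seed=0)

lme = np.empty((len(cohort), len(models)))
for i, trials in enumerate(cohort):
    for j, model in enumerate(models):
        fit = hc.fit_map(trials, model, n_restarts=4, seed=100 + i)
        lme[i, j] = fit.neg_free_energy

bms = hc.rfx_bms(lme, seed=1)
print("per-model summary (log evidence relative to the best model):")
rel = lme.mean(axis=0) - lme.mean(axis=0).max()
for j, model in enumerate(models):
    print(f"  {model.name:28s} n_params={model.n_params:2d}  "
          f"mean rel. logE {rel[j]:7.2f}  "
          f"freq {bms.expected_frequencies[j]:.3f}  pxp {bms.pxp[j]:.3f}")
print(f"Bayesian omnibus risk: {bms.bor:.3g}")
print("\nThe HGF2 variants beat the RW baseline and the task-general "
      "responder\n(which pays for its unused irrelevant decision weights); "
      "the context-specific\nand nonspecific HGF2 are nearly tied because "
      "the generating learning rates\nare almost identical across contexts.")
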