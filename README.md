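# hgfcue

Hierarchical Gaussian Filter (HGF) modelling of behaviour in a
dual-contingency probabilistic cueing task.

In the task this package models, an auditory cue carries two features whose
validity as predictors of a visual target's *location* and *latency* drifts
over time (90/70/50/30/10%, changing every ~32 trials with volatile regime
shifts), while participants alternate between location and latency
discrimination — so each contingency dimension is task-relevant on half the
blocks. The package is for computational-neuroscience researchers who want
to simulate this paradigm, infer an agent's trial-by-trial beliefs from
choices, compare learning models at the group level, and extract model-based
regressors for downstream neural (GLM) analyses.

## What it implements

- **Task simulation** (`task`): volatility-structured cue-validity
  schedules, decorrelated spatial/temporal schedule pairs, 960-trial
  sessions in 20 alternating blocks, and forward-simulated agents.
- **Observer models** (`observers`): the binary HGF, 3-level and 2-level,
  with context-specific or nonspecific learning parameters, and a
  Rescorla–Wagner baseline. Per trial the observer predicts the outcome
  `mu1hat = s(mu2)`, computes the prediction error `delta1 = u − mu1hat`,
  and updates its validity belief by the precision-weighted step
  `delta1 / pi2`; the precision-weighted PE `eps2 = psi2 * delta1` is the
  quantity used as a neural regressor.
- **Response models** (`responses`): relevance-weighted logistic choice,
  `p(y) = s((zeta_rel (2 mu1hat_task − 1) + zeta_irrel (2 mu1hat_other − 1))(2y − 1))`,
  in task-general and task-specific variants.
- **Fitting** (`fitting`): MAP estimation with empirical Gaussian priors in
  transformed space and a Laplace approximation to log model evidence.
- **Model selection** (`selection`): the 10-model factorial space and
  variational random-effects BMS with exceedance probabilities, Bayesian
  omnibus risk and protected exceedance probabilities (PXP).
- **Behavioural analysis** (`analysis`): slow-RT exclusion, stable-run
  second-half selection, predictability × relevance accuracy tables, and
  trial-wise |prediction| / |precision-weighted PE| regressors split by
  dimension and relevance.
- **Canned experiments** (`experiments`): cohort simulation, model
  recovery, decision-weight recovery, regressor-independence diagnostics.

See `docs/methods.md` for the model equations, parameter transforms,
priors, and every numerical convention.

## Worked example

`examples/fit_and_compare.py` simulates five agents from the winning model
(2-level context-specific HGF + task-specific responder, at the reference
parameter values), fits four competing models by MAP and compares them:

```
per-model summary (log evidence relative to the best model):
  hgf2_ctx+task_specific       n_params= 8  mean rel. logE    0.00  freq 0.393  pxp 0.393
  hgf2_nonctx+task_specific    n_params= 6  mean rel. logE   -0.01  freq 0.383  pxp 0.376
  hgf2_ctx+task_general        n_params=10  mean rel. logE   -9.00  freq 0.111  pxp 0.115
  rw+task_specific             n_params= 4  mean rel. logE   -4.31  freq 0.112  pxp 0.115
Bayesian omnibus risk: 0.381
```

Reading the numbers: both HGF2 variants explain the choices far better than
the RW baseline (≈ 4 nats per agent) and than the task-general responder,
which pays an Occam penalty for two irrelevant decision weights the data do
not support (≈ 9 nats). The context-specific and nonspecific HGF2 are
nearly tied — the reference learning rates barely differ between contexts —
so the Dirichlet frequencies split between them and the omnibus risk stays
high, meaning the cohort does not decisively distinguish this pair.

The other examples each exercise one capability and print a short
interpretation:

- `examples/simulate_session.py` — session structure and accuracy by
  relevant cue validity;
- `examples/belief_trajectories.py` — belief tracking of the hidden
  validity series and the decline of prediction errors within stable runs;
- `examples/behavioural_analysis.py` — trial filters, the predictability ×
  relevance accuracy table, and regressor correlations.

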