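"""Reference parameter values for the dual-contingency cueing paradigm.

These constants define the canonical study conditions used throughout the
package: the empirical prior specification for model fitting and a reference
(posterior-mean) parameter set for the winning observer+response model —
a two-level HGF with context-specific learning rates and a task-specific
response model — used as the default generating parameters in simulation
studies (model recovery, parameter recovery, regressor diagnostics).
"""

from __future__ import annotations

import numpy as np

# Empirical prior means/SDs per free parameter, in the transformed space in
# which each parameter is estimated (log for variances and decision weights,
# identity for the omegas, logit for RW learning rates).
PRIOR_LOG_SIGMA2_0 = (0.10, 4.0)
PRIOR_OMEGA = (-5.0, 1.0)
PRIOR_LOG_ZETA = (1.38, 1.0)
PRIOR_LOG_KAPPA = (0.0, 1.0)
PRIOR_LOG_THETA = (-6.0, 1.0)
PRIOR_LOGIT_ALPHA = (0.0, 2.0)

# Posterior-mean estimates (transformed space) for the winning model:
# 2-level HGF, context-specific omega, task-specific zeta.
REFERENCE_PARAMS: dict[str, float] = {
    "log_sigma2_0_s": 0.10,
    "log_sigma2_0_t": 0.09,
    "omega_s_rel": -5.13,
    "omega_t_rel": -5.11,
    "omega_s_irrel": -5.17,
    "omega_t_irrel": -5.22,
    "log_zeta_s_rel": 0.64,
    "log_zeta_t_rel": 0.67,
}

# Matching posterior SDs, used to draw heterogeneous simulated cohorts.
REFERENCE_PARAM_SD: dict[str, float] = {
    "log_sigma2_0_s": 0.01,
    "log_sigma2_0_t": 0.02,
    "omega_s_rel": 0.15,
    "omega_t_rel": 0.20,
    "omega_s_irrel": 0.23,
    "omega_t_irrel": 0.53,
    "log_zeta_s_rel": 0.14,
    "log_zeta_t_rel": 0.18,
}


def sample_reference_params(rng: np.random.Generator) -> dict[str, float]:
    """Draw one agent's parameters around the reference set.

    Each transformed parameter is drawn from a normal with the reference
    posterior mean and SD, giving a plausible between-agent spread for
    parameter-recovery experiments.
    """
    return {
        k: float(rng.normal(m, REFERENCE_PARAM_SD[k]))
        for k, m in REFERENCE_PARAMS.items()
    }
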