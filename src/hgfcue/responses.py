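"""Relevance-weighted logistic response models.

Choice probabilities are a binary softmax of the agent's pre-outcome
predictions.  With the response y and predictions coded in contingency space,

    p(y) = s( zeta_rel  * (2*mu1hat_task  - 1) * (2*y - 1)
            + zeta_irrel * (2*mu1hat_other - 1) * (2*y - 1) )

so that responses congruent with confident predictions are more likely, with
zeta acting as an inverse-decision-noise weight.  In the *task-general*
variant both the currently relevant prediction (the task's own dimension) and
the irrelevant one (the other dimension) carry weight; the *task-specific*
variant fixes both irrelevant weights to zero.  Each zeta subscript names the
prediction dimension: in a spatial-task trial the relevant weight is
``zeta_s_rel`` (spatial predictions) and the irrelevant one ``zeta_t_irrel``
(temporal predictions), and conversely for temporal-task trials.

``literal_sign=True`` restores the negative-sign form in which
prediction-congruent responses are *less* likely; the positive-sign form is
the default, as only it yields above-chance cue-following behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = ["ResponseParams", "response_probability", "response_loglik"]

_P_FLOOR = 1e-12


@dataclass
class ResponseParams:
    variant: str = "task_specific"
    zeta_s_rel: float = 1.0
    zeta_t_rel: float = 1.0
    zeta_s_irrel: float = 0.0
    zeta_t_irrel: float = 0.0
    literal_sign: bool = False

    def __post_init__(self):
        if self.variant not in ("task_specific", "task_general"):
            raise ValueError(f"unknown response variant {self.variant!r}")
        for z in (self.zeta_s_rel, self.zeta_t_rel,
                  self.zeta_s_irrel, self.zeta_t_irrel):
            if z < 0:
                raise ValueError("zeta weights must be nonnegative")
        if self.variant == "task_specific":
            self.zeta_s_irrel = 0.0
            self.zeta_t_irrel = 0.0

    def weights(self, task: str) -> tuple[float, float]:
        """(relevant, irrelevant) weights for trials of the given task."""
        if task == "spatial":
            return self.zeta_s_rel, self.zeta_t_irrel
        if task == "temporal":
            return self.zeta_t_rel, self.zeta_s_irrel
        raise ValueError(f"unknown task {task!r}")


def response_probability(mu1hat_task, mu1hat_other, y,
                         params: ResponseParams, task: str):
    """Probability of response ``y`` given the two predictions.

    ``mu1hat_task`` is the prediction for the task's own dimension and
    ``mu1hat_other`` for the other dimension; scalars or aligned arrays.
    """
    z_rel, z_irrel = params.weights(task)
    drive = (z_rel * (2.0 * np.asarray(mu1hat_task) - 1.0)
             + z_irrel * (2.0 * np.asarray(mu1hat_other) - 1.0))
    sign = -1.0 if params.literal_sign else 1.0
    return expit(sign * drive * (2.0 * np.asarray(y) - 1.0))


def response_loglik(trials: pd.DataFrame, traj_s, traj_t,
                    params: ResponseParams) -> float:
    """Summed log probability of the observed responses.

    Scores each trial's current-task response (y_s on spatial-task trials,
    y_t on temporal-task trials); trials with a missing response contribute
    zero.  Trajectories must be aligned with the trial table.
    """
    n = len(trials)
    if len(traj_s) != n or len(traj_t) != n:
        raise ValueError("trajectory/trial length mismatch")
    loglik = 0.0
    is_spatial = (trials["task"] == "spatial").to_numpy()
    for task, mask, ycol, mh_task, mh_other in (
            ("spatial", is_spatial, "y_s", traj_s.mu1hat, traj_t.mu1hat),
            ("temporal", ~is_spatial, "y_t", traj_t.mu1hat, traj_s.mu1hat)):
        y = trials[ycol].to_numpy(dtype=float)
        scored = mask & np.isfinite(y)
        if not scored.any():
            continue
        p = response_probability(mh_task[scored], mh_other[scored],
                                 y[scored], params, task)
        loglik += float(np.log(np.clip(p, _P_FLOOR, 1.0)).sum())
    return loglik
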