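"""Trial-by-trial observer models for binary cue-target contingencies.

Implements the binary Hierarchical Gaussian Filter (HGF) in its 3-level and
2-level forms, with context-specific or nonspecific learning parameters, and
a Rescorla-Wagner (RW) delta-rule baseline.

The generative model tracked by the HGF: at the lowest level the target
feature ``u`` (coded in contingency space, so ``u = 1`` means the arbitrary
cue-target association held on that trial) is Bernoulli with probability
``s(x2)``, where ``s`` is the logistic sigmoid and ``x2`` is the latent
(logit-scale) cue validity. ``x2`` performs a Gaussian random walk whose step
variance is ``exp(kappa * x3 + omega)``; the log-volatility ``x3`` performs a
random walk with variance ``theta``. Inverting this model yields closed-form
variational updates: per trial the observer forms a prediction
``mu1hat = s(mu2)``, observes ``u``, computes the outcome prediction error
``delta1 = u - mu1hat``, and updates its validity belief by the
precision-weighted step ``delta1 / pi2``, where ``pi2`` is the posterior
precision at level 2.  The 2-level variant freezes the volatility level
(``kappa = 0``), so the step variance reduces to ``exp(omega)``.

Context specificity: the constant step-size parameter ``omega`` may differ
between trials where the filtered dimension is task-relevant and trials where
it is not (``omega_rel`` vs ``omega_irrel``); both dimensions are always
filtered on every trial, the context only selects which omega applies.

The precision-weighted prediction error reported at level 2 is
``eps2 = psi2 * delta1``.  The generic precision ratio is
``psi2 = pi1hat / pi2``; for binary outcomes we fix ``pi1hat = 1`` by default,
so ``eps2`` equals the belief update ``delta1 / pi2``.  The alternative
convention ``pi1hat = 1 / (mu1hat * (1 - mu1hat))`` is available via
``ObserverParams.unit_pi1hat = False``; it rescales ``eps2`` (by about 4 near
``mu1hat = 0.5``) without affecting the belief trajectory itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import expit

__all__ = [
    "ObserverParams",
    "BeliefTrajectory",
    "sigmoid",
    "hgf_filter",
    "rw_filter",
    "filter_trials_both_dimensions",
]

VAR_FLOOR = 1e-8

_STATE_NAMES = (
    "mu1hat", "delta1", "mu2hat", "mu2", "sigma2", "pi2hat", "pi2",
    "psi2", "eps2", "mu3", "sigma3", "delta2", "eps3",
)


def sigmoid(x):
    """Logistic sigmoid ``s(x) = 1 / (1 + exp(-x))``, strictly in (0, 1)."""
    return expit(x)


@dataclass
class ObserverParams:
    """Parameters of one agent's observer model (both dimensions).

    ``variant`` selects the filter: ``"hgf3"`` (full three-level),
    ``"hgf2"`` (volatility level frozen, ``kappa`` forced to 0) or ``"rw"``
    (fixed-learning-rate delta rule).  Omegas are log step-size variances;
    ``theta`` is the volatility random-walk variance (HGF3 only); ``alpha_*``
    are RW learning rates in [0, 1].
    """

    variant: str = "hgf2"
    kappa: float = 0.0
    theta: float = float(np.exp(-6.0))
    log_sigma2_0_s: float = 0.10
    log_sigma2_0_t: float = 0.10
    omega_s_rel: float = -5.0
    omega_s_irrel: float = -5.0
    omega_t_rel: float = -5.0
    omega_t_irrel: float = -5.0
    mu2_0: float = 0.0
    mu3_0: float = 1.0
    sigma3_0: float = 1.0
    alpha_s: float = 0.2
    alpha_t: float = 0.2
    unit_pi1hat: bool = True

    def __post_init__(self):
        if self.variant not in ("hgf3", "hgf2", "rw"):
            raise ValueError(f"unknown observer variant {self.variant!r}")
        if self.variant == "hgf2":
            self.kappa = 0.0
        if self.variant in ("hgf3", "hgf2"):
            if self.theta <= 0:
                raise ValueError("theta must be strictly positive")
            if self.sigma3_0 <= 0:
                raise ValueError("sigma3_0 must be strictly positive")
        if self.variant == "rw":
            for a in (self.alpha_s, self.alpha_t):
                if not 0.0 <= a <= 1.0:
                    raise ValueError("RW learning rate must lie in [0, 1]")

    def omegas(self, dimension: str) -> tuple[float, float]:
        if dimension == "spatial":
            return self.omega_s_rel, self.omega_s_irrel
        return self.omega_t_rel, self.omega_t_irrel

    def sigma2_0(self, dimension: str) -> float:
        ls = self.log_sigma2_0_s if dimension == "spatial" else self.log_sigma2_0_t
        return float(np.exp(ls))

    def alpha(self, dimension: str) -> float:
        return self.alpha_s if dimension == "spatial" else self.alpha_t

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class BeliefTrajectory:
    """Per-trial belief states of one dimension's filter.

    Row ``k`` holds the pre-outcome prediction quantities for trial ``k``
    (``mu1hat``, ``mu2hat``, ``pi2hat``) and the post-outcome updates after
    observing ``u(k)`` (``mu2``, ``sigma2``, ``eps2``, ...).  For the 2-level
    HGF, ``mu3`` and ``sigma3`` stay at their initial values; for the RW
    filter only ``mu1hat``, ``delta1`` and ``eps2`` (= alpha * delta1) are
    meaningful and the remaining fields are NaN.
    """

    dimension: str
    valid: bool = True
    mu1hat: np.ndarray = field(default_factory=lambda: np.empty(0))
    delta1: np.ndarray = field(default_factory=lambda: np.empty(0))
    mu2hat: np.ndarray = field(default_factory=lambda: np.empty(0))
    mu2: np.ndarray = field(default_factory=lambda: np.empty(0))
    sigma2: np.ndarray = field(default_factory=lambda: np.empty(0))
    pi2hat: np.ndarray = field(default_factory=lambda: np.empty(0))
    pi2: np.ndarray = field(default_factory=lambda: np.empty(0))
    psi2: np.ndarray = field(default_factory=lambda: np.empty(0))
    eps2: np.ndarray = field(default_factory=lambda: np.empty(0))
    mu3: np.ndarray = field(default_factory=lambda: np.empty(0))
    sigma3: np.ndarray = field(default_factory=lambda: np.empty(0))
    delta2: np.ndarray = field(default_factory=lambda: np.empty(0))
    eps3: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __len__(self) -> int:
        return len(self.mu1hat)

    def to_frame(self) -> pd.DataFrame:
        """Serialize as one row per trial, one column per state variable."""
        data = {name: getattr(self, name) for name in _STATE_NAMES}
        df = pd.DataFrame(data)
        df.insert(0, "trial", np.arange(len(df)))
        return df


@njit(cache=True)
def _hgf_core(u, is_rel, kappa, om_rel, om_irrel, theta,
              mu2_0, sigma2_0, mu3_0, sigma3_0, three_level, unit_pi1hat):
    n = u.shape[0]
    out = np.empty((13, n))
    m2, s2 = mu2_0, sigma2_0
    m3, s3 = mu3_0, sigma3_0
    ok = True
    for k in range(n):
        om = om_rel if is_rel[k] else om_irrel
        v2 = np.exp(kappa * m3 + om)
        mh1 = 1.0 / (1.0 + np.exp(-m2))
        s2hat = s2 + v2
        if not np.isfinite(s2hat) or s2hat <= 0.0:
            ok = False
            break
        p2hat = 1.0 / s2hat
        d1 = u[k] - mh1
        p2 = p2hat + mh1 * (1.0 - mh1)
        if not np.isfinite(p2) or p2 <= 0.0:
            ok = False
            break
        new_s2 = 1.0 / p2
        if new_s2 < VAR_FLOOR:
            new_s2 = VAR_FLOOR
        new_m2 = m2 + d1 / p2
        if unit_pi1hat:
            psi = 1.0 / p2
        else:
            psi = 1.0 / (mh1 * (1.0 - mh1) * p2)
        e2 = psi * d1
        # volatility prediction error (defined for both variants; drives the
        # third level only when it is inferred)
        d2 = (new_s2 + (new_m2 - m2) ** 2) / s2hat - 1.0
        if three_level:
            if s3 + theta <= 0.0:
                ok = False
                break
            p3hat = 1.0 / (s3 + theta)
            w2 = v2 / s2hat
            r2 = (v2 - s2) / s2hat
            p3 = p3hat + 0.5 * kappa * kappa * w2 * (w2 + r2 * d2)
            if p3 <= 0.0:
                ok = False
                break
            new_s3 = 1.0 / p3
            if new_s3 < VAR_FLOOR:
                new_s3 = VAR_FLOOR
            new_m3 = m3 + new_s3 * 0.5 * kappa * w2 * d2
            e3 = new_m3 - m3
        else:
            new_s3, new_m3, e3 = s3, m3, 0.0
        out[0, k] = mh1
        out[1, k] = d1
        out[2, k] = m2
        out[3, k] = new_m2
        out[4, k] = new_s2
        out[5, k] = p2hat
        out[6, k] = p2
        out[7, k] = psi
        out[8, k] = e2
        out[9, k] = new_m3
        out[10, k] = new_s3
        out[11, k] = d2
        out[12, k] = e3
        m2, s2, m3, s3 = new_m2, new_s2, new_m3, new_s3
        if not (np.isfinite(m2) and np.isfinite(s2)
                and np.isfinite(m3) and np.isfinite(s3)):
            ok = False
            break
    return out, ok


def _outcomes(trials: pd.DataFrame, dimension: str) -> tuple[np.ndarray, np.ndarray]:
    if dimension not in ("spatial", "temporal"):
        raise ValueError(f"unknown dimension {dimension!r}")
    col = "u_s" if dimension == "spatial" else "u_t"
    u = np.asarray(trials[col], dtype=float)
    if not np.all(np.isin(u, (0.0, 1.0))):
        raise ValueError(f"{col} must be binary (0/1)")
    is_rel = np.asarray(trials["task"] == dimension)
    return u, is_rel


def hgf_filter(trials: pd.DataFrame, params: ObserverParams,
               dimension: str) -> BeliefTrajectory:
    """Run the binary HGF over one contingency dimension of a trial table.

    ``trials`` must carry the contingency-space outcome column (``u_s`` or
    ``u_t``) and the per-trial ``task`` label, which selects between
    ``omega_rel`` and ``omega_irrel``.  Returns the full belief trajectory;
    ``valid`` is False when the parameters produced a numerical pathology
    (non-finite state or non-positive volatility precision), in which case
    downstream likelihoods should treat the parameter vector as inadmissible.
    """
    if params.variant == "rw":
        return rw_filter(trials, params, dimension)
    u, is_rel = _outcomes(trials, dimension)
    om_rel, om_irrel = params.omegas(dimension)
    out, ok = _hgf_core(
        u, is_rel, params.kappa, om_rel, om_irrel, params.theta,
        params.mu2_0, params.sigma2_0(dimension), params.mu3_0,
        params.sigma3_0, params.variant == "hgf3", params.unit_pi1hat,
    )
    traj = BeliefTrajectory(dimension=dimension, valid=bool(ok))
    for i, name in enumerate(_STATE_NAMES):
        setattr(traj, name, out[i].copy())
    return traj


@njit(cache=True)
def _rw_core(u, alpha):
    n = u.shape[0]
    mu1hat = np.empty(n)
    delta1 = np.empty(n)
    eps = np.empty(n)
    v = 0.5
    for k in range(n):
        mu1hat[k] = v
        delta1[k] = u[k] - v
        eps[k] = alpha * delta1[k]
        v = v + alpha * (u[k] - v)
    return mu1hat, delta1, eps


def rw_filter(trials: pd.DataFrame, params: ObserverParams,
              dimension: str) -> BeliefTrajectory:
    """Rescorla-Wagner delta rule: v(k+1) = v(k) + alpha (u(k) - v(k)).

    The prediction ``mu1hat(k)`` is the pre-update value v(k), initialised at
    0.5; the learning rate is fixed per dimension with no context
    specificity.
    """
    u, _ = _outcomes(trials, dimension)
    alpha = params.alpha(dimension)
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("RW learning rate must lie in [0, 1]")
    mu1hat, delta1, eps = _rw_core(u, alpha)
    traj = BeliefTrajectory(dimension=dimension, valid=True)
    nan = np.full(len(u), np.nan)
    for name in _STATE_NAMES:
        setattr(traj, name, nan.copy())
    traj.mu1hat = mu1hat
    traj.delta1 = delta1
    traj.eps2 = eps
    return traj


def filter_trials_both_dimensions(
    trials: pd.DataFrame, params: ObserverParams
) -> tuple[BeliefTrajectory, BeliefTrajectory]:
    """Convenience: filter the spatial and temporal dimensions jointly."""
    return (hgf_filter(trials, params, "spatial"),
            hgf_filter(trials, params, "temporal"))
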