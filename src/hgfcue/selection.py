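"""Model space enumeration and random-effects Bayesian model selection.

The canonical model space crosses 5 observer models (3-level HGF and 2-level
HGF, each with context-specific or nonspecific learning parameters, plus a
Rescorla-Wagner baseline) with 2 response models (task-general and
task-specific), giving 10 models.

Group-level comparison treats the model identity as a random effect across
subjects: given a subjects x models matrix of log evidences, a variational
Dirichlet posterior over population model frequencies is estimated, from
which we report expected frequencies, exceedance probabilities (EP; the
posterior probability that a model is the most frequent), the Bayesian
omnibus risk (BOR; the posterior probability that all models are equally
frequent, obtained by comparing the free energies of the null and the
estimated alternative), and protected exceedance probabilities
PXP = (1 - BOR) * EP + BOR / K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, logsumexp

__all__ = ["ModelSpec", "enumerate_model_space", "rfx_bms", "BmsResult"]

OBSERVERS = ("hgf3_ctx", "hgf3_nonctx", "hgf2_ctx", "hgf2_nonctx", "rw")
RESPONDERS = ("task_general", "task_specific")


@dataclass(frozen=True)
class ModelSpec:
    """One observer x responder combination and its free-parameter list.

    Free parameters are named in the transformed space in which they are
    estimated (``log_*`` for positivity-constrained parameters, ``logit_*``
    for rates in [0, 1], plain names for unconstrained ones).
    """

    observer: str
    responder: str

    def __post_init__(self):
        if self.observer not in OBSERVERS:
            raise ValueError(f"unknown observer {self.observer!r}")
        if self.responder not in RESPONDERS:
            raise ValueError(f"unknown responder {self.responder!r}")

    @property
    def name(self) -> str:
        return f"{self.observer}+{self.responder}"

    @property
    def observer_variant(self) -> str:
        return "rw" if self.observer == "rw" else self.observer.split("_")[0]

    @property
    def context_specific(self) -> bool:
        return self.observer.endswith("_ctx")

    @property
    def param_names(self) -> tuple[str, ...]:
        names: list[str] = []
        if self.observer == "rw":
            names += ["logit_alpha_s", "logit_alpha_t"]
        else:
            names += ["log_sigma2_0_s", "log_sigma2_0_t"]
            if self.context_specific:
                names += ["omega_s_rel", "omega_s_irrel",
                          "omega_t_rel", "omega_t_irrel"]
            else:
                names += ["omega_s", "omega_t"]
            if self.observer_variant == "hgf3":
                names += ["log_kappa", "log_theta"]
        names += ["log_zeta_s_rel", "log_zeta_t_rel"]
        if self.responder == "task_general":
            names += ["log_zeta_s_irrel", "log_zeta_t_irrel"]
        return tuple(names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)


def enumerate_model_space(observers=OBSERVERS,
                          responders=RESPONDERS) -> list[ModelSpec]:
    """The canonical factorial model space, in fixed observer-major order."""
    return [ModelSpec(o, r) for o in observers for r in responders]


@dataclass
class BmsResult:
    """Random-effects model-selection summary over K models."""

    dirichlet_alpha: np.ndarray
    expected_frequencies: np.ndarray
    exceedance_prob: np.ndarray
    bor: float
    pxp: np.ndarray
    model_attributions: np.ndarray = field(default_factory=lambda: np.empty(0))
    free_energy_alt: float = 0.0
    free_energy_null: float = 0.0

    @property
    def best(self) -> int:
        return int(np.argmax(self.pxp))


def _vb_dirichlet(lme: np.ndarray, alpha0: np.ndarray,
                  max_iter: int = 500, tol: float = 1e-9):
    alpha = alpha0.copy()
    g = np.full_like(lme, 1.0 / lme.shape[1])
    for _ in range(max_iter):
        elogr = digamma(alpha) - digamma(alpha.sum())
        logu = lme + elogr
        g = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    return alpha, g


def _dirichlet_kl(alpha: np.ndarray, alpha0: np.ndarray) -> float:
    a0, a = alpha0, alpha
    return float(
        gammaln(a.sum()) - gammaln(a).sum()
        - gammaln(a0.sum()) + gammaln(a0).sum()
        + ((a - a0) * (digamma(a) - digamma(a.sum()))).sum()
    )


def rfx_bms(log_evidences: np.ndarray, n_samples: int = 100_000,
            seed: int = 0, alpha0: np.ndarray | None = None) -> BmsResult:
    """Random-effects BMS over a subjects x models log-evidence matrix.

    Exceedance probabilities are estimated by Monte Carlo sampling from the
    fitted Dirichlet posterior (``n_samples`` draws, seeded).  The BOR
    compares the free energy of the estimated frequency model against the
    fixed equal-frequency null, F0 = sum_n [logsumexp_k lme_nk - log K].
    """
    lme = np.asarray(log_evidences, dtype=float)
    if lme.ndim != 2 or lme.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 models")
    if not np.all(np.isfinite(lme)):
        raise ValueError("log evidences must be finite")
    n_subj, k = lme.shape
    alpha0 = np.ones(k) if alpha0 is None else np.asarray(alpha0, float)

    alpha, g = _vb_dirichlet(lme, alpha0)
    r = alpha / alpha.sum()

    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    xp = np.bincount(winners, minlength=k) / n_samples

    elogr = digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = np.where(g > 0, g * np.log(g), 0.0).sum()
    f_alt = float((g * (lme + elogr)).sum() - entropy
                  - _dirichlet_kl(alpha, alpha0))
    f_null = float((logsumexp(lme, axis=1) - np.log(k)).sum())
    bor = float(1.0 / (1.0 + np.exp(f_alt - f_null)))
    pxp = (1.0 - bor) * xp + bor / k
    return BmsResult(
        dirichlet_alpha=alpha,
        expected_frequencies=r,
        exceedance_prob=xp,
        bor=bor,
        pxp=pxp,
        model_attributions=g,
        free_energy_alt=f_alt,
        free_energy_null=f_null,
    )
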