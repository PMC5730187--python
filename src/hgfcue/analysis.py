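"""Behavioural condition construction, trial filters and model regressors.

Condition construction collapses the five validity levels into three
predictability bins (strong = {90%, 10%}, weak = {70%, 30%},
unpredictable = {50%}) and crosses them with task relevance (whether the
binned dimension is the one currently reported).  Accuracy is assessed on
the second half of each stable-validity run, after discarding slow-RT
outliers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .observers import BeliefTrajectory
from .task import ContingencySchedule, DIMENSIONS

__all__ = [
    "filter_trials",
    "stable_second_half",
    "accuracy_table",
    "extract_regressors",
    "regressor_correlations",
    "mean_abs_correlation",
    "predictability_anova",
    "parameter_accuracy_correlation",
]

PREDICTABILITY_BINS = {
    0.9: "strong", 0.1: "strong",
    0.7: "weak", 0.3: "weak",
    0.5: "unpredictable",
}


def _responded(trials: pd.DataFrame) -> np.ndarray:
    y = np.where(trials["task"] == "spatial", trials["y_s"], trials["y_t"])
    return np.isfinite(y.astype(float))


def filter_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Discard slow-RT outliers: RT > median + 2 SD (strict inequality).

    The cutoff is computed over responded trials with an RT, using the
    sample SD (ddof=1; 0 for a single trial); trials with a missing RT pass
    through unfiltered.
    """
    rt = trials["rt"].to_numpy(dtype=float)
    have = np.isfinite(rt) & _responded(trials)
    if not have.any():
        return trials.copy()
    sd = np.std(rt[have], ddof=1) if have.sum() > 1 else 0.0
    cutoff = np.median(rt[have]) + 2.0 * sd
    keep = ~(np.isfinite(rt) & (rt > cutoff))
    return trials.loc[keep].copy()


def stable_second_half(trials: pd.DataFrame,
                       schedule: ContingencySchedule) -> pd.DataFrame:
    """Mark trials in the later half of each stable-validity run.

    Adds boolean columns ``stable_s`` / ``stable_t``: within a run of length
    L, trials with 1-based within-run index > ceil(L/2) are marked (so the
    final floor(L/2) trials; a run of length 1 contributes none).  The two
    dimensions are marked independently since their schedules are
    independent.  Runs are delimited on the full schedule, so the marks stay
    correct on already-filtered trial subsets.
    """
    out = trials.copy()
    idx = out["trial"].to_numpy()
    for dim, col in (("spatial", "stable_s"), ("temporal", "stable_t")):
        mark = np.zeros(schedule.n_trials, dtype=bool)
        for start, length, _ in schedule.runs(dim):
            half = int(np.ceil(length / 2))
            mark[start + half:start + length] = True
        out[col] = mark[idx]
    return out


def _correct(trials: pd.DataFrame) -> np.ndarray:
    is_sp = trials["task"] == "spatial"
    y = np.where(is_sp, trials["y_s"], trials["y_t"]).astype(float)
    u = np.where(is_sp, trials["u_s"], trials["u_t"]).astype(float)
    return np.where(np.isfinite(y), (y == u).astype(float), np.nan)


def accuracy_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracy per dimension x predictability x relevance cell.

    ``trials`` should already carry the ``stable_s`` / ``stable_t`` marks
    (see :func:`stable_second_half`) and have RT outliers removed; a cell's
    trials are the stable trials of that dimension at the binned validity,
    split by whether the dimension matches the current task.  Accuracy is the
    proportion of correct discriminations (current-task response equals the
    target feature, both in contingency space).  Empty cells report
    ``n_trials = 0`` and NaN accuracy.
    """
    correct = _correct(trials)
    rows = []
    for dim in DIMENSIONS:
        vcol = "validity_s" if dim == "spatial" else "validity_t"
        scol = "stable_s" if dim == "spatial" else "stable_t"
        stable = trials[scol].to_numpy() if scol in trials else np.ones(len(trials), bool)
        bins = trials[vcol].map(PREDICTABILITY_BINS)
        relevant = (trials["task"] == dim).to_numpy()
        for pred in ("strong", "weak", "unpredictable"):
            for rel, rel_name in ((True, "relevant"), (False, "irrelevant")):
                mask = (stable & (bins == pred).to_numpy()
                        & (relevant == rel) & np.isfinite(correct))
                n = int(mask.sum())
                rows.append({
                    "dimension": dim,
                    "predictability": pred,
                    "relevance": rel_name,
                    "n_trials": n,
                    "accuracy": float(correct[mask].mean()) if n else np.nan,
                })
    return pd.DataFrame(rows)


def extract_regressors(traj_s: BeliefTrajectory, traj_t: BeliefTrajectory,
                       trials: pd.DataFrame, signed: bool = False) -> pd.DataFrame:
    """Trial-wise model regressors, split by dimension and task relevance.

    Prediction regressors |mu2hat| use the pre-outcome (cue-locked) belief
    about cue validity; PE regressors |eps2| use the post-outcome
    (target-locked) precision-weighted prediction error.  Each trial
    contributes to exactly one relevance cell per dimension (relevant when
    the trial's task matches the dimension); entries outside a cell's trials
    are zero.  ``signed=True`` keeps the sign of eps2 (control analysis).
    """
    n = len(trials)
    if len(traj_s) != n or len(traj_t) != n:
        raise ValueError("trajectories and trials are misaligned")
    mag = (lambda v: v) if signed else np.abs
    out = {"trial": trials["trial"].to_numpy()}
    for dim, traj in (("s", traj_s), ("t", traj_t)):
        rel = (trials["task"] == ("spatial" if dim == "s" else "temporal")).to_numpy()
        for kind, series in (("pred", mag(traj.mu2hat)), ("pe", mag(traj.eps2))):
            out[f"{kind}_{dim}_rel"] = np.where(rel, series, 0.0)
            out[f"{kind}_{dim}_irrel"] = np.where(~rel, series, 0.0)
    return pd.DataFrame(out)


def regressor_correlations(regs: pd.DataFrame, center: bool = True) -> pd.DataFrame:
    """Pairwise Pearson correlations between the regressor columns.

    With ``center`` (default), each regressor is mean-centred over its own
    supporting trials (nonzero entries) before correlating, mirroring how
    parametric modulators enter a convolution GLM; without it the raw
    zero-filled magnitudes are correlated, which induces structural
    anticorrelation between the disjoint relevant/irrelevant supports.
    Constant regressors yield NaN rows/columns (flagged by the caller via
    ``isna``).
    """
    cols = [c for c in regs.columns if c != "trial"]
    x = regs[cols].to_numpy(dtype=float).copy()
    if center:
        for j in range(x.shape[1]):
            support = x[:, j] != 0.0
            if support.any():
                x[support, j] -= x[support, j].mean()
    sd = x.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, np.where(sd == 0, np.nan, 1.0))
    return pd.DataFrame(corr, index=cols, columns=cols)


def mean_abs_correlation(corr: pd.DataFrame) -> float:
    """Mean absolute off-diagonal correlation (NaN entries excluded)."""
    a = corr.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, np.nan)
    iu = np.triu_indices_from(a, k=1)
    vals = a[iu]
    return float(np.nanmean(np.abs(vals)))


def predictability_anova(cell_means: pd.DataFrame) -> pd.DataFrame:
    """Repeated-measures ANOVA (predictability x relevance) on cell means.

    Expects long-format columns ``subject``, ``predictability``,
    ``relevance``, ``accuracy`` for a single dimension; returns the standard
    F-table.  Provided for simulation demos of the predictability-by-
    relevance interaction.
    """
    from statsmodels.stats.anova import AnovaRM
    res = AnovaRM(cell_means, depvar="accuracy", subject="subject",
                  within=["predictability", "relevance"]).fit()
    return res.anova_table


def parameter_accuracy_correlation(params: pd.DataFrame,
                                   accuracy: np.ndarray) -> pd.DataFrame:
    """Per-parameter Pearson correlation with subjects' mean accuracy.

    A plain correlation report (one row per parameter column: r and p),
    as a simple between-subject validation of fitted parameters.
    """
    rows = []
    acc = np.asarray(accuracy, dtype=float)
    for col in params.columns:
        r, p = stats.pearsonr(params[col].to_numpy(dtype=float), acc)
        rows.append({"parameter": col, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)
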