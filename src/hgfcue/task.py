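"""Simulation of the dual-contingency probabilistic cueing task.

The paradigm: on each trial an auditory cue with two features (pitch,
composition) precedes a visual target with two features (location, latency).
Cue pitch probabilistically predicts target location and cue composition
predicts target latency, with validities drawn from {90, 70, 50, 30, 10}%
that change every ~32 trials (range 8-54).  How often validity changes is
itself volatile: run lengths are drawn around a volatility mean of 16, 32 or
48 trials that advances after every 5 validity changes.  The two contingency
series (spatial, temporal) are generated independently and a schedule pair is
accepted only once their trial-wise Pearson correlation is negligible.
Participants alternate between location and latency discrimination in 20
blocks of ~48 trials (960 trials total).

Everything is coded in *contingency space*: the outcome ``u_d = 1`` means the
arbitrary cue-target association held on that trial (e.g. right target after
high-pitch cue), so ``P(u_d = 1) = validity_d`` irrespective of the cue drawn.
Responses ``y_d`` use the identical coding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .observers import ObserverParams, filter_trials_both_dimensions
from .responses import ResponseParams, response_probability

__all__ = [
    "SessionConfig",
    "ContingencySchedule",
    "generate_validity_series",
    "generate_validity_schedule",
    "default_schedule",
    "generate_trials",
    "simulate_agent",
    "simulate_session",
    "read_trials",
    "write_trials",
]

DIMENSIONS = ("spatial", "temporal")

# Seed of the stored ("fixture") default schedule pair used when a single
# canonical session layout is wanted across simulated participants.
DEFAULT_SCHEDULE_SEED = 20_170


@dataclass
class SessionConfig:
    """Session-level generative settings (defaults reproduce the paradigm)."""

    n_blocks: int = 20
    mean_block_len: int = 48
    block_len_range: tuple[int, int] = (38, 58)
    validity_levels: tuple[float, ...] = (0.9, 0.7, 0.5, 0.3, 0.1)
    volatility_means: tuple[int, ...] = (16, 32, 48)
    runs_per_volatility: int = 5
    run_len_range: tuple[int, int] = (8, 54)
    run_len_halfwidth: int = 8
    max_series_correlation: float = 1e-4
    max_attempts: int = 100_000
    first_task: str = "spatial"
    rng_seed: int = 0

    def __post_init__(self):
        if not all(0.0 < v < 1.0 for v in self.validity_levels):
            raise ValueError("validity levels must lie in (0, 1)")
        if self.first_task not in DIMENSIONS:
            raise ValueError("first_task must be 'spatial' or 'temporal'")
        if self.run_len_range[0] > self.run_len_range[1]:
            raise ValueError("invalid run_len_range")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.mean_block_len

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "SessionConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("block_len_range", "validity_levels", "volatility_means",
                    "run_len_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class ContingencySchedule:
    """Piecewise-constant validity series for both contingency dimensions."""

    validity_s: np.ndarray
    validity_t: np.ndarray
    run_lengths_s: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    run_lengths_t: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    n_attempts: int = 1

    @property
    def n_trials(self) -> int:
        return len(self.validity_s)

    def validity(self, dimension: str) -> np.ndarray:
        return self.validity_s if dimension == "spatial" else self.validity_t

    def change_points(self, dimension: str) -> np.ndarray:
        """Trial indices k >= 1 where validity(k) != validity(k-1)."""
        v = self.validity(dimension)
        return np.flatnonzero(np.diff(v) != 0) + 1

    def runs(self, dimension: str) -> list[tuple[int, int, float]]:
        """Realized runs as (start, length, validity), truncated at the end."""
        v = self.validity(dimension)
        bounds = np.concatenate(([0], self.change_points(dimension),
                                 [len(v)]))
        return [(int(a), int(b - a), float(v[a]))
                for a, b in zip(bounds[:-1], bounds[1:])]

    def correlation(self) -> float:
        return float(np.corrcoef(self.validity_s, self.validity_t)[0, 1])


def _draw_series(rng: np.random.Generator, cfg: SessionConfig,
                 n_trials: int) -> tuple[np.ndarray, np.ndarray]:
    levels = np.asarray(cfg.validity_levels, dtype=float)
    if len(set(cfg.validity_levels)) < 2:
        raise ValueError(
            "at least two distinct validity levels are required so that "
            "consecutive levels never repeat")
    lo, hi = cfg.run_len_range
    hw = cfg.run_len_halfwidth
    # volatility means cycle pseudorandomly: a fresh permutation per cycle,
    # never repeating the mean active at the cycle boundary
    vol_order = rng.permutation(cfg.volatility_means)
    vol_idx = 0
    runs_in_phase = 0
    level = float(rng.choice(levels))
    validity = np.empty(n_trials)
    run_lengths: list[int] = []
    pos = 0
    while pos < n_trials:
        mean = int(vol_order[vol_idx])
        length = int(rng.integers(mean - hw, mean + hw + 1))
        length = int(np.clip(length, lo, hi))
        run_lengths.append(length)
        end = min(pos + length, n_trials)
        validity[pos:end] = level
        pos = end
        runs_in_phase += 1
        if runs_in_phase == cfg.runs_per_volatility:
            runs_in_phase = 0
            vol_idx += 1
            if vol_idx == len(vol_order):
                prev = vol_order[-1]
                vol_order = rng.permutation(cfg.volatility_means)
                while len(vol_order) > 1 and vol_order[0] == prev:
                    vol_order = rng.permutation(cfg.volatility_means)
                vol_idx = 0
        # no repetitions of consecutive validity levels
        level = float(rng.choice(levels[levels != level]))
    return validity, np.asarray(run_lengths, dtype=int)


def generate_validity_series(cfg: SessionConfig, n_trials: int,
                             seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Generate a single validity series; returns (validity, run_lengths).

    ``run_lengths`` are the drawn (untruncated) lengths of all runs started,
    which is the right sample for run-length statistics; the realized series
    truncates the final run at ``n_trials``.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    return _draw_series(rng, cfg, n_trials)


def generate_validity_schedule(cfg: SessionConfig, n_trials: int | None = None,
                               seed: int | None = None,
                               decorrelate: bool = True) -> ContingencySchedule:
    """Generate the (spatial, temporal) schedule pair.

    Both series are drawn independently; with ``decorrelate`` the pair is
    regenerated under incremented sub-seeds until the absolute Pearson
    correlation of the two trial-wise validity series is at most
    ``cfg.max_series_correlation``.  Raises ``RuntimeError`` if no pair is
    accepted within ``cfg.max_attempts`` attempts (a configuration error:
    e.g. an unattainable correlation bound for short sessions).
    """
    n = cfg.n_trials if n_trials is None else n_trials
    base = cfg.rng_seed if seed is None else seed
    root = np.random.SeedSequence(base)
    for attempt in range(cfg.max_attempts if decorrelate else 1):
        ss, st = root.spawn(2)
        vs, rls = _draw_series(np.random.default_rng(ss), cfg, n)
        vt, rlt = _draw_series(np.random.default_rng(st), cfg, n)
        r = np.corrcoef(vs, vt)[0, 1]
        if not decorrelate or abs(r) <= cfg.max_series_correlation:
            return ContingencySchedule(vs, vt, rls, rlt,
                                       n_attempts=attempt + 1)
    raise RuntimeError(
        f"no schedule pair with |r| <= {cfg.max_series_correlation} found "
        f"in {cfg.max_attempts} attempts")


def default_schedule(cfg: SessionConfig | None = None) -> ContingencySchedule:
    """The canonical accepted schedule pair (fixed fixture seed).

    Mirrors the study design in which a single precomputed, decorrelated
    validity time-series pair was shared by all participants.
    """
    cfg = cfg or SessionConfig()
    return generate_validity_schedule(cfg, seed=DEFAULT_SCHEDULE_SEED)


def _block_lengths(rng: np.random.Generator, cfg: SessionConfig) -> np.ndarray:
    lo, hi = cfg.block_len_range
    lens = rng.integers(lo, hi + 1, size=cfg.n_blocks)
    target = cfg.n_trials
    while lens.sum() != target:
        step = 1 if lens.sum() < target else -1
        i = int(rng.integers(cfg.n_blocks))
        if lo <= lens[i] + step <= hi:
            lens[i] += step
    return lens


def generate_trials(schedule: ContingencySchedule, cfg: SessionConfig,
                    seed: int | None = None) -> pd.DataFrame:
    """Draw cue features and contingency-space outcomes for a session.

    Returns one row per trial with columns: trial, block, task, cue_pitch,
    cue_composition, validity_s, validity_t, u_s, u_t, y_s, y_t, rt.
    Responses and RTs are NaN until an agent (or participant) fills them.
    """
    n = cfg.n_trials
    if schedule.n_trials < n:
        raise ValueError("schedule does not cover the configured session")
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    lens = _block_lengths(rng, cfg)
    block = np.repeat(np.arange(cfg.n_blocks), lens)
    order = DIMENSIONS if cfg.first_task == "spatial" else DIMENSIONS[::-1]
    task = np.array([order[b % 2] for b in block])
    vs = schedule.validity_s[:n]
    vt = schedule.validity_t[:n]
    trials = pd.DataFrame({
        "trial": np.arange(n),
        "block": block,
        "task": task,
        "cue_pitch": rng.integers(0, 2, n),
        "cue_composition": rng.integers(0, 2, n),
        "validity_s": vs,
        "validity_t": vt,
        "u_s": (rng.random(n) < vs).astype(int),
        "u_t": (rng.random(n) < vt).astype(int),
        "y_s": np.nan,
        "y_t": np.nan,
        "rt": np.nan,
    })
    return trials


def simulate_agent(trials: pd.DataFrame, observer: ObserverParams,
                   responder: ResponseParams, seed: int = 0,
                   rt_lognormal: tuple[float, float] | None = None) -> pd.DataFrame:
    """Fill in responses by forward-simulating an observer+response agent.

    Belief updates use the presented outcomes ``u`` (not the sampled
    responses).  On each trial only the current task's response is recorded,
    sampled from the relevance-weighted logistic response model given the
    pre-outcome predictions.  Optionally draws log-normal RTs (parameters of
    the underlying normal, in log-seconds) as a stub for RT-filter testing.
    """
    rng = np.random.default_rng(seed)
    traj_s, traj_t = filter_trials_both_dimensions(trials, observer)
    if not (traj_s.valid and traj_t.valid):
        raise ValueError("observer parameters produced an invalid trajectory")
    out = trials.copy()
    is_spatial = (out["task"] == "spatial").to_numpy()
    p1_s = response_probability(traj_s.mu1hat, traj_t.mu1hat,
                                np.ones(len(out)), responder, "spatial")
    p1_t = response_probability(traj_t.mu1hat, traj_s.mu1hat,
                                np.ones(len(out)), responder, "temporal")
    draws = rng.random(len(out))
    y_s = (draws < p1_s).astype(float)
    y_t = (draws < p1_t).astype(float)
    out.loc[is_spatial, "y_s"] = y_s[is_spatial]
    out.loc[~is_spatial, "y_t"] = y_t[~is_spatial]
    if rt_lognormal is not None:
        mu, sd = rt_lognormal
        out["rt"] = rng.lognormal(mu, sd, len(out))
    return out


def simulate_session(observer: ObserverParams, responder: ResponseParams,
                     cfg: SessionConfig | None = None, seed: int = 0,
                     schedule: ContingencySchedule | None = None,
                     rt_lognormal: tuple[float, float] | None = None) -> pd.DataFrame:
    """Generate a full session and simulate one agent on it.

    Schedule generation, trial generation and response sampling use separate
    seeds spawned from ``seed`` so that agents can be re-simulated on a fixed
    schedule.
    """
    cfg = cfg or SessionConfig()
    s_sched, s_trials, s_resp = np.random.SeedSequence(seed).generate_state(3)
    if schedule is None:
        schedule = generate_validity_schedule(cfg, seed=int(s_sched) % 2**31)
    trials = generate_trials(schedule, cfg, seed=int(s_trials) % 2**31)
    return simulate_agent(trials, observer, responder,
                          seed=int(s_resp) % 2**31, rt_lognormal=rt_lognormal)


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    return pd.read_csv(path)
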