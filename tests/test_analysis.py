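"""Behavioural filters, condition tables and regressor extraction."""

import numpy as np
import pandas as pd
import pytest

import hgfcue as hc


def _toy_trials(rts, tasks=None):
    n = len(rts)
    tasks = tasks or ["spatial"] * n
    return pd.DataFrame({
        "trial": np.arange(n), "block": 0, "task": tasks,
        "u_s": 1, "u_t": 0, "validity_s": 0.9, "validity_t": 0.5,
        "y_s": [1.0 if t == "spatial" else np.nan for t in tasks],
        "y_t": [0.0 if t == "temporal" else np.nan for t in tasks],
        "rt": rts,
    })


class TestRtFilter:
    def test_toy_list_all_retained(self):
        # median 0.55, sample SD 1.2527, cutoff 3.055 > 3.0
        trials = _toy_trials([0.4, 0.5, 0.6, 3.0])
        assert len(hc.filter_trials(trials)) == 4

    def test_clear_outlier_removed(self):
        trials = _toy_trials([0.4, 0.45, 0.5, 0.55, 0.5, 0.6, 9.0])
        kept = hc.filter_trials(trials)
        assert len(kept) == 6 and 9.0 not in kept["rt"].to_numpy()

    def test_identical_rts_retained_by_strict_inequality(self):
        trials = _toy_trials([0.5] * 6)
        assert len(hc.filter_trials(trials)) == 6

    def test_empty_input_passes_through(self):
        trials = _toy_trials([])
        assert len(hc.filter_trials(trials)) == 0

    def test_missing_rts_untouched(self):
        trials = _toy_trials([0.4, np.nan, 0.5, 0.6, np.nan])
        assert len(hc.filter_trials(trials)) == 5

    def test_commutes_with_stable_half_marking(self, reference_agent):
        trials, observer, responder = reference_agent
        trials = hc.simulate_agent(trials, observer, responder, seed=3,
                                   rt_lognormal=(-0.5, 0.4))
        sched = hc.default_schedule()
        a = hc.filter_trials(hc.stable_second_half(trials, sched))
        b = hc.stable_second_half(hc.filter_trials(trials), sched)
        pd.testing.assert_frame_equal(a.reset_index(drop=True),
                                      b.reset_index(drop=True))


class TestStableSecondHalf:
    def _sched(self, lengths, levels):
        v = np.concatenate([np.full(l, lv) for l, lv in zip(lengths, levels)])
        return hc.ContingencySchedule(v, np.full(len(v), 0.5))

    def test_even_run_keeps_later_half(self):
        sched = self._sched([10], [0.9])
        trials = _toy_trials([np.nan] * 10)
        marked = hc.stable_second_half(trials, sched)
        np.testing.assert_array_equal(
            marked["stable_s"], [False] * 5 + [True] * 5)

    def test_length_one_run_contributes_nothing(self):
        sched = self._sched([1, 9], [0.9, 0.5])
        trials = _toy_trials([np.nan] * 10)
        marked = hc.stable_second_half(trials, sched)
        assert not marked["stable_s"].iloc[0]

    def test_toy_schedule_matches_brute_force(self):
        lengths, levels = [3, 5, 4, 7], [0.9, 0.3, 0.7, 0.1]
        sched = self._sched(lengths, levels)
        trials = _toy_trials([np.nan] * sum(lengths))
        marked = hc.stable_second_half(trials, sched)
        expected = []
        for L in lengths:
            half = int(np.ceil(L / 2))
            expected += [i >= half for i in range(L)]
        np.testing.assert_array_equal(marked["stable_s"], expected)

    def test_dimensions_marked_independently(self):
        v_s = np.concatenate([np.full(6, 0.9), np.full(6, 0.3)])
        v_t = np.full(12, 0.5)
        sched = hc.ContingencySchedule(v_s, v_t)
        trials = _toy_trials([np.nan] * 12)
        marked = hc.stable_second_half(trials, sched)
        assert marked["stable_s"].sum() == 6   # two runs of 6 -> 3 + 3
        assert marked["stable_t"].sum() == 6   # one run of 12 -> last 6


class TestAccuracyTable:
    def _session(self, responder, seed=0):
        observer, _ = hc.unpack_params(hc.GENERATING_MODEL, hc.REFERENCE_PARAMS)
        trials = hc.simulate_session(observer, responder, seed=seed,
                                     schedule=hc.default_schedule())
        return hc.stable_second_half(trials, hc.default_schedule())

    def test_perfect_responder_hits_ceiling(self):
        trials = self._session(hc.ResponseParams(variant="task_specific"))
        trials["y_s"] = np.where(trials["task"] == "spatial",
                                 trials["u_s"].astype(float), np.nan)
        trials["y_t"] = np.where(trials["task"] == "temporal",
                                 trials["u_t"].astype(float), np.nan)
        table = hc.accuracy_table(trials)
        filled = table[table["n_trials"] > 0]
        assert (filled["accuracy"] == 1.0).all()

    def test_coin_flip_responder_near_chance(self):
        responder = hc.ResponseParams(variant="task_specific",
                                      zeta_s_rel=0.0, zeta_t_rel=0.0)
        tables = [hc.accuracy_table(self._session(responder, seed=s))
                  for s in range(3)]
        acc = pd.concat(tables).groupby(level=0)["accuracy"].mean()
        pooled = pd.concat(tables)
        w = pooled["n_trials"]
        overall = (pooled["accuracy"] * w).sum() / w.sum()
        assert abs(overall - 0.5) < 0.03

    def test_predictability_by_relevance_interaction(self):
        # a sharp cue-follower profits from predictability only in the
        # relevant context
        responder = hc.ResponseParams(variant="task_specific",
                                      zeta_s_rel=8.0, zeta_t_rel=8.0)
        tables = pd.concat([hc.accuracy_table(self._session(responder, seed=s))
                            for s in (11, 12, 13)])
        cell = tables.groupby(["predictability", "relevance"]).apply(
            lambda d: (d["accuracy"] * d["n_trials"]).sum() / d["n_trials"].sum(),
            include_groups=False)
        assert cell["strong", "relevant"] > cell["unpredictable", "relevant"] + 0.1
        assert abs(cell["strong", "irrelevant"]
                   - cell["unpredictable", "irrelevant"]) < 0.1

    def test_empty_cells_flagged_not_zero(self):
        trials = _toy_trials([0.4, 0.5])
        trials["stable_s"] = True
        trials["stable_t"] = True
        table = hc.accuracy_table(trials)
        empty = table[table["n_trials"] == 0]
        assert len(empty) > 0 and empty["accuracy"].isna().all()


class TestRegressors:
    def test_zero_beliefs_give_zero_prediction_regressor(self, reference_agent):
        trials, *_ = reference_agent
        n = len(trials)
        z = np.zeros(n)
        traj = hc.BeliefTrajectory("spatial", mu1hat=z + 0.5, delta1=z,
                                   mu2hat=z, eps2=z)
        regs = hc.extract_regressors(traj, traj, trials)
        assert (regs["pred_s_rel"] == 0).all()
        assert (regs["pred_s_irrel"] == 0).all()

    def test_disjoint_relevance_split(self, reference_trajectories):
        trials, traj_s, traj_t = reference_trajectories
        regs = hc.extract_regressors(traj_s, traj_t, trials)
        assert (regs["pred_s_rel"] * regs["pred_s_irrel"] == 0).all()
        rel_mask = (trials["task"] == "spatial").to_numpy()
        assert np.all(regs["pred_s_rel"].to_numpy()[rel_mask]
                      == np.abs(traj_s.mu2hat[rel_mask]))
        assert (regs.drop(columns="trial") >= 0).all().all()

    def test_signed_variant_is_antisymmetric(self, reference_agent):
        trials, observer, _ = reference_agent
        flipped = trials.copy()
        flipped["u_s"] = 1 - flipped["u_s"]
        flipped["u_t"] = 1 - flipped["u_t"]
        a_s, a_t = (hc.hgf_filter(trials, observer, d)
                    for d in ("spatial", "temporal"))
        b_s, b_t = (hc.hgf_filter(flipped, observer, d)
                    for d in ("spatial", "temporal"))
        ra = hc.extract_regressors(a_s, a_t, trials, signed=True)
        rb = hc.extract_regressors(b_s, b_t, flipped, signed=True)
        np.testing.assert_allclose(rb["pe_s_rel"], -ra["pe_s_rel"], atol=1e-10)

    def test_misalignment_rejected(self, reference_trajectories):
        trials, traj_s, traj_t = reference_trajectories
        with pytest.raises(ValueError):
            hc.extract_regressors(traj_s, traj_t, trials.iloc[:-1])

    def test_correlation_matrix_structure(self, reference_trajectories):
        trials, traj_s, traj_t = reference_trajectories
        regs = hc.extract_regressors(traj_s, traj_t, trials)
        corr = hc.regressor_correlations(regs)
        np.testing.assert_allclose(corr, corr.T)
        np.testing.assert_allclose(np.diag(corr), 1.0)

    def test_white_noise_regressors_uncorrelated(self):
        rng = np.random.default_rng(0)
        regs = pd.DataFrame(rng.normal(size=(5000, 4)),
                            columns=list("abcd"))
        corr = hc.regressor_correlations(regs, center=False)
        off = corr.to_numpy()[np.triu_indices(4, 1)]
        assert np.max(np.abs(off)) < 0.05

    def test_constant_regressor_flagged_nan(self):
        regs = pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)})
        corr = hc.regressor_correlations(regs, center=True)
        assert np.isnan(corr.loc["a", "b"])
        assert corr.loc["b", "b"] == 1.0


class TestGroupUtilities:
    def test_rm_anova_detects_strong_interaction(self):
        rng = np.random.default_rng(5)
        rows = []
        for subj in range(12):
            for pred, base in (("strong", 0.9), ("weak", 0.7),
                               ("unpredictable", 0.5)):
                for rel in ("relevant", "irrelevant"):
                    acc = (base if rel == "relevant" else 0.5)
                    rows.append({"subject": subj, "predictability": pred,
                                 "relevance": rel,
                                 "accuracy": acc + rng.normal(0, 0.02)})
        table = hc.predictability_anova(pd.DataFrame(rows))
        inter = table.loc["predictability:relevance"]
        assert inter["Pr > F"] < 0.001

    def test_parameter_accuracy_correlation_report(self):
        rng = np.random.default_rng(6)
        acc = rng.uniform(0.5, 0.9, 20)
        params = pd.DataFrame({
            "informative": acc + rng.normal(0, 0.02, 20),
            "noise": rng.normal(size=20),
        })
        rep = hc.parameter_accuracy_correlation(params, acc)
        r_inf = rep.loc[rep["parameter"] == "informative", "r"].item()
        p_inf = rep.loc[rep["parameter"] == "informative", "p"].item()
        assert r_inf > 0.9 and p_inf < 1e-6
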