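import numpy as np
import pytest

import hgfcue as hc


@pytest.fixture(scope="session")
def default_cfg():
    return hc.SessionConfig()


@pytest.fixture(scope="session")
def small_cfg():
    # 4 alternating blocks, 160 trials: enough structure for fast fits
    return hc.SessionConfig(n_blocks=4, mean_block_len=40,
                            block_len_range=(30, 50), rng_seed=11)


@pytest.fixture(scope="session")
def reference_agent():
    """One 960-trial session simulated from the winning reference model."""
    observer, responder = hc.unpack_params(hc.GENERATING_MODEL,
                                           hc.REFERENCE_PARAMS)
    trials = hc.simulate_session(observer, responder, seed=42)
    return trials, observer, responder


@pytest.fixture(scope="session")
def reference_trajectories(reference_agent):
    trials, observer, _ = reference_agent
    traj_s = hc.hgf_filter(trials, observer, "spatial")
    traj_t = hc.hgf_filter(trials, observer, "temporal")
    return trials, traj_s, traj_t


@pytest.fixture(scope="session")
def constant_validity_trials():
    """Long constant-validity session (0.9 / 0.5) for convergence checks."""
    cfg = hc.SessionConfig(n_blocks=20, mean_block_len=48)
    n = cfg.n_trials
    sched = hc.ContingencySchedule(np.full(n, 0.9), np.full(n, 0.5))
    return hc.generate_trials(sched, cfg, seed=7), sched
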