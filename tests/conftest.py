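import numpy as np
import pytest

from fnirs_nfb.design import SessionConfig, build_schedule
from fnirs_nfb.online import ThresholdState, run_closed_loop
from fnirs_nfb.simulate import default_scenario, simulate_recording


@pytest.fixture(scope="session")
def full_schedule():
    """Full 12-run training schedule (2+4+4+2 runs over four days)."""
    return build_schedule(SessionConfig(), seed=0)


@pytest.fixture(scope="session")
def short_schedule():
    """Two-run training used where a full session is unnecessary."""
    return build_schedule(SessionConfig(runs_per_day=(1, 1)), seed=0)


@pytest.fixture(scope="session")
def up_session(full_schedule):
    """One upregulation participant: recording, ground truth, traces, log."""
    scenario = default_scenario("up", seed=7, channels_per_hemisphere=1)
    rec, truth = simulate_recording(full_schedule, scenario)
    traces, state, log = run_closed_loop(rec, full_schedule, "up",
                                         ThresholdState(T=2.0))
    return {"recording": rec, "truth": truth, "traces": traces,
            "state": state, "log": log, "schedule": full_schedule}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
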