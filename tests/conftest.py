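import numpy as np
import pytest

import mtlength as mt


@pytest.fixture(scope="session")
def default_params() -> mt.SimulationParams:
    return mt.make_params(seed=1)


@pytest.fixture(scope="session")
def long_default_traj(default_params) -> mt.CellTrajectory:
    """One long run at published defaults, shared by steady-state tests."""
    return mt.simulate(default_params, 10_000.0)


@pytest.fixture(scope="session")
def long_default_summary(long_default_traj) -> mt.SteadyStateSummary:
    return mt.summarize(long_default_traj, burn_in=500.0)
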