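"""Shared fixtures: expensive SSA ensembles are built once per session."""

from __future__ import annotations

import numpy as np
import pytest

import cole2sim as c


@pytest.fixture(scope="session")
def default_params() -> c.RegulationParameters:
    return c.RegulationParameters()


@pytest.fixture(scope="session")
def default_sos() -> c.SOSParameters:
    return c.SOSParameters()


@pytest.fixture(scope="session")
def sos_ensemble(default_params, default_sos) -> c.EnsembleResult:
    """Standard SOS protocol (c_p 0->6 at t=200, off at t=500), 120 cells."""
    return c.run_sos_ensemble(
        default_params, default_sos, c.SignalSchedule(),
        t_max=700.0, n_realizations=120, base_seed=1234,
    )


@pytest.fixture(scope="session")
def sos_deterministic(default_params, default_sos) -> c.Trajectory:
    return c.run_sos_deterministic(default_params, default_sos, c.SignalSchedule(),
                                   t_max=700.0)


@pytest.fixture(scope="session")
def lysis_stats(sos_ensemble) -> c.LysisStatistics:
    return c.lysis_time_distribution(sos_ensemble)


@pytest.fixture(scope="session")
def uninduced_ensemble(default_params, default_sos) -> c.EnsembleResult:
    """No stress at all: 500 cells for 200 min at c_p = 0."""
    return c.run_sos_ensemble(
        default_params, default_sos, c.SignalSchedule(((0.0, 0.0),)),
        t_max=200.0, n_realizations=500, base_seed=77,
    )
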