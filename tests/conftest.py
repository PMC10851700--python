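"""Shared fixtures: one calibrated stimulus set and simulated sessions.

Everything is generated at test time from fixed seeds; the expensive
fixtures are session-scoped so the suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from kinecode import (
    DesignSpec,
    make_design,
    make_stimulus_set,
    observer_preset,
    sessions_frame,
    simulate_cohort,
    simulate_observer,
)


@pytest.fixture(scope="session")
def stim():
    return make_stimulus_set(seed=0)


@pytest.fixture(scope="session")
def design(stim):
    return make_design(DesignSpec(seed=1), stim)


@pytest.fixture(scope="session")
def control_session(stim, design):
    profile = observer_preset("control", stim)
    return simulate_observer(profile, design, stim, seed=11,
                             observer_id="c01")


@pytest.fixture(scope="session")
def patient_session(stim, design):
    profile = observer_preset("patient", stim)
    return simulate_observer(profile, design, stim, seed=12,
                             observer_id="p01")


@pytest.fixture(scope="session")
def cohort_frame(stim):
    """16 + 16 observer cohort as one tidy trial table."""
    sessions = simulate_cohort(stim, DesignSpec(), n_control=16, n_patient=16,
                               seed=2024)
    return sessions_frame(sessions)


@pytest.fixture(scope="session")
def small_cohort_frame(stim):
    """6 + 6 observer cohort for the cheaper model-based tests."""
    sessions = simulate_cohort(stim, DesignSpec(), n_control=6, n_patient=6,
                               seed=77)
    return sessions_frame(sessions)
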