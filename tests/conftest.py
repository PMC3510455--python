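"""Shared fixtures: the expensive simulated objects are session-scoped so
the calibration surface and the pooled HMM run are built once."""

import numpy as np
import pytest

from slidefret import (FilamentGeometry, FretCoupling, SlideSimConfig,
                       StateModel, build_calibration_table, fit_hmm, idealize,
                       simulate_state_traces)

PAPER_D_GRID = (0.09e-3, 0.9e-3, 9e-3)
PAPER_LENGTHS = (21, 39, 69, 99)


@pytest.fixture(scope="session")
def calibration_table():
    """tau(D, L) surface at the 30-molecule calibration budget."""
    return build_calibration_table(PAPER_D_GRID, PAPER_LENGTHS,
                                   n_reps=30, seed=42)


@pytest.fixture(scope="session")
def state_run():
    """Three-state traces, pooled HMM fit and idealizations (200 molecules)."""
    model = StateModel(seed=11)
    traces, truths = simulate_state_traces(model, 200, 2000, seed=11)
    hmm = fit_hmm(traces, n_states=3, seed=0)
    ideals = [idealize(hmm, t, min_dwell=2) for t in traces]
    return {"model": model, "traces": traces, "truths": truths,
            "hmm": hmm, "ideals": ideals}


@pytest.fixture
def default_geometry():
    return FilamentGeometry(filament_length=99, duplex_length=39)
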