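"""Shared fixtures: steady states are expensive, so the commonly reused ones
are computed once per session."""

import pytest

import betacell as bc


@pytest.fixture(scope="session")
def params():
    return bc.load_parameters()


@pytest.fixture(scope="session")
def ctx(params):
    return bc.UnitContext.from_parameters(params)


@pytest.fixture(scope="session")
def basal_ss(params):
    """Steady state at 3 mM glucose, basal ligands."""
    ss = bc.find_steady_state(params, {"Glu": 3000.0})
    assert ss.converged
    return ss


@pytest.fixture(scope="session")
def high_glucose_ss(params, basal_ss):
    """Steady state at 8 mM glucose, basal ligands."""
    ss = bc.find_steady_state(params, {"Glu": 8000.0},
                              from_state=basal_ss.state)
    assert ss.converged
    return ss


@pytest.fixture(scope="session")
def glp1_ss(params, high_glucose_ss):
    """Steady state at 8 mM glucose after GLP-1 stimulation."""
    ss = bc.find_steady_state(params, {"Glu": 8000.0, "GLP1": 6.2e-4},
                              from_state=high_glucose_ss.state)
    assert ss.converged
    return ss
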