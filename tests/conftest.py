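import numpy as np
import pytest

import atriomech as am
from atriomech.model import CellModel, SolverOptions


@pytest.fixture(scope="session")
def sr_params():
    return am.default_parameters()


@pytest.fixture(scope="session")
def sr_model(sr_params):
    return CellModel(sr_params, solver=SolverOptions(dt_out=0.25))


@pytest.fixture(scope="session")
def sr_state():
    return am.initial_state("SR")


@pytest.fixture(scope="session")
def af_state():
    return am.initial_state("AF")


@pytest.fixture(scope="session")
def paced_trace(sr_model, sr_state):
    """Six steady beats at 1 Hz with currents, shared by property tests."""
    _, y = sr_model.pace(sr_state, 1000.0, 30, record_last=1,
                         with_currents=False)
    tr, yf = sr_model.pace(y, 1000.0, 6, with_currents=True)
    return tr, yf


@pytest.fixture(scope="session")
def fine_beat(sr_model, sr_state):
    """One steady-state beat sampled at 0.1 ms (charge/mass audits)."""
    _, y = sr_model.pace(sr_state, 1000.0, 30, record_last=1,
                         with_currents=False)
    opts = SolverOptions(dt_out=0.1)
    tr, yf = sr_model.pace(y, 1000.0, 1, with_currents=True, solver=opts)
    return tr, y, yf
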