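"""Condition initial states.

Quasi-steady paced states for each condition (SR, AF, AF case 1, AF case 2)
are shipped with the package and regenerable with `regenerate_initial_state`
(the pacing used to produce them is recorded alongside).
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from ._layout import (
    NSTATE, STATE_NAMES,
    S_V, S_M, S_H, S_J, S_F, S_FCA, S_ITO, S_IUR, S_CSS, S_ASS, S_CBC,
    S_ABC, S_CASS, S_CABC, S_CASRSS, S_CASRBC, S_NAI, S_KI, S_CAMK,
    S_CATNC, S_XD, S_SL,
)

CONDITIONS = ("SR", "AF", "AF_case1", "AF_case2")

_STATE_FILE = "initial_states.json"


def bootstrap_state() -> "StateVector":
    """A crude resting guess used only to seed state regeneration."""
    from .model import StateVector
    y = np.zeros(NSTATE)
    y[S_V] = -75.0
    y[S_M] = 0.003
    y[S_H] = 0.9
    y[S_J] = 0.9
    y[S_F] = 1.0
    y[S_FCA] = 0.8
    y[S_ITO] = 1.0
    y[S_IUR] = 1.0
    y[S_CSS] = 1.0
    y[S_ASS] = 0.12
    y[S_CBC] = 1.0
    y[S_ABC] = 0.12
    y[S_CASS] = 0.15
    y[S_CABC] = 0.15
    y[S_CASRSS] = 0.6
    y[S_CASRBC] = 0.6
    y[S_NAI] = 7.0
    y[S_KI] = 140.0
    y[S_CAMK] = 0.002
    y[S_CATNC] = 15.0
    y[S_XD] = 0.01
    y[S_SL] = 2.2
    return StateVector(y)


def _load_states() -> dict:
    with resources.files("atriomech.data").joinpath(_STATE_FILE).open() as f:
        return json.load(f)


def initial_state(condition: str = "SR"):
    """Stored quasi-steady state for a condition label.

    Raises KeyError for unknown labels.  The returned state satisfies the
    state-vector invariants and was produced by pacing the corresponding
    parameter set at the BCL recorded in the shipped metadata.
    """
    from .model import StateVector
    if condition not in CONDITIONS:
        raise KeyError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    entry = _load_states()[condition]
    return StateVector(np.array(entry["state"], dtype=float))


def initial_state_metadata(condition: str) -> dict:
    """Pacing provenance (bcl, beat count) of the stored state."""
    entry = _load_states()[condition]
    return {k: v for k, v in entry.items() if k != "state"}


def condition_parameters(condition: str):
    """ParameterSet for a condition label (SR defaults + AF remodeling)."""
    from .interventions import RemodelingSpec, apply_af_remodeling
    from .parameters import default_parameters
    if condition not in CONDITIONS:
        raise KeyError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    p = default_parameters()
    if condition == "SR":
        return p
    spec = RemodelingSpec(
        case1_no_tnc_remodeling=(condition == "AF_case1"),
        case2_ikur_reversed=(condition == "AF_case2"),
    )
    return apply_af_remodeling(p, spec)


def regenerate_initial_state(condition: str, bcl: float = 1000.0,
                             n_beats: int = 300):
    """Recompute a condition's quasi-steady state by pacing from bootstrap.

    Returns (StateVector, metadata dict).  Used by the shipped-state
    generation script; slow.
    """
    from .model import CellModel
    model = CellModel(condition_parameters(condition))
    state, n, converged = model.pace_to_steady_state(
        bootstrap_state(), bcl, max_beats=n_beats)
    meta = {"bcl_ms": bcl, "n_beats": n, "converged": bool(converged),
            "state_names": STATE_NAMES}
    return state, meta
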