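"""The coupled electromechanical cell model and its integration.

`CellModel` bundles a `ParameterSet` with optional run-time modifiers (a
current clamp replacing ICaL or IKr by a recorded waveform) and exposes
`derivatives`, `currents`, `integrate` and `pace`.  Integration uses a
stiff-capable adaptive solver (LSODA) with fixed output sampling, so runs
are deterministic given fixed solver options.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import odeint

from . import _kernels
from ._layout import (
    NSTATE, NCURRENT, STATE_NAMES, STATE_UNITS, CURRENT_NAMES, CURRENT_UNITS,
    S_V, GATE_INDICES, CONC_INDICES,
)
from ._kernels import CLAMP_NONE, CLAMP_ICAL, CLAMP_IKR
from .parameters import ParameterSet
from .trace import Trace, concat


class SolverError(RuntimeError):
    """Integration failure; carries the last accepted time and state."""

    def __init__(self, message, t_last=None, state_last=None):
        super().__init__(message)
        self.t_last = t_last
        self.state_last = state_last


@dataclass(frozen=True)
class SolverOptions:
    """Adaptive stiff-solver configuration.

    `atol_scale` multiplies per-state characteristic magnitudes to build the
    absolute tolerance vector; `dt_out` is the fixed output sampling step.
    """

    rtol: float = 1e-6
    atol_scale: float = 1e-8
    max_step: float = 1.0     # ms
    dt_out: float = 0.1       # ms
    method: str = "LSODA"

    def atol_vector(self) -> np.ndarray:
        scale = np.ones(NSTATE)
        scale[S_V] = 100.0
        for i in CONC_INDICES:
            scale[i] = 10.0
        return self.atol_scale * scale


@dataclass(frozen=True)
class ChannelClamp:
    """Replace a channel's current with a periodically tiled waveform.

    `t` (ms, starting at 0) and `i` (A/F) describe one steady-state beat;
    the waveform repeats with period `bcl`.
    """

    channel: str              # "ICaL" or "IKr"
    t: np.ndarray
    i: np.ndarray
    bcl: float

    def __post_init__(self):
        if self.channel not in ("ICaL", "IKr"):
            raise ValueError("clampable channels are 'ICaL' and 'IKr'")
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "i", np.asarray(self.i, dtype=float))
        if self.t.shape != self.i.shape or self.t.ndim != 1:
            raise ValueError("clamp waveform arrays must be 1-d, same length")
        if self.t[-1] < self.bcl - 1e-6:
            # waveform must cover one full period for interpolation
            raise ValueError("clamp waveform shorter than its period")

    @property
    def mode(self) -> int:
        return CLAMP_ICAL if self.channel == "ICaL" else CLAMP_IKR


def _clamp_args(clamp: Optional[ChannelClamp]):
    if clamp is None:
        return CLAMP_NONE, _kernels._EMPTY, _kernels._EMPTY, 1.0
    return clamp.mode, clamp.t, clamp.i, float(clamp.bcl)


# ---------------------------------------------------------------------------
# state utilities
# ---------------------------------------------------------------------------
class StateVector:
    """Named view over the flat model state (see `_layout.STATE_NAMES`)."""

    __slots__ = ("values",)

    def __init__(self, values):
        arr = np.asarray(values, dtype=float).copy()
        if arr.shape != (NSTATE,):
            raise ValueError(f"state must have length {NSTATE}")
        self.values = arr

    def __getattr__(self, name):
        try:
            return self.values[STATE_NAMES.index(name)]
        except ValueError:
            raise AttributeError(name) from None

    def __getitem__(self, name):
        return self.values[STATE_NAMES.index(name)]

    def as_dict(self) -> dict:
        return dict(zip(STATE_NAMES, self.values.tolist()))

    def copy(self) -> "StateVector":
        return StateVector(self.values)

    def check_invariants(self, tol: float = 1e-6) -> None:
        """Gates within [0,1]; concentrations positive; RU occupancies sum to 1."""
        for i in GATE_INDICES:
            v = self.values[i]
            if not (-tol <= v <= 1.0 + tol):
                raise ValueError(
                    f"gate {STATE_NAMES[i]} = {v} outside [0, 1]")
        for i in CONC_INDICES:
            if not self.values[i] > 0:
                raise ValueError(
                    f"concentration {STATE_NAMES[i]} must be positive")
        p = self["RU_perm"]
        if not (-tol <= p <= 1.0 + tol):
            raise ValueError("RU occupancy fractions must lie in [0, 1]")

    @property
    def ru_occupancies(self) -> np.ndarray:
        """Non-permissive / permissive regulatory-unit occupancy."""
        p = self["RU_perm"]
        return np.array([1.0 - p, p])


def _first_nonfinite(values: np.ndarray) -> Optional[str]:
    bad = ~np.isfinite(values)
    if bad.any():
        return STATE_NAMES[int(np.argmax(bad))]
    return None


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------
@dataclass
class CellModel:
    """Parameterized cell with optional channel clamp."""

    params: ParameterSet
    clamp: Optional[ChannelClamp] = None
    solver: SolverOptions = field(default_factory=SolverOptions)

    def with_params(self, params: ParameterSet) -> "CellModel":
        return replace(self, params=params)

    def with_clamp(self, clamp: Optional[ChannelClamp]) -> "CellModel":
        return replace(self, clamp=clamp)

    # -- pointwise API ----------------------------------------------------
    def derivatives(self, state, t: float = 0.0,
                    i_stim: float = 0.0) -> np.ndarray:
        """Time derivative of every state field (see class docstring)."""
        y = state.values if isinstance(state, StateVector) else \
            np.asarray(state, dtype=float)
        bad = _first_nonfinite(y)
        if bad is not None:
            raise ValueError(f"non-finite state field: {bad}")
        mode, ct, ci, per = _clamp_args(self.clamp)
        return _kernels.rhs_only(t, y, self.params.to_array(), i_stim,
                                 mode, ct, ci, per)

    def currents(self, state, t: float = 0.0) -> dict:
        """All sarcolemmal currents (A/F), Ca fluxes (uM/ms) and Ta (kPa)."""
        y = state.values if isinstance(state, StateVector) else \
            np.asarray(state, dtype=float)
        mode, ct, ci, per = _clamp_args(self.clamp)
        buf = np.empty(NCURRENT)
        _kernels.rhs(t, y, self.params.to_array(), 0.0, mode, ct, ci, per,
                     buf)
        return dict(zip(CURRENT_NAMES, buf.tolist()))

    # -- integration -------------------------------------------------------
    def integrate(self, state, duration: float,
                  stim_times: Sequence[float] = (),
                  record: bool = True,
                  with_currents: bool = True,
                  t0: float = 0.0,
                  solver: Optional[SolverOptions] = None):
        """Integrate for `duration` ms, stimulating at `stim_times`.

        Returns (Trace, final StateVector).  With record=False only the
        final state is kept (fast conditioning runs).
        """
        opts = solver or self.solver
        y0 = state.values if isinstance(state, StateVector) else \
            np.asarray(state, dtype=float)
        bad = _first_nonfinite(y0)
        if bad is not None:
            raise ValueError(f"non-finite state field: {bad}")
        if duration < 0:
            raise ValueError("duration must be >= 0")
        P = self.params.to_array()
        mode, ct, ci, per = _clamp_args(self.clamp)
        amp, dur = self.params.stim_amp, self.params.stim_dur

        t_end = t0 + duration
        if duration == 0:
            tr = self._make_trace(np.array([t0]), y0[None, :],
                                  np.asarray(stim_times, dtype=float),
                                  P, mode, ct, ci, per, with_currents)
            return tr, StateVector(y0)

        # segment boundaries at stimulus edges so pulses are never skipped
        edges = {t0, t_end}
        stims = sorted(float(s) for s in stim_times
                       if t0 - 1e-9 <= s < t_end)
        for s in stims:
            edges.add(s)
            edges.add(min(s + dur, t_end))
        edges = sorted(edges)

        atol = opts.atol_vector()

        def f(y, t, istim):
            return _kernels.rhs_only(t, y, P, istim, mode, ct, ci, per)

        ts_out, ys_out = [], []
        y = y0.copy()
        for a, b in zip(edges[:-1], edges[1:]):
            if b - a <= 1e-12:
                continue
            stim_on = any(s <= a + 1e-9 < s + dur for s in stims)
            istim = amp if stim_on else 0.0
            if record:
                # global output grid at multiples of dt_out
                k0 = int(np.ceil((a - t0) / opts.dt_out - 1e-9))
                k1 = int(np.floor((b - t0) / opts.dt_out + 1e-9))
                t_eval = t0 + np.arange(k0, k1 + 1) * opts.dt_out
                t_eval = t_eval[(t_eval > a + 1e-9) & (t_eval < b - 1e-9)]
                t_eval = np.concatenate([[a], t_eval, [b]])
            else:
                t_eval = np.array([a, b])
            hmax = min(opts.max_step, b - a) if stim_on else opts.max_step
            out, info = odeint(
                f, y, t_eval, args=(istim,), rtol=opts.rtol, atol=atol,
                hmax=hmax, mxstep=100000, full_output=True,
                tfirst=False, printmessg=False)
            if info["message"] != "Integration successful.":
                n_ok = int(np.sum(np.isfinite(out).all(axis=1)))
                t_last = t_eval[max(n_ok - 1, 0)]
                raise SolverError(
                    f"integration failed at t={t_last:.3f} ms: "
                    f"{info['message']}",
                    t_last=t_last,
                    state_last=StateVector(out[max(n_ok - 1, 0)]))
            if record:
                # keep only on-grid samples so the output stays uniform
                frac = (t_eval[:-1] - t0) / opts.dt_out
                on_grid = np.abs(frac - np.round(frac)) < 1e-6
                ts_out.append(t_eval[:-1][on_grid])
                ys_out.append(out[:-1][on_grid])
            y = out[-1].copy()
        if record:
            ts_out.append(np.array([t_end]))
            ys_out.append(y[None, :])

        if record and ts_out:
            ts = np.concatenate(ts_out)
            ys = np.concatenate(ys_out, axis=0)
            keep = np.concatenate([[True], np.diff(ts) > 1e-9])
            ts, ys = ts[keep], ys[keep]
        else:
            ts = np.array([t_end])
            ys = y[None, :]
        tr = self._make_trace(ts, ys, np.asarray(stims, dtype=float),
                              P, mode, ct, ci, per, with_currents)
        return tr, StateVector(y)

    def _make_trace(self, ts, ys, stims, P, mode, ct, ci, per,
                    with_currents) -> Trace:
        data = {name: ys[:, k] for k, name in enumerate(STATE_NAMES)}
        units = dict(zip(STATE_NAMES, STATE_UNITS))
        if with_currents:
            cur = _kernels.currents_matrix(ts, ys, P, mode, ct, ci, per)
            for k, name in enumerate(CURRENT_NAMES):
                data[name] = cur[:, k]
            units.update(zip(CURRENT_NAMES, CURRENT_UNITS))
        return Trace(ts, data, units, stims)

    def pace(self, state, bcl: float, n_beats: int,
             record_last: Optional[int] = None,
             with_currents: bool = True,
             t0: float = 0.0,
             solver: Optional[SolverOptions] = None):
        """Deliver `n_beats` stimuli at interval `bcl` ms.

        Records the last `record_last` beats (all by default).  Returns
        (Trace, final StateVector); the trace time axis is global, and the
        stimulus times mark beat boundaries for per-beat analysis.
        """
        if bcl <= self.params.stim_dur:
            raise ValueError("bcl must exceed the stimulus duration")
        if n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if record_last is None:
            record_last = n_beats
        record_last = min(record_last, n_beats)
        n_skip = n_beats - record_last

        y = state
        traces = []
        if n_skip:
            _, y = self.integrate(y, n_skip * bcl,
                                  stim_times=np.arange(n_skip) * bcl + t0,
                                  record=False, t0=t0, solver=solver)
        t_rec = t0 + n_skip * bcl
        tr, y = self.integrate(
            y, record_last * bcl,
            stim_times=t_rec + np.arange(record_last) * bcl,
            record=True, with_currents=with_currents, t0=t_rec,
            solver=solver)
        traces.append(tr)
        return concat(traces) if len(traces) > 1 else traces[0], y

    def pace_to_steady_state(self, state, bcl: float,
                             max_beats: int = 500,
                             rel_tol: float = 1e-4,
                             check_every: int = 10,
                             solver: Optional[SolverOptions] = None):
        """Pace until the per-beat relative state change falls below rel_tol.

        Returns (final StateVector, n_beats_used, converged).
        """
        y = state.values if isinstance(state, StateVector) else \
            np.asarray(state, dtype=float)
        scale = np.maximum(np.abs(y), 1e-3)
        n = 0
        converged = False
        prev = y.copy()
        while n < max_beats:
            k = min(check_every, max_beats - n)
            _, s = self.integrate(StateVector(y), k * bcl,
                                  stim_times=np.arange(k) * bcl,
                                  record=False, solver=solver)
            y = s.values
            n += k
            delta = np.max(np.abs(y - prev) / scale) / k
            if delta < rel_tol:
                converged = True
                break
            prev = y.copy()
        return StateVector(y), n, converged
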