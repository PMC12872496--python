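"""Experiment orchestration: rate-dependence scans, conductance-scan
vulnerability maps, rapid-pace-pause afterdepolarization protocols,
phase-3 EAD induction, clamp dissection and myofilament sweeps.

Every protocol returns a `ProtocolResult` carrying an ordered intervention
manifest, the recorded trace, per-beat analyses and summary biomarkers, so
a run can be replayed exactly from its manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import biomarkers as bm
from .biomarkers import BiomarkerConfig, analyze_beats, aggregate_label
from .interventions import (DrugSpec, apply_drug, apply_phase3_ina_mods,
                            enable_ikach, scale_conductances)
from .model import CellModel, SolverOptions, StateVector
from .parameters import ParameterSet
from .state import condition_parameters, initial_state
from .trace import Trace, concat

# the pacing intervals of the rate-dependence analysis (ms)
DEFAULT_BCL_LIST = (2000.0, 1000.0, 500.0, 330.0, 250.0, 200.0, 180.0)


@dataclass
class ProtocolResult:
    """Outcome of one protocol run."""

    condition: str
    manifest: List[str]
    trace: Optional[Trace]
    beats: List[bm.BeatAnalysis]
    summary: dict = field(default_factory=dict)

    @property
    def labels(self) -> List[str]:
        return [b.label for b in self.beats]

    @property
    def label(self) -> str:
        return aggregate_label(self.labels)

    def beats_frame(self) -> pd.DataFrame:
        return bm.beats_frame(self.beats)


@dataclass
class ScanGrid:
    """Vulnerability map over two conductance-multiplier axes."""

    axis1_channel: str
    axis1_values: np.ndarray
    axis2_channel: str
    axis2_values: np.ndarray
    labels: np.ndarray          # shape (len(axis1), len(axis2)), dtype object

    def __post_init__(self):
        self.axis1_values = np.asarray(self.axis1_values, dtype=float)
        self.axis2_values = np.asarray(self.axis2_values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape != (len(self.axis1_values),
                                 len(self.axis2_values)):
            raise ValueError("label matrix shape does not match the axes")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.labels,
            index=pd.Index(self.axis1_values, name=self.axis1_channel),
            columns=pd.Index(self.axis2_values, name=self.axis2_channel))


def _steady_state(model: CellModel, state, bcl: float, n_beats: int):
    _, y = model.pace(state, bcl, n_beats, record_last=0 + 1,
                      with_currents=False)
    return y


def _condition_setup(condition: str, interventions=None,
                     params: Optional[ParameterSet] = None):
    """(params, initial state, manifest) for a condition plus interventions.

    `interventions` is a sequence of (description, transform) pairs or bare
    callables ParameterSet -> ParameterSet.
    """
    p = params if params is not None else condition_parameters(condition)
    manifest = [f"condition:{condition}"]
    for item in interventions or ():
        if isinstance(item, tuple):
            desc, fn = item
        else:
            desc, fn = getattr(item, "__name__", repr(item)), item
        p = fn(p)
        manifest.append(str(desc))
    return p, initial_state(condition), manifest


# ---------------------------------------------------------------------------
# rate dependence
# ---------------------------------------------------------------------------
def run_rate_dependence(condition: str = "SR",
                        drug: Optional[DrugSpec] = None,
                        bcl_list: Sequence[float] = DEFAULT_BCL_LIST,
                        n_pre_beats: int = 60,
                        n_analyze: int = 3,
                        cfg: Optional[BiomarkerConfig] = None,
                        solver: Optional[SolverOptions] = None
                        ) -> pd.DataFrame:
    """Steady-state biomarkers vs BCL, with and without the drug.

    Returns one row per BCL with APD, dV/dt_max and Ta_max for control and
    drug plus their differences (delta = drug - control).  Beats without
    1:1 capture are flagged and their biomarkers left missing, never
    averaged in.
    """
    rows = []
    for bcl in bcl_list:
        entry = {"bcl": float(bcl)}
        for tag, use_drug in (("control", False), ("drug", True)):
            p, y0, _ = _condition_setup(condition)
            if use_drug:
                if drug is None:
                    entry.update({f"apd_{tag}": np.nan,
                                  f"dvdt_max_{tag}": np.nan,
                                  f"ta_max_{tag}": np.nan,
                                  f"label_{tag}": "none"})
                    continue
                p = apply_drug(p, drug)
            model = CellModel(p, solver=solver or SolverOptions(dt_out=0.25))
            y = _steady_state(model, y0, bcl, n_pre_beats)
            tr, _ = model.pace(y, bcl, n_analyze, with_currents=True)
            beats = analyze_beats(tr, cfg, bcl=bcl)
            good = [b for b in beats if b.label in ("normal", "EAD", "A-EAD",
                                                    "DAD")]
            last = good[-1] if good else None
            entry[f"apd_{tag}"] = last.apd if last and last.apd else np.nan
            entry[f"dvdt_max_{tag}"] = last.dvdt_max if last else np.nan
            entry[f"ta_max_{tag}"] = last.ta_max if last else np.nan
            entry[f"label_{tag}"] = aggregate_label([b.label for b in beats])
        entry["delta_apd"] = entry["apd_drug"] - entry["apd_control"]
        entry["delta_dvdt_max"] = (entry["dvdt_max_drug"]
                                   - entry["dvdt_max_control"])
        entry["delta_ta_max"] = entry["ta_max_drug"] - entry["ta_max_control"]
        rows.append(entry)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# conductance-scan vulnerability maps
# ---------------------------------------------------------------------------
def run_conductance_scan(condition: str = "SR",
                         axis1=("GCaL", (2.0, 3.0, 4.0, 5.0)),
                         axis2=("GKur", (1.0, 0.9, 0.8, 0.7, 0.6, 0.5)),
                         n_beats: int = 70,
                         bcl: float = 2000.0,
                         n_analyze: int = 8,
                         drug: Optional[DrugSpec] = None,
                         reverse_af_gcal: bool = True,
                         cfg: Optional[BiomarkerConfig] = None,
                         solver: Optional[SolverOptions] = None) -> ScanGrid:
    """Map AP abnormality labels over a conductance-multiplier grid.

    Each cell is simulated independently from the condition's initial
    state; the final `n_analyze` beats are classified.  For AF conditions
    the remodeling-induced GCaL halving is reversed before the grid
    multipliers are applied (so multipliers act on the restored baseline);
    a solver failure marks the cell "failed" and the scan continues.
    """
    ch1, vals1 = axis1
    ch2, vals2 = axis2
    labels = np.empty((len(vals1), len(vals2)), dtype=object)
    for i, f1 in enumerate(vals1):
        for j, f2 in enumerate(vals2):
            try:
                res = run_scan_cell(condition, {ch1: f1, ch2: f2},
                                    n_beats=n_beats, bcl=bcl,
                                    n_analyze=n_analyze, drug=drug,
                                    reverse_af_gcal=reverse_af_gcal,
                                    cfg=cfg, solver=solver)
                labels[i, j] = res.label
            except Exception:
                labels[i, j] = "failed"
    return ScanGrid(ch1, np.asarray(vals1), ch2, np.asarray(vals2), labels)


def run_scan_cell(condition: str, multipliers: dict,
                  n_beats: int = 70, bcl: float = 2000.0,
                  n_analyze: int = 8,
                  drug: Optional[DrugSpec] = None,
                  reverse_af_gcal: bool = True,
                  cfg: Optional[BiomarkerConfig] = None,
                  solver: Optional[SolverOptions] = None) -> ProtocolResult:
    """One cell of the vulnerability map, with the full trace tail."""
    interventions = []
    if condition.startswith("AF") and reverse_af_gcal:
        interventions.append(("reverse AF GCaL halving",
                              lambda p: scale_conductances(p, {"GCaL": 2.0})))
    interventions.append((f"scale {multipliers}",
                          lambda p: scale_conductances(p, multipliers)))
    if drug is not None:
        interventions.append((f"drug {drug.name} {drug.concentration}",
                              lambda p: apply_drug(p, drug)))
    p, y0, manifest = _condition_setup(condition, interventions)
    model = CellModel(p, solver=solver or SolverOptions(dt_out=0.25))
    tr, _ = model.pace(y0, bcl, n_beats,
                       record_last=min(n_analyze, n_beats),
                       with_currents=True)
    beats = analyze_beats(tr, cfg, bcl=bcl)
    return ProtocolResult(condition, manifest, tr, beats,
                          summary={"multipliers": dict(multipliers),
                                   "bcl": bcl, "n_beats": n_beats})


# ---------------------------------------------------------------------------
# rapid-pace / pause protocols (DADs, phase-3 EADs)
# ---------------------------------------------------------------------------
def run_rapid_pace_pause(condition: str = "SR",
                         interventions=None,
                         fast_bcl: float = 100.0,
                         fast_duration: float = 20000.0,
                         pause: Optional[float] = None,
                         slow_bcl: float = 2000.0,
                         n_slow_beats: int = 10,
                         n_condition_beats: int = 50,
                         cfg: Optional[BiomarkerConfig] = None,
                         solver: Optional[SolverOptions] = None
                         ) -> ProtocolResult:
    """Rapid pacing (default 10 Hz for 20 s), a pause, then slow pacing.

    DAD detection is active during the pause and the slow-phase diastolic
    intervals.  The returned trace covers the last second of the fast
    phase, the pause and the slow beats; the summary records the state at
    the end of the fast phase (Na/Ca loading) and the diastolic subspace
    Ca2+ minimum during the pause.
    """
    if pause is None:
        pause = slow_bcl
    if pause < 0:
        raise ValueError("pause must be >= 0")
    p, y0, manifest = _condition_setup(condition, interventions)
    opts = solver or SolverOptions(dt_out=0.25)
    model = CellModel(p, solver=opts)

    # condition at the slow rate, then pace fast
    y = _steady_state(model, y0, slow_bcl, n_condition_beats)
    n_fast = int(round(fast_duration / fast_bcl))
    keep_fast = min(n_fast, int(round(1000.0 / fast_bcl)))
    tr_fast, y_fast = model.pace(y, fast_bcl, n_fast,
                                 record_last=keep_fast, with_currents=True)
    manifest.append(f"pace {n_fast} beats at bcl={fast_bcl} ms")
    t0 = tr_fast.t[-1]

    traces = [tr_fast]
    y = y_fast
    if pause > 0:
        tr_pause, y = model.integrate(y, pause, stim_times=(), t0=t0,
                                      with_currents=True)
        manifest.append(f"pause {pause} ms")
        traces.append(tr_pause)
        t0 = tr_pause.t[-1]
    tr_slow, y = model.pace(y, slow_bcl, n_slow_beats, t0=t0,
                            with_currents=True)
    manifest.append(f"pace {n_slow_beats} beats at bcl={slow_bcl} ms")
    traces.append(tr_slow)
    trace = concat(traces)

    beats = analyze_beats(tr_slow, cfg, bcl=slow_bcl)
    pause_sl = trace.slice(tr_fast.t[-1], tr_fast.t[-1] + pause) \
        if pause > 0 else None
    summary = {
        "fast_bcl": fast_bcl, "n_fast": n_fast, "pause": pause,
        "slow_bcl": slow_bcl,
        "na_i_end_fast": float(y_fast["Na_i"]),
        "ca_sr_end_fast": float(max(y_fast["Ca_SRss"],
                                    y_fast["Ca_SRbc"])),
        "ca_ss_end_fast": float(y_fast["Ca_ss"]),
    }
    if pause_sl is not None:
        summary["ca_ss_pause_min"] = float(pause_sl["Ca_ss"].min())
        summary["ca_bc_pause_min"] = float(pause_sl["Ca_bc"].min())
        summary["vm_pause"] = float(pause_sl["Vm"].min())
        dad = bm._detect_dad(pause_sl.t, pause_sl["Vm"], 0,
                             pause_sl.t[-1] + 1.0,
                             cfg or BiomarkerConfig())
        summary["pause_dad_amplitude"] = dad
    return ProtocolResult(condition, manifest, trace, beats, summary)


def run_phase3_protocol(ach_conc: float = 1.0,
                        drug: Optional[DrugSpec] = None,
                        contraction_overrides: Optional[dict] = None,
                        condition: str = "SR",
                        gcal_factor: float = 0.8,
                        gkur_factor: float = 3.0,
                        fast_bcl: float = 100.0,
                        fast_duration: float = 20000.0,
                        pause: Optional[float] = None,
                        slow_bcl: float = 1000.0,
                        n_slow_beats: int = 6,
                        apply_ina_mods: bool = True,
                        n_condition_beats: int = 30,
                        cfg: Optional[BiomarkerConfig] = None,
                        solver: Optional[SolverOptions] = None
                        ) -> ProtocolResult:
    """Phase-3 EAD induction: 10 Hz for 20 s, a pause, then 1 Hz.

    The substrate combines IKACh (parasympathetic activation), Na-channel
    reactivation mods (fast recovery, +15 mV availability shift) and a
    negative plateau (GCaL x0.8, GKur x3).  Post-pause beats are analyzed
    for phase-3 EADs; the summary reports the take-off potential and
    amplitude of the first post-pause EAD.
    """
    interventions = [
        (f"IKACh ACh={ach_conc} uM", lambda p: enable_ikach(p, ach_conc)),
        (f"scale GCaL x{gcal_factor}, GKur x{gkur_factor}",
         lambda p: scale_conductances(p, {"GCaL": gcal_factor,
                                          "GKur": gkur_factor})),
    ]
    if apply_ina_mods:
        interventions.insert(
            1, ("INa reactivation mods (recovery x1e-3, +15 mV shift)",
                apply_phase3_ina_mods))
    if contraction_overrides:
        interventions.append(
            (f"contraction overrides {contraction_overrides}",
             lambda p: p.with_updates(**contraction_overrides)))
    if drug is not None:
        interventions.append((f"drug {drug.name} {drug.concentration}",
                              lambda p: apply_drug(p, drug)))

    res = run_rapid_pace_pause(
        condition, interventions, fast_bcl=fast_bcl,
        fast_duration=fast_duration, pause=pause, slow_bcl=slow_bcl,
        n_slow_beats=n_slow_beats, n_condition_beats=n_condition_beats,
        cfg=cfg, solver=solver)

    first = res.beats[0] if res.beats else None
    res.summary["first_postpause_label"] = first.label if first else "none"
    res.summary["ead_takeoff"] = bm.takeoff_potential(res.beats)
    if first is not None and res.trace is not None:
        # plateau potential of the first post-pause beat: Vm at mid-plateau
        t = res.trace.t
        s = first.t_stim
        m = (t >= s + 30) & (t <= s + 120)
        res.summary["first_postpause_plateau"] = \
            float(np.median(res.trace["Vm"][m])) if m.any() else np.nan
    return res


# ---------------------------------------------------------------------------
# myofilament sensitivity sweeps
# ---------------------------------------------------------------------------
def run_myofilament_sweep(base_protocol: Callable[..., ProtocolResult],
                          parameter: str,
                          values: Sequence[float],
                          relative: bool = True,
                          **protocol_kwargs) -> pd.DataFrame:
    """Re-run a protocol varying one contraction parameter.

    `parameter` is one of 'kd', 'gamma', 'koff', 'SL'; `values` are
    multiplicative factors when `relative` (0% change = 1.0) or absolute
    values otherwise.  Returns one row per value with the aggregate label
    and summary biomarkers.
    """
    pmap = {"kd": "kd_scale", "gamma": "gamma", "koff": "koff", "SL": "SL"}
    if parameter not in pmap:
        raise KeyError(f"unknown myofilament parameter {parameter!r}; "
                       f"expected one of {sorted(pmap)}")
    pname = pmap[parameter]
    base = ParameterSet()
    rows = []
    for v in values:
        if relative and parameter != "SL":
            override = {pname: base[pname] * v} if pname != "kd_scale" \
                else {pname: v}
        else:
            override = {pname: v}
        res = base_protocol(contraction_overrides=override,
                            **protocol_kwargs)
        apds = [b.apd for b in res.beats if b.apd]
        rows.append({
            "parameter": parameter, "value": v, "override": str(override),
            "label": res.label,
            "apd_mean": float(np.mean(apds)) if apds else np.nan,
            "ta_max": float(np.nanmax([b.ta_max for b in res.beats]))
            if res.beats else np.nan,
        })
    return pd.DataFrame(rows)


def run_scan_cell_sweep(condition: str, multipliers: dict,
                        parameter: str, values: Sequence[float],
                        n_beats: int = 70, bcl: float = 2000.0,
                        **kwargs) -> pd.DataFrame:
    """Myofilament sweep over a conductance-scan cell (phase-2 EAD case)."""
    pmap = {"kd": "kd_scale", "gamma": "gamma", "koff": "koff", "SL": "SL"}
    pname = pmap[parameter]
    base = ParameterSet()
    rows = []
    for v in values:
        if parameter == "SL":
            override = {pname: v}
        elif parameter == "kd":
            override = {pname: v}
        else:
            override = {pname: base[pname] * v}
        interventions = [(f"contraction override {override}",
                          lambda p, o=override: p.with_updates(**o))]
        p, y0, manifest = _condition_setup(condition, interventions)
        if condition.startswith("AF"):
            p = scale_conductances(p, {"GCaL": 2.0})
            manifest.append("reverse AF GCaL halving")
        p = scale_conductances(p, multipliers)
        manifest.append(f"scale {multipliers}")
        model = CellModel(p, solver=kwargs.get("solver")
                          or SolverOptions(dt_out=0.25))
        tr, _ = model.pace(y0, bcl, n_beats, record_last=8,
                           with_currents=True)
        beats = analyze_beats(tr, bcl=bcl)
        apds = [b.apd for b in beats if b.apd]
        rows.append({"parameter": parameter, "value": v,
                     "label": aggregate_label([b.label for b in beats]),
                     "apd_mean": float(np.mean(apds)) if apds else np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# clamp waveforms
# ---------------------------------------------------------------------------
def record_clamp_waveform(condition: str, channel: str,
                          bcl: float = 2000.0,
                          n_pre_beats: int = 60,
                          path=None,
                          solver: Optional[SolverOptions] = None):
    """One steady-state-beat current waveform for channel clamping.

    The condition is paced to quasi-steady state at `bcl`; the recorded
    beat is returned as a Trace (time from 0, channels: the current) and
    optionally written to CSV with bcl metadata in the header names.
    Non-converged pacing is recorded as a warning in the metadata.
    """
    from .model import ChannelClamp
    if channel not in ("ICaL", "IKr"):
        raise ValueError("clampable channels are 'ICaL' and 'IKr'")
    p = condition_parameters(condition)
    model = CellModel(p, solver=solver or SolverOptions(dt_out=0.25))
    y, n, converged = model.pace_to_steady_state(initial_state(condition),
                                                 bcl, max_beats=n_pre_beats)
    tr, _ = model.pace(y, bcl, 1, with_currents=True)
    t = tr.t - tr.t[0]
    wave = Trace(t, {channel: tr[channel]}, {channel: "A/F"},
                 np.array([0.0]))
    meta = {"condition": condition, "bcl": bcl, "n_beats": n,
            "converged": bool(converged)}
    if not converged:
        meta["warning"] = "pacing did not reach the convergence tolerance"
    if path is not None:
        wave.to_csv(path)
    clamp = ChannelClamp(channel, t, tr[channel], bcl)
    return wave, clamp, meta
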