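"""Per-beat feature extraction and abnormality classification.

Works on `Trace` objects whose `stim_times` mark the beat boundaries.
Labels: normal, EAD (early afterdepolarization during repolarization),
A-EAD (EADs on alternating beats only), RF (repolarization failure),
DAD (delayed afterdepolarization after full repolarization), failed
(no analyzable upstroke).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

LABELS = ("normal", "EAD", "A-EAD", "RF", "DAD", "failed")


@dataclass(frozen=True)
class BiomarkerConfig:
    """Detection thresholds (all configurable; defaults documented in the
    methods note)."""

    repol_fraction: float = 0.9      # APD level (APD90)
    ead_dvdt_thresh: float = 0.05    # mV/ms, sustained positive dV/dt
    ead_sustain_ms: float = 2.0      # minimum duration of the excursion
    ead_min_amp: float = 0.5         # mV rise during the excursion
    ead_earliest: float = 80.0       # ms after upstroke; excludes the
                                     # normal phase-1 notch/dome sequence
    dad_amp_thresh: float = 1.0      # mV above the diastolic baseline
    rf_vm_thresh: float = -60.0      # Vm that must be reached before next stim
    full_repol_offset: float = 10.0  # mV above RMP = "fully repolarized"
    upstroke_window: float = 20.0    # ms after stimulus containing upstroke


@dataclass
class BeatAnalysis:
    """Biomarkers of one paced beat."""

    index: int
    t_stim: float                    # ms
    rmp: float                       # mV, just before the stimulus
    v_peak: float                    # mV
    dvdt_max: float                  # V/s
    apd: Optional[float]             # ms at the configured repol fraction
    ca_ss_dia: float = np.nan        # uM
    ca_ss_sys: float = np.nan
    ca_bc_dia: float = np.nan
    ca_bc_sys: float = np.nan
    ta_max: float = np.nan           # kPa
    ta_relax_dur: Optional[float] = None   # ms, peak -> 90% decay
    label: str = "normal"
    ead: bool = False
    ead_takeoff: Optional[float] = None    # mV
    dad_amplitude: Optional[float] = None  # mV

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "index", "t_stim", "rmp", "v_peak", "dvdt_max", "apd",
            "ca_ss_dia", "ca_ss_sys", "ca_bc_dia", "ca_bc_sys", "ta_max",
            "ta_relax_dur", "label", "ead_takeoff", "dad_amplitude")}


def apd(t, v, repol_fraction: float = 0.9, rmp: Optional[float] = None,
        t_end: Optional[float] = None):
    """Action-potential duration of a single-beat Vm window.

    Measured from the time of maximal upstroke velocity to the crossing of
    RMP + (1 - repol_fraction) * amplitude.  Returns None (and the caller
    marks the beat an RF candidate) when the crossing does not occur before
    `t_end`.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(t) < 4:
        raise ValueError("beat window too short")
    dv = np.gradient(v, t)
    iup = int(np.argmax(dv))
    if rmp is None:
        rmp = v[: max(iup, 1)].min() if iup > 0 else v[0]
    amp = v.max() - rmp
    if amp <= 5.0 or dv[iup] <= 1.0:
        raise ValueError("beat contains no upstroke")
    level = rmp + (1.0 - repol_fraction) * amp
    after = slice(int(np.argmax(v)), len(t))
    below = np.where(v[after] <= level)[0]
    if len(below) == 0:
        return None
    k = below[0] + after.start
    if t_end is not None and t[k] > t_end:
        return None
    # linear interpolation of the crossing time
    if k > 0 and v[k - 1] > level:
        frac = (v[k - 1] - level) / (v[k - 1] - v[k])
        t_cross = t[k - 1] + frac * (t[k] - t[k - 1])
    else:
        t_cross = t[k]
    return float(t_cross - t[iup])


def _detect_ead(t, v, i_peak, i_repol, cfg: BiomarkerConfig):
    """Positive-dV/dt excursions during repolarization.

    Returns (found, takeoff_mV): the take-off potential is Vm at the
    negative-to-positive dV/dt zero-crossing that initiates the secondary
    depolarization.
    """
    if i_repol - i_peak < 4:
        return False, None
    tt = t[i_peak:i_repol]
    vv = v[i_peak:i_repol]
    dv = np.gradient(vv, tt)
    pos = dv > cfg.ead_dvdt_thresh
    if not pos.any():
        return False, None
    # group consecutive positive runs
    edges = np.flatnonzero(np.diff(np.concatenate(([0], pos.view(np.int8),
                                                   [0]))))
    for a, b in zip(edges[::2], edges[1::2]):
        dur = tt[min(b, len(tt) - 1)] - tt[a]
        rise = vv[a:b].max() - vv[a] if b > a else 0.0
        # skip excursions that begin immediately at the AP peak
        if dur >= cfg.ead_sustain_ms and rise >= cfg.ead_min_amp and a > 1:
            return True, float(vv[a])
    return False, None


def _detect_dad(t, v, i_repol, t_next, cfg: BiomarkerConfig):
    """Largest post-repolarization depolarizing *bump* before the next
    stimulus.  A bump must rise above the preceding local baseline and fall
    again (slow monotone diastolic drift is not a DAD)."""
    from scipy.signal import find_peaks
    m = (t >= t[i_repol]) & (t < t_next - 1.0)
    if m.sum() < 5:
        return None
    vv = v[m]
    peaks, props = find_peaks(vv, prominence=cfg.dad_amp_thresh)
    if len(peaks) == 0:
        return None
    return float(props["prominences"].max())


def analyze_beats(trace, cfg: Optional[BiomarkerConfig] = None,
                  bcl: Optional[float] = None) -> List[BeatAnalysis]:
    """Per-beat biomarker extraction over a paced trace.

    Beat boundaries are the stimulus times recorded in the trace; the final
    beat extends to the end of the trace.
    """
    cfg = cfg or BiomarkerConfig()
    stims = np.asarray(trace.stim_times, dtype=float)
    if len(stims) == 0:
        raise ValueError("trace carries no stimulus times")
    t = trace.t
    v = trace["Vm"]
    if bcl is None:
        bcl = float(np.median(np.diff(stims))) if len(stims) > 1 \
            else float(t[-1] - stims[0])
    bounds = list(stims) + [stims[-1] + bcl]
    out: List[BeatAnalysis] = []
    for k, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        m = (t >= a) & (t < min(b, t[-1] + 1e-9))
        if m.sum() < 8:
            continue
        tb, vb = t[m], v[m]
        # RMP: last pre-stimulus sample (previous diastole), else first sample
        pre = np.where(t < a)[0]
        rmp = float(v[pre[-1]]) if len(pre) else float(vb[0])
        dv = np.gradient(vb, tb)
        iwin = tb <= a + cfg.upstroke_window
        dvdt_max = float(dv[iwin].max()) if iwin.any() else float(dv.max())
        v_peak = float(vb.max())
        beat = BeatAnalysis(index=k, t_stim=float(a), rmp=rmp, v_peak=v_peak,
                            dvdt_max=dvdt_max, apd=None)
        amp = v_peak - rmp
        if amp <= 15.0 or dvdt_max <= 2.0:
            beat.label = "failed"
            out.append(beat)
            continue
        try:
            beat.apd = apd(tb, vb, cfg.repol_fraction, rmp=rmp)
        except ValueError:
            beat.label = "failed"
            out.append(beat)
            continue

        i_peak = int(np.argmax(vb))
        full_level = max(rmp + cfg.full_repol_offset, cfg.rf_vm_thresh)
        below = np.where(vb[i_peak:] <= full_level)[0]
        i_repol = below[0] + i_peak if len(below) else len(vb) - 1

        reached = (vb[i_peak:] <= cfg.rf_vm_thresh).any()
        if not reached:
            beat.label = "RF"
            beat.apd = None
        # EAD search window: after the early notch/dome sequence, down to
        # full repolarization
        i_start = int(np.searchsorted(tb, tb[i_peak] + cfg.ead_earliest))
        i_start = min(max(i_start, i_peak), i_repol)
        ead, takeoff = _detect_ead(tb, vb, i_start, i_repol, cfg)
        beat.ead = ead
        if ead:
            beat.ead_takeoff = takeoff
            if beat.label == "normal":
                beat.label = "EAD"
        if beat.label not in ("RF",):
            dad = _detect_dad(tb, vb, i_repol, b, cfg)
            if dad is not None:
                beat.dad_amplitude = dad
                if beat.label == "normal":
                    beat.label = "DAD"

        # Ca and tension biomarkers when the channels are present
        if "Ca_ss" in trace:
            c = trace["Ca_ss"][m]
            beat.ca_ss_dia, beat.ca_ss_sys = float(c.min()), float(c.max())
        if "Ca_bc" in trace:
            c = trace["Ca_bc"][m]
            beat.ca_bc_dia, beat.ca_bc_sys = float(c.min()), float(c.max())
        if "Ta" in trace:
            ta = trace["Ta"][m]
            beat.ta_max = float(ta.max())
            ipk = int(np.argmax(ta))
            base = float(ta.min())
            level = ta[ipk] - cfg.repol_fraction * (ta[ipk] - base)
            dec = np.where(ta[ipk:] <= level)[0]
            beat.ta_relax_dur = float(tb[dec[0] + ipk] - tb[ipk]) \
                if len(dec) else None
        out.append(beat)
    _apply_alternans(out)
    return out


def _apply_alternans(beats: List[BeatAnalysis]) -> None:
    """Rewrite EAD labels as A-EAD when EADs occur on alternating beats only.

    Requires at least four consecutive analyzed beats.
    """
    if len(beats) < 4:
        return
    flags = [b.ead for b in beats]
    n_ead = sum(flags)
    if n_ead < 2 or all(flags):
        return
    even = all(flags[i] for i in range(0, len(flags), 2)) and \
        not any(flags[i] for i in range(1, len(flags), 2))
    odd = all(flags[i] for i in range(1, len(flags), 2)) and \
        not any(flags[i] for i in range(0, len(flags), 2))
    if even or odd:
        for b in beats:
            if b.label == "EAD":
                b.label = "A-EAD"


def classify_beats(trace, cfg: Optional[BiomarkerConfig] = None,
                   bcl: Optional[float] = None) -> List[str]:
    """Per-beat abnormality labels (precedence RF > EAD/A-EAD > DAD)."""
    return [b.label for b in analyze_beats(trace, cfg, bcl)]


def aggregate_label(labels) -> str:
    """Single label for a simulation cell: RF > A-EAD > EAD > DAD > normal."""
    labels = list(labels)
    if not labels:
        return "failed"
    if any(l == "RF" for l in labels):
        return "RF"
    if any(l == "A-EAD" for l in labels):
        return "A-EAD"
    if any(l == "EAD" for l in labels):
        return "EAD"
    if any(l == "DAD" for l in labels):
        return "DAD"
    if all(l == "failed" for l in labels):
        return "failed"
    return "normal"


def takeoff_potential(beats) -> float:
    """Take-off potential (mV) of the first EAD among analyzed beats;
    NaN when no beat carries an EAD."""
    if isinstance(beats, BeatAnalysis):
        beats = [beats]
    for b in beats:
        if b.ead and b.ead_takeoff is not None:
            return float(b.ead_takeoff)
    return float("nan")


def beats_frame(beats: List[BeatAnalysis]) -> pd.DataFrame:
    """One row per beat (CSV-friendly)."""
    return pd.DataFrame([b.as_dict() for b in beats])


def delta(biomarkers_drug: pd.DataFrame,
          biomarkers_control: pd.DataFrame,
          on: str = "bcl") -> pd.DataFrame:
    """Drug-minus-control difference of matched biomarker tables.

    Both tables must be indexed the same way (e.g. one row per BCL); missing
    values propagate.  Antisymmetric: swapping the arguments negates it.
    """
    d = biomarkers_drug.set_index(on) if on in biomarkers_drug else \
        biomarkers_drug
    c = biomarkers_control.set_index(on) if on in biomarkers_control else \
        biomarkers_control
    if not d.index.equals(c.index):
        raise ValueError("tables are not matched (different index)")
    num_d = d.select_dtypes("number")
    num_c = c.select_dtypes("number")
    out = num_d - num_c
    out.columns = [f"delta_{c}" for c in out.columns]
    return out.reset_index()
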