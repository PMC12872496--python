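"""Synthetic waveforms with analytically known ground truth.

These drive the classifier/biomarker tests without the ODE model: each
constructor returns a `Trace` plus a ground-truth annotation dict.
"""

from __future__ import annotations

import numpy as np

from .trace import Trace


def _beat_template(t, rmp, peak, plateau_ms, repol_ms, upstroke_ms=2.0):
    """Trapezoidal action potential: linear upstroke, flat plateau, linear
    repolarization back to rest."""
    v = np.full_like(t, rmp)
    m = t < upstroke_ms
    v[m] = rmp + (peak - rmp) * t[m] / upstroke_ms
    m = (t >= upstroke_ms) & (t < upstroke_ms + plateau_ms)
    v[m] = peak
    m = (t >= upstroke_ms + plateau_ms) & \
        (t < upstroke_ms + plateau_ms + repol_ms)
    v[m] = peak + (rmp - peak) * (t[m] - upstroke_ms - plateau_ms) / repol_ms
    return v


def trapezoid_ap(n_beats: int = 4, bcl: float = 1000.0, dt: float = 0.2,
                 rmp: float = -80.0, peak: float = 20.0,
                 plateau_ms: float = 200.0, repol_ms: float = 100.0):
    """Trapezoidal APs with a closed-form APD at any repolarization level.

    APD(f) from the upstroke to the crossing of rmp + (1-f)*amplitude:
    upstroke time + plateau + f * repol_ms (measured from the dV/dt max at
    the upstroke midpoint; the ground truth uses the upstroke end).
    """
    t = np.arange(0.0, n_beats * bcl, dt)
    v = np.full_like(t, rmp)
    stims = np.arange(n_beats) * bcl
    for s in stims:
        m = (t >= s) & (t < s + bcl)
        v[m] = _beat_template(t[m] - s, rmp, peak, plateau_ms, repol_ms)
    truth = {
        "labels": ["normal"] * n_beats,
        # from upstroke to the 90%-repolarization crossing
        "apd90": 2.0 + plateau_ms + 0.9 * repol_ms,
        "apd_full": 2.0 + plateau_ms + repol_ms,
        "rmp": rmp, "peak": peak,
    }
    return Trace(t, {"Vm": v}, {"Vm": "mV"}, stims), truth


def bump_ap(bump_beats=(1, 3, 5), n_beats: int = 6, bcl: float = 1000.0,
            dt: float = 0.2, bump_amp: float = 20.0,
            bump_at_ms: float = 230.0, bump_width_ms: float = 20.0,
            takeoff_level: float = None, **kw):
    """Trapezoidal APs with a triangular depolarizing bump during the
    repolarization phase of the selected beats (ground-truth EADs).

    With the default geometry (plateau 200 ms, repolarization 100 ms) the
    bump interrupts repolarization around -50 mV, below the AP peak."""
    tr, truth = trapezoid_ap(n_beats=n_beats, bcl=bcl, dt=dt, **kw)
    v = tr["Vm"]
    labels = list(truth["labels"])
    for k in bump_beats:
        s = tr.stim_times[k]
        m = (tr.t >= s + bump_at_ms) & (tr.t < s + bump_at_ms + bump_width_ms)
        x = (tr.t[m] - s - bump_at_ms) / bump_width_ms
        v[m] += bump_amp * (1.0 - np.abs(2.0 * x - 1.0))
        labels[k] = "EAD"
    flags = [k in bump_beats for k in range(n_beats)]
    alternating = (n_beats >= 4 and any(flags) and not all(flags)
                   and (all(flags[0::2]) + all(flags[1::2]) == 1)
                   and (not any(flags[1::2]) or not any(flags[0::2])))
    if alternating:
        labels = ["A-EAD" if l == "EAD" else l for l in labels]
    truth["labels"] = labels
    truth["bump_beats"] = list(bump_beats)
    return tr, truth


def alternans_ap(n_beats: int = 6, bcl: float = 1000.0, dt: float = 0.2,
                 **kw):
    """EAD bumps on alternating beats only (ground truth A-EAD)."""
    return bump_ap(bump_beats=tuple(range(1, n_beats, 2)), n_beats=n_beats,
                   bcl=bcl, dt=dt, **kw)


def dad_train(n_beats: int = 4, bcl: float = 1000.0, dt: float = 0.2,
              amplitude: float = 2.0, dad_at_ms: float = 600.0,
              dad_width_ms: float = 60.0, **kw):
    """Trapezoidal APs plus a diastolic depolarizing bump on every beat
    (ground-truth DADs)."""
    tr, truth = trapezoid_ap(n_beats=n_beats, bcl=bcl, dt=dt, **kw)
    v = tr["Vm"]
    for s in tr.stim_times:
        m = (tr.t >= s + dad_at_ms) & (tr.t < s + dad_at_ms + dad_width_ms)
        x = (tr.t[m] - s - dad_at_ms) / dad_width_ms
        v[m] += amplitude * np.sin(np.pi * x) ** 2
    truth["labels"] = ["DAD"] * n_beats
    truth["dad_amplitude"] = amplitude
    return tr, truth


def rf_ap(n_beats: int = 4, bcl: float = 1000.0, dt: float = 0.2,
          rmp: float = -80.0, peak: float = 20.0,
          hang_level: float = -30.0):
    """APs that never repolarize below `hang_level` (repolarization
    failure)."""
    t = np.arange(0.0, n_beats * bcl, dt)
    v = np.full_like(t, hang_level)
    stims = np.arange(n_beats) * bcl
    for s in stims:
        m = (t >= s) & (t < s + 2.0)
        v[m] = hang_level + (peak - hang_level) * (t[m] - s) / 2.0
        m = (t >= s + 2.0) & (t < s + 150.0)
        v[m] = peak + (hang_level - peak) * (t[m] - s - 2.0) / 148.0
    v[t < 2.0] = rmp + (peak - rmp) * t[t < 2.0] / 2.0
    truth = {"labels": ["RF"] * n_beats}
    return Trace(t, {"Vm": v}, {"Vm": "mV"}, stims), truth


def current_pulse(amplitude: float = -2.0, t_on: float = 50.0,
                  t_off: float = 250.0, duration: float = 400.0,
                  dt: float = 0.2):
    """Rectangular current waveform (clamp-input fixture)."""
    t = np.arange(0.0, duration, dt)
    i = np.where((t >= t_on) & (t < t_off), amplitude, 0.0)
    tr = Trace(t, {"I": i}, {"I": "A/F"})
    truth = {"integral": amplitude * (t_off - t_on)}
    return tr, truth


_KINDS = {
    "trapezoid_AP": trapezoid_ap,
    "bump_AP": bump_ap,
    "alternans_AP": alternans_ap,
    "dad_train": dad_train,
    "rf_AP": rf_ap,
    "current_pulse": current_pulse,
}


def make_fixture_waveforms(kind: str, **parameters):
    """Deterministic synthetic waveform + ground-truth annotation bundle."""
    try:
        fn = _KINDS[kind]
    except KeyError:
        raise KeyError(f"unknown fixture kind {kind!r}; "
                       f"expected one of {sorted(_KINDS)}") from None
    return fn(**parameters)
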