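"""Pure ParameterSet -> ParameterSet transforms: drugs, AF remodeling,
conductance scaling, Na-channel reactivation mods, IKACh, current clamps.

All transforms return copies and never mutate their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .parameters import CONDUCTANCE_NAMES, ParameterSet

# map protocol channel labels to conductance parameters
CHANNEL_PARAMS = {
    "INa": "gNa", "ICaL": "gCaL", "Ito": "gto", "IKur": "gKur",
    "IKr": "gKr", "IKs": "gKs", "IK1": "gK1", "INaCa": "kNaCa",
    "IKACh": "gKACh",
    # accept GX-style aliases used in conductance-scan notation
    "GNa": "gNa", "GCaL": "gCaL", "Gto": "gto", "GKur": "gKur",
    "GKr": "gKr", "GKs": "gKs", "GK1": "gK1",
}


def hill_block_fraction(conc: float, ic50: float, n_h: float) -> float:
    """Fraction of channels blocked at concentration `conc`.

    conc and ic50 must share units; f = conc^nH / (conc^nH + ic50^nH).
    The blocked channel's conductance is multiplied by (1 - f).
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    if n_h <= 0:
        raise ValueError("Hill coefficient must be positive")
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    if conc == 0.0:
        return 0.0
    x = (conc / ic50) ** n_h
    return x / (x + 1.0)


@dataclass(frozen=True)
class DrugTarget:
    channel: str
    ic50: float
    n_h: float
    units: str = "uM"


@dataclass(frozen=True)
class DrugSpec:
    """A pore-block drug: each target conductance is scaled by
    (1 - hill_block_fraction)."""

    name: str
    concentration: float          # in `units`
    targets: Tuple[DrugTarget, ...]
    units: str = "uM"

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        object.__setattr__(self, "targets", tuple(self.targets))

    def block_fractions(self) -> dict:
        out = {}
        for t in self.targets:
            conc = self.concentration
            if t.units != self.units:
                conc = _convert_conc(conc, self.units, t.units)
            out[t.channel] = hill_block_fraction(conc, t.ic50, t.n_h)
        return out


_CONC_SCALE = {"nM": 1e-3, "uM": 1.0, "mM": 1e3}


def _convert_conc(value: float, from_u: str, to_u: str) -> float:
    try:
        return value * _CONC_SCALE[from_u] / _CONC_SCALE[to_u]
    except KeyError as e:
        raise ValueError(f"unknown concentration unit {e}") from None


def drug_4ap(concentration: float = 5.0) -> DrugSpec:
    """4-aminopyridine: IKur-selective at low dose (IC50 8 uM, nH 1.3)."""
    return DrugSpec("4-AP", concentration,
                    (DrugTarget("IKur", ic50=8.0, n_h=1.3, units="uM"),))


def drug_ave0118(concentration: float = 6.0) -> DrugSpec:
    """AVE0118: blocks IKur (IC50 3.126 uM, nH 0.431) and Ito
    (IC50 5.45 mM -- note the millimolar units -- nH 0.385)."""
    return DrugSpec("AVE0118", concentration, (
        DrugTarget("IKur", ic50=3.126, n_h=0.431, units="uM"),
        DrugTarget("Ito", ic50=5.45, n_h=0.385, units="mM"),
    ))


DRUG_LIBRARY = {"4-AP": drug_4ap, "4AP": drug_4ap, "AVE0118": drug_ave0118}


def apply_drug(params: ParameterSet, drug: DrugSpec) -> ParameterSet:
    """Scale each targeted conductance by (1 - block fraction)."""
    factors = {}
    for channel, frac in drug.block_fractions().items():
        pname = CHANNEL_PARAMS.get(channel)
        if pname is None or pname not in CONDUCTANCE_NAMES:
            raise KeyError(f"unknown drug target channel {channel!r}")
        factors[pname] = factors.get(pname, 1.0) * (1.0 - frac)
    return params.scaled(**factors) if factors else params


def scale_conductances(params: ParameterSet, multipliers: dict) -> ParameterSet:
    """Pure multiplicative conductance scaling ({channel: factor})."""
    factors = {}
    for channel, f in multipliers.items():
        if f <= 0:
            raise ValueError(f"multiplier for {channel} must be > 0")
        pname = CHANNEL_PARAMS.get(channel, channel)
        if pname not in CONDUCTANCE_NAMES:
            raise KeyError(f"unknown channel {channel!r}")
        factors[pname] = factors.get(pname, 1.0) * f
    return params.scaled(**factors) if factors else params


# ---------------------------------------------------------------------------
# AF remodeling
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class RemodelingSpec:
    """Chronic-AF remodeling, applied as ordered multiplicative groups:
    electrical -> CaMKII -> mechano-calcium feedback -> SR Ca handling.

    Factor conventions: "down X%" multiplies by (1 - X/100); "up X%" with
    X < 100 multiplies by (1 + X/100); "up 200%" reads "increased to 200%",
    i.e. a factor of 2.  Each factor is stored explicitly and overridable.

    `case1_no_tnc_remodeling` skips the contraction/TnC factors;
    `case2_ikur_reversed` restores gKur to its SR value.  `gKur_factor`
    defaults to 0.5: whether AF reduces IKur varies across patients, and the
    "reversal" case only differs from full AF if the reduction is applied,
    so the full-AF default halves gKur (override to 1.0 to disable).
    """

    electrical: dict = field(default_factory=lambda: {
        "gNa": 0.9, "gCaL": 0.5, "gto": 0.2, "gKs": 2.0, "gK1": 2.0,
        "kNaCa": 1.4,
    })
    gKur_factor: float = 0.5
    camkii: dict = field(default_factory=lambda: {
        "CaMK0": 1.4, "alphaCaMK": 2.0, "betaCaMK": 0.5,
    })
    mcf: dict = field(default_factory=lambda: {
        "koff": 0.5, "gamma": 0.7, "TnCmax": 0.75,
        # slowed cross-bridge cycling (slow beta-myosin isoform shift):
        # both attachment and detachment rates halved
        "r0P": 0.5, "r0N": 0.5, "mufp0": 0.5,
    })
    sr_ca: dict = field(default_factory=lambda: {
        "RyRo_k": 0.5, "RyRc_k": 0.5, "kSRleak": 1.25, "k4": 0.8,
        "SERCAKmf": 1.15,
    })
    case1_no_tnc_remodeling: bool = False
    case2_ikur_reversed: bool = False

    def __post_init__(self):
        if self.case1_no_tnc_remodeling and self.case2_ikur_reversed:
            raise ValueError("case 1 and case 2 flags are mutually exclusive")
        for group in (self.electrical, self.camkii, self.mcf, self.sr_ca):
            for name, f in group.items():
                if f <= 0:
                    raise ValueError(f"remodeling factor {name} must be > 0")


def apply_af_remodeling(params_sr: ParameterSet,
                        spec: Optional[RemodelingSpec] = None) -> ParameterSet:
    """SR -> chronic-AF parameters via the incremental factor groups."""
    spec = spec or RemodelingSpec()
    p = params_sr
    electrical = dict(spec.electrical)
    if not spec.case2_ikur_reversed and spec.gKur_factor != 1.0:
        electrical["gKur"] = spec.gKur_factor
    p = p.scaled(**electrical)
    p = p.scaled(**spec.camkii)
    if not spec.case1_no_tnc_remodeling:
        p = p.scaled(**spec.mcf)
    p = p.scaled(**spec.sr_ca)
    return p


# ---------------------------------------------------------------------------
# afterdepolarization-substrate transforms
# ---------------------------------------------------------------------------
def apply_phase3_ina_mods(params: ParameterSet) -> ParameterSet:
    """Permit Na-channel reactivation during late repolarization:
    recovery-from-inactivation time constants x 1e-3 and the availability
    curve shifted +15 mV."""
    return params.with_updates(
        ina_recovery_scale=params.ina_recovery_scale * 1e-3,
        ina_avail_shift=params.ina_avail_shift + 15.0,
    )


def enable_ikach(params: ParameterSet, ach_conc: float) -> ParameterSet:
    """Activate the acetylcholine-gated K+ current at [ACh] (uM)."""
    if ach_conc < 0:
        raise ValueError("ACh concentration must be >= 0")
    if ach_conc == 0:
        return params
    return params.with_updates(ACh=ach_conc)


def sensitize_ryr_sr_gate(params: ParameterSet,
                          factor: float = 0.1) -> ParameterSet:
    """Reduce the slope of the SR-load dependence of RyR release
    (Ca2+ -> AP backward-coupling EAD substrate)."""
    if factor <= 0:
        raise ValueError("factor must be > 0")
    return params.with_updates(RyRsrca_k=params.RyRsrca_k * factor)


def clamp_current(model, channel: str, waveform, bcl: Optional[float] = None):
    """Model variant with `channel` ("ICaL" or "IKr") replaced by a recorded
    waveform, tiled periodically at `bcl`.

    `waveform` is either a ChannelClamp, or a Trace containing the channel
    (one steady-state beat; bcl then defaults to its duration).  The clamped
    current enters both the voltage equation and, for ICaL, the Ca influx
    bookkeeping; the channel's gates are still integrated but ignored.
    """
    from .model import CellModel, ChannelClamp
    from .trace import Trace
    if isinstance(waveform, ChannelClamp):
        clamp = waveform
    elif isinstance(waveform, Trace):
        if channel not in waveform:
            raise KeyError(f"waveform trace has no {channel!r} channel")
        t = waveform.t - waveform.t[0]
        if bcl is None:
            bcl = t[-1]
        clamp = ChannelClamp(channel, t, waveform[channel], bcl)
    else:
        t, i = waveform
        if bcl is None:
            bcl = float(np.asarray(t)[-1])
        clamp = ChannelClamp(channel, np.asarray(t), np.asarray(i), bcl)
    if not isinstance(model, CellModel):
        model = CellModel(model)
    return model.with_clamp(clamp)
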