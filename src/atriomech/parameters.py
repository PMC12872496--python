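"""Model parameters: the single home of every conductance, Ca-handling rate,
CaMKII constant and contraction parameter.

Defaults are the sinus-rhythm (SR) cell.  Conductance values already include
the update-phase rescalings of the K+ currents (the transient-outward
conductance carries a 1.5x and the rapid delayed-rectifier a 4x factor
relative to the parent formulation they were taken from), the IKr
inactivation slope of 13 mV, the CDI half-inactivation KCa = 0.68 uM, the
fast junctional RyR inactivation recovery (12 ms) and the restored RyR
adaptation limits (0.505 / 0.427).  Contraction defaults are the calibrated
column of the cross-bridge recalibration (gamma=20, kd0=6.29 pCa,
koff=kbasic=150 1/s, mufp0=16.65 1/s, mufp1=0.65, r0P=35, r0N=14 1/s,
alpha=25.184, alphaXB=4e3).
"""

from __future__ import annotations


import json
from typing import Iterator

import numpy as np

from ._layout import NPARAM, PARAM_NAMES

# parameters that scale a current linearly and may be drug/remodeling targets
CONDUCTANCE_NAMES = (
    "gNa", "gCaL", "gto", "gKur", "gKr", "gKs", "gK1", "kNaCa", "INaK_max",
    "gCab", "gNab", "IpCa_max", "gKACh",
)

_DEFAULTS = {
    # geometry / environment
    "Cm": 50.0,          # pF
    "Vss": 2.0,         # pL
    "Vbc": 6.1,          # pL
    "VSRss": 0.25,       # pL
    "VSRbc": 0.25,       # pL
    "Nao": 140.0,        # mM
    "Ko": 5.4,           # mM
    "Cao": 1.8,          # mM
    # sarcolemmal currents (A/F scale)
    "gNa": 7.8,
    "gCaL": 0.30,
    "gto": 0.05,       # carries the 1.5x update of the parent value
    "gKur": 0.040,
    "gKr": 0.096,       # carries the 4x update of the parent value
    "gKs": 0.129,
    "gK1": 0.07,
    "kNaCa": 2000.0,
    "INaK_max": 1.8,
    "gCab": 0.0015,
    "gNab": 0.00095,
    "IpCa_max": 0.5,
    "gKACh": 0.65,
    "KCa": 0.68,         # uM (CDI EC50, shifted right from 0.65)
    "ECaL_rev": 65.0,    # mV
    "kr_inact_vhalf": 25.0,
    "kr_inact_slope": 13.0,   # reduced for complete inactivation at +V
    "ina_recovery_scale": 1.0,
    "ina_avail_shift": 0.0,
    # RyR
    "RyRtauactss": 5.0,
    "RyRtauinactss": 12.0,    # fast recovery (was 450 in the parent)
    "RyRtauadapt": 1000.0,
    "RyRtauact": 18.75,
    "RyRtauinact": 87.5,
    "RyRa1ss": 0.505,
    "RyRa2ss": 0.427,
    "RyRo_k": 0.03,      # uM
    "RyRc_k": 0.01,      # uM
    "RyRsrca_vhalf": 0.3,  # mM
    "RyRsrca_k": 0.1,      # mM
    "nu_rel_ss": 0.012,
    "nu_rel_bc": 0.0015,
    "kSRleak": 8.0e-6,
    # SERCA
    "k4": 0.45,          # uM/ms
    "SERCAKmf": 0.25,    # uM
    "SERCAKmr": 1.3,    # mM
    # intracellular transport
    "tau_diff": 0.7,    # ms
    "tau_srdiff": 40.0,  # ms
    # passive buffers
    "Bss": 30.0, "KdBss": 0.5,
    "Bbc": 24.0, "KdBbc": 0.6,
    "CSQN": 6.7, "KmCSQN": 0.8,
    # CaMKII
    "CaMK0": 0.05,
    "alphaCaMK": 0.05,     # 1/ms
    "betaCaMK": 6.8e-4,    # 1/ms
    "KmCaM": 1.5,          # uM
    "camk_ryr_shift": 0.10,  # uM
    "camk_serca": 0.5,
    # interventions
    "ACh": 0.0,          # uM
    # stimulus
    "stim_amp": -40.0,   # A/F
    "stim_dur": 1.0,     # ms
    # contraction (calibrated)
    "gamma": 20.0,
    "kd0": 6.29,         # pCa
    "koff": 150.0,       # 1/s
    "kbasic": 150.0,     # 1/s
    "mufp0": 16.65,      # 1/s
    "mufp1": 0.65,
    "r0P": 35.0,         # 1/s
    "r0N": 14.0,         # 1/s
    "alpha": 25.184,
    "alphaXB": 4.0e3,
    "fXB": 0.02,
    "TnCmax": 70.0,      # uM
    "kd_scale": 1.0,
    "SL": 2.2,           # um
    "SL_ref": 2.2,
    "lda_slope": 0.6,    # pCa per um
    "x0_dist": 0.01,     # um
    "koff_ref": 150.0,   # 1/s
    "clamp_casr": 0.0,
    "clamp_cass": 0.0,
    "tau_fca": 10.0,      # ms
    "RyRo_off_ss": 0.22,  # uM
    "RyRo_off_bc": 0.10,  # uM
    "tau_f_scale": 0.629,
    "camk_leak": 0.5,
}

assert set(_DEFAULTS) == set(PARAM_NAMES)


class ParameterSet:
    """Immutable-by-convention mapping of model parameters.

    All transform operations (`with_updates`, drug application, remodeling)
    return copies; in-place mutation is reserved for construction.
    """

    __slots__ = ("_values",)

    def __init__(self, **overrides: float):
        values = dict(_DEFAULTS)
        for key, val in overrides.items():
            if key not in values:
                raise KeyError(f"unknown parameter {key!r}")
            values[key] = float(val)
        object.__setattr__(self, "_values", values)
        self.validate()

    # -- mapping / attribute access -------------------------------------
    def __getattr__(self, name: str) -> float:
        if name.startswith("_"):
            raise AttributeError(name)
        try:
            return self._values[name]
        except KeyError:
            raise AttributeError(name) from None

    def __getitem__(self, name: str) -> float:
        return self._values[name]

    def __iter__(self) -> Iterator[str]:
        return iter(PARAM_NAMES)

    def __eq__(self, other) -> bool:
        return isinstance(other, ParameterSet) and self._values == other._values

    def __repr__(self) -> str:
        return f"ParameterSet({len(PARAM_NAMES)} parameters)"

    def as_dict(self) -> dict:
        return dict(self._values)

    def with_updates(self, **updates: float) -> "ParameterSet":
        """Copy with the named parameters replaced."""
        vals = dict(self._values)
        for key, val in updates.items():
            if key not in vals:
                raise KeyError(f"unknown parameter {key!r}")
            vals[key] = float(val)
        new = object.__new__(type(self))
        object.__setattr__(new, "_values", vals)
        new.validate()
        return new

    def scaled(self, **factors: float) -> "ParameterSet":
        """Copy with the named parameters multiplied by the given factors."""
        return self.with_updates(
            **{k: self._values[k] * f for k, f in factors.items()})

    def validate(self) -> None:
        for name in CONDUCTANCE_NAMES:
            if self._values[name] < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        for name in ("koff", "kbasic", "mufp0", "r0P", "r0N", "k4",
                     "kSRleak", "nu_rel_ss", "nu_rel_bc", "ACh",
                     "RyRo_k", "RyRc_k", "TnCmax", "gamma"):
            if self._values[name] < 0:
                raise ValueError(f"rate/scale {name} must be >= 0")

    # -- kernel interface ------------------------------------------------
    def to_array(self) -> np.ndarray:
        return np.array([self._values[n] for n in PARAM_NAMES], dtype=float)

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(self._values, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterSet":
        return cls(**data)


def default_parameters() -> ParameterSet:
    """The calibrated sinus-rhythm parameter set."""
    return ParameterSet()
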