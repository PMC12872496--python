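"""Isolated contraction submodel: Ca2+-clamped force experiments.

Used to characterize the regulatory-unit / cross-bridge model on its own:
the fast solution-switching protocol (force development rate Kact after a
Ca2+ step, force redevelopment rate Ktr after a slack-restretch), and the
steady-state Ta-pCa relation.  Free Ca2+ is prescribed, not computed, so
these runs probe only the myofilament equations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import odeint
from scipy.optimize import curve_fit

from . import _kernels
from .parameters import ParameterSet


def _rhs(y, t, P, ca):
    d = _kernels.contraction_rates(ca, y[0], y[1], y[2], y[3], P, 0.0)
    return [d[0], d[1], d[2], d[3]]


def _tension(y, P):
    return _kernels.contraction_rates(0.0, y[0], y[1], y[2], y[3], P, 0.0)[4]


def relaxed_state(params: ParameterSet, ca: float = 0.1,
                  settle_ms: float = 20000.0) -> np.ndarray:
    """Contraction state equilibrated at the given free Ca (uM)."""
    P = params.to_array()
    y0 = np.array([1.0, 0.0, 0.0, params.x0_dist])
    t = np.array([0.0, settle_ms])
    return odeint(_rhs, y0, t, args=(P, ca))[-1]


def force_transient(params: ParameterSet, ca: float, y0=None,
                    duration_ms: float = 3000.0, dt: float = 1.0):
    """Integrate the clamped submodel at constant Ca; returns (t, Ta, y_end)."""
    P = params.to_array()
    if y0 is None:
        y0 = relaxed_state(params)
    t = np.arange(0.0, duration_ms + dt / 2, dt)
    ys = odeint(_rhs, np.asarray(y0, dtype=float), t, args=(P, float(ca)))
    ta = np.array([_tension(y, P) for y in ys])
    return t, ta, ys[-1]


def _monoexp_rate(t, f):
    """Rate constant (1/s) of a monoexponential fit f(t)=A(1-exp(-k t))+c."""
    f = np.asarray(f, dtype=float)
    fin = f[-1]
    f0 = f[0]
    if abs(fin - f0) < 1e-9:
        raise RuntimeError("no force development to fit")

    def model(tt, k, a, c):
        return c + a * (1.0 - np.exp(-k * tt * 1e-3))

    try:
        popt, _ = curve_fit(model, t, f,
                            p0=[10.0, fin - f0, f0], maxfev=10000)
    except RuntimeError as e:
        raise RuntimeError(f"monoexponential fit failed: {e}") from e
    k = float(popt[0])
    if not np.isfinite(k) or k <= 0:
        raise RuntimeError(f"monoexponential fit returned rate {k}")
    return k


@dataclass
class ContractionCalibration:
    """Results of the solution-switching characterization."""

    k_act: float          # force development rate after the Ca step (1/s)
    k_tr: float           # force redevelopment rate after slack (1/s)
    ta_max: float         # plateau tension at saturating Ca (kPa)
    pca_grid: np.ndarray
    ta_pca: np.ndarray    # steady-state tension over the pCa grid (kPa)
    pca50: float          # half-activation point of the Ta-pCa curve

    def as_dict(self) -> dict:
        return {"k_act": self.k_act, "k_tr": self.k_tr,
                "ta_max": self.ta_max, "pca50": self.pca50,
                "pca_grid": self.pca_grid.tolist(),
                "ta_pca": self.ta_pca.tolist()}


def ta_pca_curve(params: ParameterSet, pca_grid=None,
                 settle_ms: float = 20000.0):
    """Steady-state tension over a pCa grid at the parameter set's SL."""
    if pca_grid is None:
        pca_grid = np.arange(7.2, 4.79, -0.1)
    pca_grid = np.asarray(pca_grid, dtype=float)
    P = params.to_array()
    tas = []
    y = relaxed_state(params)
    # sweep from low to high Ca, re-equilibrating at each step
    for pca in sorted(pca_grid, reverse=True):
        ca = 10.0 ** (6.0 - pca)     # uM
        y = odeint(_rhs, y, [0.0, settle_ms], args=(P, ca))[-1]
        tas.append(_tension(y, P))
    order = np.argsort(pca_grid)[::-1]
    out = np.empty_like(pca_grid)
    out[order] = np.array(tas)
    return pca_grid, out


def half_activation_pca(pca_grid, ta) -> float:
    """pCa at half-maximal steady-state tension (linear interpolation)."""
    ta = np.asarray(ta, dtype=float)
    pca = np.asarray(pca_grid, dtype=float)
    order = np.argsort(pca)[::-1]         # increasing Ca
    pca, ta = pca[order], ta[order]
    half = ta.min() + 0.5 * (ta.max() - ta.min())
    above = np.where(ta >= half)[0]
    if len(above) == 0 or above[0] == 0:
        raise RuntimeError("Ta-pCa curve does not bracket half-activation")
    i = above[0]
    frac = (half - ta[i - 1]) / (ta[i] - ta[i - 1])
    return float(pca[i - 1] + frac * (pca[i] - pca[i - 1]))


def calibrate_contraction(params: ParameterSet,
                          ca_low: float = 0.1, ca_high: float = 316.0,
                          pca_grid=None) -> ContractionCalibration:
    """Fast solution-switching characterization of the contraction model.

    A Ca2+ step from `ca_low` to `ca_high` (uM) develops force at rate Kact;
    at saturating Ca2+ a slack-restretch detaches all cross-bridges and the
    force redevelops at rate Ktr.  Both rates come from monoexponential
    fits.  Also returns the Ta-pCa curve and its half-activation point.
    """
    # activation: step from the relaxed state
    y_rel = relaxed_state(params, ca=ca_low)
    t, ta, y_end = force_transient(params, ca_high, y0=y_rel,
                                   duration_ms=2000.0)
    k_act = _monoexp_rate(t, ta)
    ta_plateau = float(ta[-1])

    # slack test: detach every cross-bridge, keep thin-filament activation
    y_slack = y_end.copy()
    y_slack[2] = 0.0                      # attached fraction
    y_slack[3] = params.x0_dist           # distortion resets on restretch
    t2, ta2, _ = force_transient(params, ca_high, y0=y_slack,
                                 duration_ms=2000.0)
    k_tr = _monoexp_rate(t2, ta2)

    grid, curve = ta_pca_curve(params, pca_grid)
    pca50 = half_activation_pca(grid, curve)
    return ContractionCalibration(k_act=k_act, k_tr=k_tr, ta_max=ta_plateau,
                                  pca_grid=grid, ta_pca=curve, pca50=pca50)
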