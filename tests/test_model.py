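"""Cell-model invariants: gating bounds, conservation, current identities,
integration behavior."""

import numpy as np
import pytest

import atriomech as am
from atriomech._layout import (CONC_INDICES, GATE_INDICES, NSTATE,
                               PARAM_NAMES, STATE_NAMES)
from atriomech.model import CellModel, SolverOptions, StateVector
from atriomech.state import bootstrap_state


class TestLayout:
    def test_state_and_parameter_tables_consistent(self):
        assert len(STATE_NAMES) == NSTATE
        assert len(set(STATE_NAMES)) == NSTATE
        assert len(set(PARAM_NAMES)) == len(PARAM_NAMES)
        p = am.default_parameters()
        arr = p.to_array()
        for i, name in enumerate(PARAM_NAMES):
            assert arr[i] == p[name]


class TestDerivatives:
    def test_resting_fixed_point_has_small_derivatives(self, sr_model,
                                                       sr_state):
        # settle 20 s without stimulation, then every derivative ~ 0
        _, y = sr_model.integrate(sr_state, 20000.0, record=False)
        d = sr_model.derivatives(y)
        assert abs(d[0]) < 5e-3            # dVm/dt (mV/ms)
        for i in GATE_INDICES:
            assert abs(d[i]) < 1e-4
        for i in CONC_INDICES:
            assert abs(d[i]) < 1e-4

    def test_gate_at_zero_cannot_go_negative(self, sr_model, sr_state):
        y = sr_state.values.copy()
        for i in GATE_INDICES:
            yy = y.copy()
            yy[i] = 0.0
            d = sr_model.derivatives(StateVector(yy))
            assert d[i] >= 0.0

    def test_ru_occupancy_derivatives_conserve(self, sr_model, sr_state):
        # occupancies are (1-p, p): their derivatives cancel exactly
        d = sr_model.derivatives(sr_state)
        i_p = STATE_NAMES.index("RU_perm")
        assert (-d[i_p]) + d[i_p] == 0.0

    def test_nonfinite_state_identifies_field(self, sr_model, sr_state):
        y = sr_state.values.copy()
        y[STATE_NAMES.index("Ca_ss")] = np.nan
        with pytest.raises(ValueError, match="Ca_ss"):
            sr_model.derivatives(StateVector(y))


class TestCurrents:
    def test_ohmic_current_zero_at_reversal(self, sr_params, sr_state):
        # put Vm exactly at EK: all K currents with (V - EK) driving vanish
        y = sr_state.values.copy()
        ki, ko = y[STATE_NAMES.index("K_i")], sr_params.Ko
        ek = 26.712338 * np.log(ko / ki)
        y[0] = ek
        cur = CellModel(sr_params).currents(StateVector(y))
        for name in ("Ito", "IKur", "IKr", "IKs", "IK1"):
            assert cur[name] == pytest.approx(0.0, abs=1e-12)

    def test_ikur_linear_in_conductance(self, sr_params, sr_state):
        y = sr_state.values.copy()
        y[0] = 0.0     # depolarized, nonzero driving force
        c1 = CellModel(sr_params).currents(StateVector(y))
        half = sr_params.scaled(gKur=0.5)
        c2 = CellModel(half).currents(StateVector(y))
        assert c2["IKur"] == pytest.approx(0.5 * c1["IKur"])
        assert c2["INa"] == pytest.approx(c1["INa"])

    def test_ikach_zero_without_ach(self, sr_params, sr_state):
        for v in (-90.0, -40.0, 0.0):
            y = sr_state.values.copy()
            y[0] = v
            cur = CellModel(sr_params).currents(StateVector(y))
            assert cur["IKACh"] == 0.0
        p = am.enable_ikach(sr_params, 1.0)
        y = sr_state.values.copy()
        y[0] = -40.0
        assert CellModel(p).currents(StateVector(y))["IKACh"] > 0.0


class TestIntegration:
    def test_zero_duration_returns_initial_sample(self, sr_model, sr_state):
        tr, y = sr_model.integrate(sr_state, 0.0)
        assert len(tr.t) == 1
        assert np.allclose(y.values, sr_state.values)

    def test_unstimulated_rest_is_stable_for_ten_seconds(self, sr_model,
                                                         sr_state):
        _, y0 = sr_model.integrate(sr_state, 20000.0, record=False)
        tr, _ = sr_model.integrate(y0, 10000.0,
                                   solver=SolverOptions(dt_out=5.0))
        assert np.ptp(tr["Vm"]) < 0.5

    def test_single_beat_has_one_stimulus_artifact(self, sr_model, sr_state):
        tr, _ = sr_model.pace(sr_state, 1000.0, 1, with_currents=False)
        v = tr["Vm"]
        upstrokes = np.sum(np.diff((v > -20).astype(int)) == 1)
        assert len(tr.stim_times) == 1
        assert upstrokes == 1

    def test_integration_deterministic(self, sr_model, sr_state):
        tr1, y1 = sr_model.pace(sr_state, 1000.0, 2, with_currents=False)
        tr2, y2 = sr_model.pace(sr_state, 1000.0, 2, with_currents=False)
        assert np.array_equal(tr1["Vm"], tr2["Vm"])
        assert np.array_equal(y1.values, y2.values)

    def test_gating_bounds_and_positivity_along_trajectory(self, paced_trace):
        tr, yf = paced_trace
        for i in GATE_INDICES:
            g = tr.data[STATE_NAMES[i]]
            assert g.min() >= -1e-6 and g.max() <= 1.0 + 1e-6
        for i in CONC_INDICES:
            assert tr.data[STATE_NAMES[i]].min() > 0.0
        yf.check_invariants()

    def test_bcl_must_exceed_stimulus(self, sr_model, sr_state):
        with pytest.raises(ValueError):
            sr_model.pace(sr_state, 0.5, 1)


class TestConservation:
    def test_charge_bookkeeping(self, fine_beat):
        """Cm dVm/dt + sum(I_ion) + I_stim = 0 at every recorded sample.

        Checked numerically: the time-derivative of the recorded Vm matches
        -Itot away from the stimulus window.
        """
        tr, _, _ = fine_beat
        t, v, itot = tr.t, tr["Vm"], tr["Itot"]
        dvdt = np.gradient(v, t)
        m = (t - tr.stim_times[0] > 3.0)     # exclude the stimulus pulse
        resid = dvdt[m] + itot[m]
        scale = max(np.abs(dvdt).max(), 1.0)
        assert np.median(np.abs(resid)) < 1e-3 * scale
        assert np.percentile(np.abs(resid), 99) < 2e-2 * scale

    def test_calcium_mass_audit(self, fine_beat):
        """Net change in total cell Ca over one steady beat equals the
        integral of the transmembrane Ca fluxes within 1%."""
        tr, y0, yf = fine_beat
        p = am.default_parameters()

        def total_ca(state):
            s = dict(zip(STATE_NAMES, state.values))
            def buf(ca, b, kd):
                return b * ca / (kd + ca)
            amol = 0.0
            # free + fast buffer, ss and bc (uM * pL = amol)
            amol += (s["Ca_ss"] + buf(s["Ca_ss"], p.Bss, p.KdBss)) * p.Vss
            amol += (s["Ca_bc"] + buf(s["Ca_bc"], p.Bbc, p.KdBbc)) * p.Vbc
            amol += s["Ca_TnC"] * p.Vbc
            # SR pools in mM = 1000 uM
            for pool, vol in (("Ca_SRss", p.VSRss), ("Ca_SRbc", p.VSRbc)):
                ca = s[pool] * 1e3
                csq = p.CSQN * 1e3 * ca / (p.KmCSQN * 1e3 + ca)
                amol += (ca + csq) * vol
            return amol

        d_total = total_ca(yf) - total_ca(y0)
        # transmembrane Ca flux: A/F -> amol/ms via Cm/(2F), signs per the
        # bookkeeping convention (positive INaCa imports Ca)
        i_ca = (2.0 * tr["INaCa"] - tr["ICaL"] - tr["ICab"] - tr["IpCa"])
        influx = np.trapezoid(i_ca, tr.t) * p.Cm * 1e-3 / (2 * 96.4867) * 1e3
        scale = np.trapezoid(np.abs(tr["ICaL"]), tr.t) * p.Cm * 1e-3 \
            / (2 * 96.4867) * 1e3
        assert abs(d_total - influx) < 0.01 * scale


class TestSolverConvergence:
    def test_apd_stable_under_tolerance_tightening(self, sr_state):
        from atriomech import biomarkers as bm
        apds = []
        for scale in (1.0, 0.1):
            opts = SolverOptions(rtol=1e-6 * scale,
                                 atol_scale=1e-8 * scale, dt_out=0.1)
            model = CellModel(am.default_parameters(), solver=opts)
            _, y = model.pace(sr_state, 1000.0, 10, record_last=1,
                              with_currents=False)
            tr, _ = model.pace(y, 1000.0, 2, with_currents=False)
            apds.append(bm.analyze_beats(tr, bcl=1000.0)[-1].apd)
        assert abs(apds[1] - apds[0]) / apds[0] < 0.005


class TestInitialStates:
    @pytest.mark.parametrize("condition", am.CONDITIONS)
    def test_stored_states_satisfy_invariants(self, condition):
        am.initial_state(condition).check_invariants()

    def test_unknown_condition_rejected(self):
        with pytest.raises(KeyError):
            am.initial_state("ventricle")

    def test_af_diastolic_state_differs_from_sr(self, sr_state, af_state):
        assert af_state["Vm"] < sr_state["Vm"]   # hyperpolarized

    def test_sr_state_self_consistent_under_pacing(self, sr_model, sr_state):
        _, y = sr_model.pace(sr_state, 1000.0, 50, record_last=1,
                             with_currents=False)
        # slow ionic drift only: key fast states return close to start
        assert abs(y["Vm"] - sr_state["Vm"]) < 1.5
        assert abs(y["Ca_SRss"] - sr_state["Ca_SRss"]) < 0.1
        assert abs(y["Na_i"] - sr_state["Na_i"]) < 0.5
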