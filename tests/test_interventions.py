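"""Drug block, AF remodeling and substrate transforms (pure functions)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import atriomech as am
from atriomech.interventions import (
    CHANNEL_PARAMS, DrugSpec, DrugTarget, RemodelingSpec,
    apply_af_remodeling, apply_drug, apply_phase3_ina_mods, drug_4ap,
    drug_ave0118, enable_ikach, hill_block_fraction, scale_conductances,
    sensitize_ryr_sr_gate)


class TestHillBlock:
    def test_zero_concentration_blocks_nothing(self):
        assert hill_block_fraction(0.0, 8.0, 1.3) == 0.0

    @pytest.mark.parametrize("nh", [0.3, 1.0, 1.3, 4.0])
    def test_half_block_at_ic50(self, nh):
        assert hill_block_fraction(8.0, 8.0, nh) == pytest.approx(0.5)

    def test_4ap_block_fraction_on_ikur(self):
        # 5 uM against IC50 8 uM, nH 1.3: x^n/(x^n+1) with x = 5/8
        x = (5.0 / 8.0) ** 1.3
        assert hill_block_fraction(5.0, 8.0, 1.3) == \
            pytest.approx(x / (x + 1.0))
        assert hill_block_fraction(5.0, 8.0, 1.3) == \
            pytest.approx(0.35178, abs=1e-4)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(1e-3, 1e3), st.floats(1e-3, 1e3), st.floats(0.1, 5.0))
    def test_monotone_in_concentration(self, c, ic50, nh):
        f1 = hill_block_fraction(c, ic50, nh)
        f2 = hill_block_fraction(c * 1.5, ic50, nh)
        assert 0.0 <= f1 < f2 <= 1.0

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            hill_block_fraction(1.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            hill_block_fraction(1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            hill_block_fraction(-1.0, 1.0, 1.0)


class TestApplyDrug:
    def test_4ap_targets_only_ikur(self, sr_params):
        p = apply_drug(sr_params, drug_4ap(5.0))
        frac = hill_block_fraction(5.0, 8.0, 1.3)
        assert p.gKur == pytest.approx(sr_params.gKur * (1 - frac))
        changed = {k for k in sr_params if p[k] != sr_params[k]}
        assert changed == {"gKur"}

    def test_ave0118_blocks_ikur_and_ito_with_mm_units(self, sr_params):
        p = apply_drug(sr_params, drug_ave0118(6.0))
        f_kur = hill_block_fraction(6.0, 3.126, 0.431)
        f_to = hill_block_fraction(6.0e-3, 5.45, 0.385)  # conc in mM
        assert p.gKur == pytest.approx(sr_params.gKur * (1 - f_kur))
        assert p.gto == pytest.approx(sr_params.gto * (1 - f_to))
        assert f_to < 0.1 < f_kur      # mM-scale IC50 keeps Ito block small

    def test_zero_concentration_is_identity(self, sr_params):
        assert apply_drug(sr_params, drug_4ap(0.0)) == sr_params

    def test_unknown_target_channel_rejected(self, sr_params):
        bad = DrugSpec("x", 1.0, (DrugTarget("IBogus", 1.0, 1.0),))
        with pytest.raises(KeyError):
            apply_drug(sr_params, bad)

    def test_input_never_mutated(self, sr_params):
        before = sr_params.as_dict()
        apply_drug(sr_params, drug_4ap(5.0))
        assert sr_params.as_dict() == before


class TestAfRemodeling:
    def test_table_factors(self, sr_params):
        p = apply_af_remodeling(sr_params)
        assert p.gto == pytest.approx(0.2 * sr_params.gto)
        assert p.kNaCa == pytest.approx(1.4 * sr_params.kNaCa)
        assert p.gCaL == pytest.approx(0.5 * sr_params.gCaL)
        assert p.gKs == pytest.approx(2.0 * sr_params.gKs)
        assert p.gK1 == pytest.approx(2.0 * sr_params.gK1)
        assert p.gNa == pytest.approx(0.9 * sr_params.gNa)
        assert p.koff == pytest.approx(0.5 * sr_params.koff)
        assert p.gamma == pytest.approx(0.7 * sr_params.gamma)
        assert p.TnCmax == pytest.approx(0.75 * sr_params.TnCmax)
        assert p.RyRo_k == pytest.approx(0.5 * sr_params.RyRo_k)
        assert p.kSRleak == pytest.approx(1.25 * sr_params.kSRleak)
        assert p.k4 == pytest.approx(0.8 * sr_params.k4)
        assert p.SERCAKmf == pytest.approx(1.15 * sr_params.SERCAKmf)

    def test_identity_spec(self, sr_params):
        spec = RemodelingSpec(electrical={}, gKur_factor=1.0, camkii={},
                              mcf={}, sr_ca={})
        assert apply_af_remodeling(sr_params, spec) == sr_params

    def test_case1_skips_contractile_remodeling(self, sr_params):
        p = apply_af_remodeling(sr_params,
                                RemodelingSpec(case1_no_tnc_remodeling=True))
        assert p.TnCmax == sr_params.TnCmax
        assert p.koff == sr_params.koff
        assert p.gto == pytest.approx(0.2 * sr_params.gto)

    def test_case2_restores_ikur(self, sr_params):
        full = apply_af_remodeling(sr_params)
        case2 = apply_af_remodeling(
            sr_params, RemodelingSpec(case2_ikur_reversed=True))
        assert full.gKur == pytest.approx(0.5 * sr_params.gKur)
        assert case2.gKur == pytest.approx(sr_params.gKur)

    def test_conflicting_cases_rejected(self):
        with pytest.raises(ValueError):
            RemodelingSpec(case1_no_tnc_remodeling=True,
                           case2_ikur_reversed=True)


class TestScaleConductances:
    def test_single_channel(self, sr_params):
        p = scale_conductances(sr_params, {"GCaL": 3.0})
        assert p.gCaL == pytest.approx(3.0 * sr_params.gCaL)
        assert p.gKur == sr_params.gKur

    def test_af_case4_substrate(self, sr_params):
        p = scale_conductances(sr_params, {"GCaL": 5.0, "GKs": 0.6})
        assert p.gCaL == pytest.approx(5.0 * sr_params.gCaL)
        assert p.gKs == pytest.approx(0.6 * sr_params.gKs)

    def test_empty_map_identity(self, sr_params):
        assert scale_conductances(sr_params, {}) == sr_params

    def test_unknown_channel_rejected(self, sr_params):
        with pytest.raises(KeyError):
            scale_conductances(sr_params, {"IFunny": 2.0})

    def test_commutes_with_drug(self, sr_params):
        a = apply_drug(scale_conductances(sr_params, {"GKur": 0.7}),
                       drug_4ap(5.0))
        b = scale_conductances(apply_drug(sr_params, drug_4ap(5.0)),
                               {"GKur": 0.7})
        for k in a:
            assert a[k] == pytest.approx(b[k])


class TestSubstrateTransforms:
    def test_phase3_ina_mods(self, sr_params):
        p = apply_phase3_ina_mods(sr_params)
        assert p.ina_recovery_scale == pytest.approx(1e-3)
        assert p.ina_avail_shift == pytest.approx(15.0)
        # only those two fields change
        changed = {k for k in sr_params if p[k] != sr_params[k]}
        assert changed == {"ina_recovery_scale", "ina_avail_shift"}

    def test_availability_curve_is_a_pure_shift(self, sr_params):
        from atriomech.model import CellModel, StateVector
        from atriomech.state import bootstrap_state
        m0 = CellModel(sr_params)
        m1 = CellModel(sr_params.with_updates(ina_avail_shift=15.0))
        y = bootstrap_state().values
        # steady-state availability at V equals shifted availability at V+15
        def h_inf(model, v):
            yy = y.copy()
            yy[0] = v
            yy[2] = 0.5
            d = model.derivatives(StateVector(yy))
            # reconstruct h_inf from dh/dt = (hinf - h)/tau at two h values
            yy2 = yy.copy()
            yy2[2] = 0.25
            d2 = model.derivatives(StateVector(yy2))
            # dh/dt = (hinf - h)/tau -> linear in h
            slope = (d2[2] - d[2]) / (0.25 - 0.5)
            return 0.5 + d[2] / slope
        for v in (-80.0, -65.0, -50.0):
            assert h_inf(m1, v + 15.0) == pytest.approx(h_inf(m0, v),
                                                        abs=1e-6)

    def test_ikach_identity_at_zero_ach(self, sr_params):
        assert enable_ikach(sr_params, 0.0) == sr_params
        p = enable_ikach(sr_params, 1.0)
        assert p.ACh == 1.0

    def test_ryr_sr_gate_sensitization(self, sr_params):
        p = sensitize_ryr_sr_gate(sr_params, 0.1)
        assert p.RyRsrca_k == pytest.approx(0.1 * sr_params.RyRsrca_k)

    def test_channel_alias_map_covers_scan_notation(self):
        for label in ("GCaL", "GKur", "GKs", "IKur", "Ito", "IKr"):
            assert CHANNEL_PARAMS[label] in am.default_parameters().as_dict()
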