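"""Isolated contraction submodel: solution-switching and Ta-pCa."""

import numpy as np
import pytest

import atriomech as am
from atriomech import contraction as ct


@pytest.fixture(scope="module")
def calibration():
    return ct.calibrate_contraction(am.default_parameters())


class TestSolutionSwitching:
    def test_rates_positive(self, calibration):
        assert calibration.k_act > 0
        assert calibration.k_tr > 0

    def test_force_redevelops_to_preslack_plateau(self):
        p = am.default_parameters()
        y_rel = ct.relaxed_state(p, ca=0.1)
        _, ta1, y_end = ct.force_transient(p, 316.0, y0=y_rel,
                                           duration_ms=4000.0)
        y_slack = y_end.copy()
        y_slack[2] = 0.0
        y_slack[3] = p.x0_dist
        _, ta2, _ = ct.force_transient(p, 316.0, y0=y_slack,
                                       duration_ms=4000.0)
        assert ta2[-1] == pytest.approx(ta1[-1], rel=0.01)

    def test_subthreshold_ca_develops_no_force(self, calibration):
        p = am.default_parameters()
        _, ta, _ = ct.force_transient(p, 0.1, duration_ms=3000.0)
        assert ta[-1] < 0.01 * calibration.ta_max


class TestTaPca:
    def test_half_activation_near_calibrated_ec50(self, calibration):
        assert calibration.pca50 == pytest.approx(
            am.default_parameters().kd0, abs=0.15)

    def test_curve_monotone_in_ca(self, calibration):
        # decreasing pCa = increasing Ca -> non-decreasing tension
        order = np.argsort(calibration.pca_grid)[::-1]
        ta = calibration.ta_pca[order]
        assert np.all(np.diff(ta) >= -1e-6 * calibration.ta_max)

    def test_desensitizing_interventions_shift_ec50_right(self):
        p = am.default_parameters()
        base = ct.half_activation_pca(*ct.ta_pca_curve(p))
        kd_up = ct.half_activation_pca(
            *ct.ta_pca_curve(p.with_updates(kd_scale=1.5)))
        short_sl = ct.half_activation_pca(
            *ct.ta_pca_curve(p.with_updates(SL=1.7)))
        assert kd_up < base          # lower pCa50 = desensitized
        assert short_sl < base
        assert kd_up == pytest.approx(base - np.log10(1.5), abs=0.06)

    def test_af_remodeling_sensitizes(self):
        p = am.default_parameters()
        base = ct.half_activation_pca(*ct.ta_pca_curve(p))
        af = ct.half_activation_pca(
            *ct.ta_pca_curve(am.apply_af_remodeling(p)))
        assert af > base
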