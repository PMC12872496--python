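"""Classifier and biomarker extraction on analytically known waveforms."""

import numpy as np
import pandas as pd
import pytest

from atriomech import biomarkers as bm
from atriomech import fixtures as fx


class TestApd:
    def test_trapezoid_apd_matches_geometry(self):
        tr, truth = fx.make_fixture_waveforms("trapezoid_AP")
        beats = bm.analyze_beats(tr)
        for b in beats:
            assert b.apd == pytest.approx(truth["apd90"], abs=2.0)

    def test_full_repolarization_fraction_gives_full_duration(self):
        tr, truth = fx.make_fixture_waveforms("trapezoid_AP")
        cfg = bm.BiomarkerConfig(repol_fraction=0.999)
        beats = bm.analyze_beats(tr, cfg)
        assert beats[0].apd == pytest.approx(truth["apd_full"], abs=2.0)

    def test_apd_monotone_in_repol_fraction(self):
        tr, _ = fx.make_fixture_waveforms("trapezoid_AP")
        apds = []
        for frac in (0.3, 0.5, 0.7, 0.9):
            beats = bm.analyze_beats(tr, bm.BiomarkerConfig(
                repol_fraction=frac))
            apds.append(beats[0].apd)
        assert all(a < b for a, b in zip(apds, apds[1:]))

    def test_determinism_identical_beats_identical_apd(self):
        tr, _ = fx.make_fixture_waveforms("trapezoid_AP", n_beats=5)
        apds = [b.apd for b in bm.analyze_beats(tr)][1:]  # beat 0 lacks a
        # pre-stimulus diastole, so compare the fully equivalent beats
        assert max(apds) - min(apds) < 1e-9


class TestClassifier:
    def test_monotone_repolarization_is_normal(self):
        tr, truth = fx.make_fixture_waveforms("trapezoid_AP", n_beats=6)
        assert bm.classify_beats(tr) == truth["labels"]

    def test_plateau_bump_every_beat_is_ead(self):
        tr, truth = fx.make_fixture_waveforms(
            "bump_AP", bump_beats=tuple(range(6)))
        assert bm.classify_beats(tr) == ["EAD"] * 6

    def test_bump_on_alternating_beats_is_a_ead(self):
        tr, truth = fx.make_fixture_waveforms("alternans_AP")
        labels = bm.classify_beats(tr)
        assert labels == truth["labels"]
        assert "A-EAD" in labels and "EAD" not in labels

    def test_dad_train_detected_with_amplitude(self):
        tr, truth = fx.make_fixture_waveforms("dad_train", amplitude=2.0)
        beats = bm.analyze_beats(tr)
        assert [b.label for b in beats] == truth["labels"]
        for b in beats:
            assert b.dad_amplitude == pytest.approx(2.0, rel=0.2)

    def test_subthreshold_dad_not_counted(self):
        tr, _ = fx.make_fixture_waveforms("dad_train", amplitude=0.5)
        assert bm.classify_beats(tr) == ["normal"] * 4

    def test_repolarization_failure(self):
        tr, truth = fx.make_fixture_waveforms("rf_AP")
        labels = bm.classify_beats(tr)
        assert labels[1:] == truth["labels"][1:]

    def test_classifier_invariant_to_time_translation(self):
        tr, _ = fx.make_fixture_waveforms("alternans_AP")
        shifted = type(tr)(tr.t + 5000.0, dict(tr.data), dict(tr.units),
                           tr.stim_times + 5000.0)
        assert bm.classify_beats(tr) == bm.classify_beats(shifted)

    def test_classifier_invariant_to_finer_sampling(self):
        a, _ = fx.make_fixture_waveforms("alternans_AP", dt=0.2)
        b, _ = fx.make_fixture_waveforms("alternans_AP", dt=0.1)
        assert bm.classify_beats(a) == bm.classify_beats(b)

    def test_aggregate_label_precedence(self):
        assert bm.aggregate_label(["normal", "RF", "EAD"]) == "RF"
        assert bm.aggregate_label(["EAD", "DAD"]) == "EAD"
        assert bm.aggregate_label(["DAD", "normal"]) == "DAD"
        assert bm.aggregate_label(["normal"] * 3) == "normal"


class TestTakeoffPotential:
    def test_constructed_phase3_bump_takeoff(self):
        # bump injected late in repolarization, starting near -50 mV
        tr, _ = fx.make_fixture_waveforms(
            "bump_AP", bump_beats=(0, 1, 2, 3), bump_at_ms=270.0,
            bump_amp=25.0, plateau_ms=200.0, repol_ms=100.0)
        beats = bm.analyze_beats(tr)
        takeoff = bm.takeoff_potential(beats)
        # repolarization runs 20 -> -80 mV over 100 ms starting at 202 ms,
        # so the bump takes off from the linear ramp value at 270 ms
        v_at_takeoff = 20.0 - 100.0 * (270.0 - 202.0) / 100.0
        assert takeoff == pytest.approx(v_at_takeoff, abs=4.0)

    def test_normal_beat_has_no_takeoff(self):
        tr, _ = fx.make_fixture_waveforms("trapezoid_AP")
        assert np.isnan(bm.takeoff_potential(bm.analyze_beats(tr)))


class TestDelta:
    def _table(self, apd):
        return pd.DataFrame({"bcl": [2000.0, 1000.0], "apd": apd})

    def test_identical_inputs_give_zero(self):
        d = bm.delta(self._table([200.0, 180.0]), self._table([200.0, 180.0]))
        assert (d["delta_apd"] == 0).all()

    def test_antisymmetry(self):
        a, b = self._table([210.0, 170.0]), self._table([200.0, 180.0])
        d1 = bm.delta(a, b)
        d2 = bm.delta(b, a)
        assert np.allclose(d1["delta_apd"], -d2["delta_apd"])

    def test_missing_propagates(self):
        d = bm.delta(self._table([np.nan, 170.0]), self._table([200.0, 180.0]))
        assert np.isnan(d["delta_apd"].iloc[0])

    def test_mismatched_tables_rejected(self):
        with pytest.raises(ValueError):
            bm.delta(self._table([1.0, 2.0]),
                     pd.DataFrame({"bcl": [500.0], "apd": [1.0]}))
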