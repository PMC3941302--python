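"""Generator properties: keystroke shapes, round trips, study structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import pianism as pm
from pianism.features import note_features
from pianism.segment import detect_keystrokes


def _percussiveness_oracle(gamma):
    """Numerical integration of the normalized continuous attack trajectory."""
    val, _ = quad(lambda u: u**gamma, 0.0, 1.0)
    return val


def _extract_single(depth, t_attack, gamma, rate=500.0, sustain=300.0, release=80.0):
    start, seg = pm.synthesize_keystroke(100.0, depth, t_attack, gamma, sustain, release, rate)
    trace = np.zeros(start + len(seg) + 50, dtype=np.int16)
    trace[start : start + len(seg)] = seg
    (event,) = detect_keystrokes(trace, rate)
    pedals = {"soft": np.zeros_like(trace), "sust": np.zeros_like(trace)}
    return event, note_features(event, trace, pedals, 1000.0 / rate)


class TestKeystroke:
    def test_linear_attack_is_half(self):
        """A linear ramp has percussiveness 0.5 (within quantization)."""
        _, feats = _extract_single(200.0, 100.0, 1.0)
        assert feats["percussiveness"] == pytest.approx(0.5, abs=0.02)

    def test_linear_attack_speed(self):
        _, feats = _extract_single(200.0, 100.0, 1.0)
        assert feats["attack_speed"] == pytest.approx(2.0, rel=0.06)

    @pytest.mark.parametrize("gamma", [0.5, 1.0, 2.0])
    def test_power_law_area_matches_integration_oracle(self, gamma):
        """Extracted percussiveness equals the oracle area 1/(gamma+1)."""
        oracle = _percussiveness_oracle(gamma)
        assert oracle == pytest.approx(1.0 / (gamma + 1.0), abs=1e-9)
        _, feats = _extract_single(250.0, 50.0, gamma)
        assert feats["percussiveness"] == pytest.approx(oracle, abs=0.02)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            pm.synthesize_keystroke(0, 0, 100, 1, 100, 50)
        with pytest.raises(ValueError):
            pm.synthesize_keystroke(0, 300, 100, 1, 100, 50)
        with pytest.raises(ValueError):
            pm.synthesize_keystroke(0, 200, -5, 1, 100, 50)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        depth=st.floats(21, 250),
        t_attack=st.floats(10, 300),
        gamma=st.floats(0.2, 4.0),
        sustain=st.floats(0, 800),
        release=st.floats(10, 200),
    )
    def test_trace_quantized_in_range(self, depth, t_attack, gamma, sustain, release):
        start, seg = pm.synthesize_keystroke(50.0, depth, t_attack, gamma, sustain, release)
        assert seg.dtype == np.int16
        assert seg.min() >= 0 and seg.max() <= 250
        # the apex is quantized to one step; with a short hold it may also
        # fall between two samples of a steep attack/release pair
        assert int(seg.max()) <= int(np.ceil(depth))
        if sustain >= 4.0:
            assert abs(int(seg.max()) - depth) <= 1


class TestPerformanceRoundTrip:
    def test_profile_parameters_recovered(self, fixed_score, clean_profile):
        """Noise-free profile parameters survive the extractor round trip."""
        rec = pm.synthesize_performance(fixed_score, clean_profile, seed=0)
        row = pm.extract_performance(rec, fixed_score)
        assert row["all.mhv_cmean_pmean"] == pytest.approx(125.0, abs=1.0)
        assert row["all.amax_cmean_pmean"] == pytest.approx(200.0, abs=1.0)
        assert row["all.percussiveness_cmean_pmean"] == pytest.approx(0.5, abs=0.02)
        assert row["all.melody_lead_pmean"] == pytest.approx(20.0, abs=2.0)
        # attack duration follows from the MHV coupling: K * D / MHV
        expected_attack = pm.synth.K_MHV * 200.0 / 125.0
        assert row["all.attack_duration_cmean_pmean"] == pytest.approx(expected_attack, abs=3.0)

    def test_articulation_offset_recovered(self, fixed_score, clean_profile):
        """articulation_offset = -50 ms shows up as legato of about -50 ms."""
        rec = pm.synthesize_performance(fixed_score, clean_profile, seed=0)
        row = pm.extract_performance(rec, fixed_score)
        assert row["all.articulation_same_hand_pmean"] == pytest.approx(-50.0, abs=5.0)

    def test_tempo_scale_doubles_ioi(self, fixed_score, clean_profile):
        import dataclasses

        slow = dataclasses.replace(clean_profile, tempo_scale=2.0)
        r1 = pm.extract_performance(
            pm.synthesize_performance(fixed_score, clean_profile, seed=0), fixed_score
        )
        r2 = pm.extract_performance(
            pm.synthesize_performance(fixed_score, slow, seed=0), fixed_score
        )
        assert r2["all.ioi_next_pmean"] == pytest.approx(
            2.0 * r1["all.ioi_next_pmean"], rel=0.01
        )

    def test_unused_soft_pedal_gives_zero_features(self, fixed_score, clean_profile):
        """use_prob = 0 leaves every soft-pedal feature exactly 0."""
        rec = pm.synthesize_performance(fixed_score, clean_profile, seed=0)
        row = pm.extract_performance(rec, fixed_score)
        soft = {k: v for k, v in row.items() if ".soft" in k}
        assert soft and all(v == 0.0 for v in soft.values() if v == v)

    def test_mhv_monotone_in_profile_mean(self, fixed_score, clean_profile):
        import dataclasses

        extracted = []
        for mhv in (80.0, 120.0, 180.0):
            prof = dataclasses.replace(clean_profile, mhv_mean=mhv)
            rec = pm.synthesize_performance(fixed_score, prof, seed=0)
            row = pm.extract_performance(rec, fixed_score)
            extracted.append(row["all.mhv_cmean_pmean"])
        assert extracted[0] < extracted[1] < extracted[2]

    def test_restrike_leaves_rest_gap(self, clean_profile):
        """Re-striking a key under legato still yields two separate events."""
        chords = (
            pm.ScoreChord(0.0, ((60, "right"),)),
            pm.ScoreChord(400.0, ((60, "right"),)),
        )
        score = pm.ScoreSpec(chords, nominal_duration_ms=900.0)
        rec = pm.synthesize_performance(score, clean_profile, seed=0)
        events = detect_keystrokes(rec.key_traces[60], rec.rate, pitch=60)
        assert len(events) == 2
        assert events[1].onset > events[0].offset


class TestStudy:
    def test_default_design_is_240(self):
        assert pm.StudyDesign().total == 240

    def test_minimal_design_single_recording(self):
        design = pm.StudyDesign(pianists=1, pieces=1, timbres=("bright",),
                                repetitions=1, seed=0)
        profiles = {"A": pm.default_profiles()["A"]}
        out = pm.generate_study(design, profiles)
        assert len(out) == 1

    def test_profile_count_mismatch_rejected(self):
        design = pm.StudyDesign(pianists=3, pieces=1, timbres=("bright",), repetitions=1)
        with pytest.raises(ValueError, match="profiles"):
            pm.generate_study(design, pm.default_profiles())

    def test_same_seed_reproduces_feature_table(self, small_study, small_table):
        import pandas as pd

        design = pm.StudyDesign(pianists=4, pieces=2, timbres=("bright", "dark"),
                                repetitions=3, seed=11)
        from .conftest import small_profiles

        modulation = pm.TimbreModulation(
            offsets={"bright": {"mhv_mean": 15}, "dark": {"mhv_mean": -15}},
            interaction={("D", "dark"): {"mhv_mean": 45}},
        )
        again = pm.build_feature_table(
            pm.generate_study(design, small_profiles(), modulation)
        )
        pd.testing.assert_frame_equal(small_table, again)

    def test_timbre_modulation_respects_bounds(self):
        prof = pm.PianistProfile(name="Z", mhv_mean=240.0)
        mod = pm.TimbreModulation(offsets={"bright": {"mhv_mean": 100}})
        assert mod.apply(prof, "bright").mhv_mean == 250.0
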