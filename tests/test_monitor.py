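"""COP region semantics, frame assessment, lean feedback and the session machine."""

import json
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mabumat as mm
from mabumat.frame import CopPoint
from mabumat.monitor import SEVERITIES


class TestCopRegionTest:
    def test_zero_displacement_inside_for_any_alpha(self):
        ref = CopPoint(500.0, 250.0)
        for alpha in (0.1, 40.0, 500.0):
            for mode in ("box", "circle"):
                r = mm.cop_region_test(ref, ref, alpha, mode)
                assert r.inside and r.d == 0.0

    def test_box_mode_strict_bounds(self):
        ref = CopPoint(500.0, 250.0)
        inside = mm.cop_region_test(CopPoint(530.0, 250.0), ref, 40.0, "box")
        assert inside.inside                       # 460 < 530 < 540
        outside = mm.cop_region_test(CopPoint(541.0, 250.0), ref, 40.0, "box")
        assert not outside.inside                  # 540 < 541
        boundary = mm.cop_region_test(CopPoint(540.0, 250.0), ref, 40.0, "box")
        assert not boundary.inside                 # strict: d == 1 is outside

    @given(dx=st.floats(-100, 100), dy=st.floats(-100, 100),
           rx=st.floats(100, 900), ry=st.floats(50, 450),
           alpha=st.floats(1, 80))
    def test_box_matches_per_axis_check_and_circle_subset(self, dx, dy, rx, ry, alpha):
        ref = CopPoint(rx, ry)
        cop = CopPoint(rx + dx, ry + dy)
        box = mm.cop_region_test(cop, ref, alpha, "box")
        circle = mm.cop_region_test(cop, ref, alpha, "circle")
        manual = (ref.x - alpha < cop.x < ref.x + alpha
                  and ref.y - alpha < cop.y < ref.y + alpha)
        assert box.inside == manual
        if circle.inside:
            assert box.inside          # circle region is contained in the box

    @given(dx=st.floats(-100, 100), dy=st.floats(-100, 100),
           a1=st.floats(1, 100), a2=st.floats(1, 100))
    def test_monotone_in_alpha(self, dx, dy, a1, a2):
        lo, hi = sorted((a1, a2))
        ref = CopPoint(500.0, 250.0)
        cop = CopPoint(500.0 + dx, 250.0 + dy)
        for mode in ("box", "circle"):
            if mm.cop_region_test(cop, ref, lo, mode).inside:
                assert mm.cop_region_test(cop, ref, hi, mode).inside


class TestLeanSeverity:
    @pytest.mark.parametrize("d, expected", [
        (0.0, "balanced"), (0.4, "balanced"), (0.41, "slight"), (0.75, "slight"),
        (0.8, "severe"), (0.999, "severe"), (1.0, "broken"), (1.2, "broken"),
    ])
    def test_bands(self, d, expected):
        assert mm.lean_severity(d) == expected
        assert expected in SEVERITIES

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            mm.lean_severity(-0.1)


class TestAssessFrame:
    def test_calibration_frame_is_good(self, ideal_frame, ideal_profile,
                                       thresholds, config):
        a = mm.assess_frame(ideal_frame, ideal_profile, thresholds, config)
        assert a.state == "Ms"
        assert not a.flags
        assert a.lean_severity == "balanced"

    def test_state_poor_iff_flags(self, ideal_profile, thresholds, config, beta):
        for lean in ((0.0, 0.0), (30.0, 0.0), (90.0, 0.0)):
            frame, _ = mm.synth_frame(mm.StanceSpec(lean_vector_mm=lean,
                                                    noise_sd=0.0), config)
            a = mm.assess_frame(mm.filter_frame(frame, beta), ideal_profile,
                                thresholds, config)
            assert (a.state == "Mp") == bool(a.flags)

    def test_lean_left_beyond_alpha_flags_overall_cop(self, ideal_profile,
                                                      thresholds, config, beta):
        frame, _ = mm.synth_frame(
            mm.StanceSpec(lean_vector_mm=(-60.0, 0.0), noise_sd=0.0), config)
        a = mm.assess_frame(mm.filter_frame(frame, beta), ideal_profile,
                            thresholds, config)
        assert a.state == "Mp"
        assert "cop_overall" in a.flags
        assert a.lean_direction[0] < -0.8       # pointing left
        assert a.lean_severity == "broken"

    def test_translated_foot_flags_position(self, ideal_profile, thresholds,
                                            config, beta):
        from mabumat.simulator import StanceSpec, _render, _quantize
        field, _ = _render(StanceSpec(noise_sd=0.0), config,
                           foot_shift_mm=(80.0, 0.0))
        frame = mm.PressureFrame(_quantize(field, config))
        a = mm.assess_frame(mm.filter_frame(frame, beta), ideal_profile,
                            thresholds, config)
        assert "foot_position" in a.flags

    def test_mirror_symmetry_swaps_left_right(self, thresholds, config, beta):
        spec = mm.StanceSpec(lr_split=0.55, toe_angle_left_deg=14.0,
                             toe_angle_right_deg=22.0, lean_vector_mm=(35.0, 0.0),
                             noise_sd=0.0)
        calib_spec = mm.StanceSpec(lr_split=0.55, toe_angle_left_deg=14.0,
                                   toe_angle_right_deg=22.0, noise_sd=0.0)
        calib, _ = mm.synth_frame(calib_spec, config)
        frame, _ = mm.synth_frame(spec, config)
        calib_f = mm.filter_frame(calib, beta)
        frame_f = mm.filter_frame(frame, beta)
        profile = mm.calibrate(calib_f, thresholds, config)
        profile_m = mm.calibrate(mm.mirror_frame(calib_f), thresholds, config)
        a = mm.assess_frame(frame_f, profile, thresholds, config)
        a_m = mm.assess_frame(mm.mirror_frame(frame_f), profile_m, thresholds, config)
        swap = {"cop_left": "cop_right", "cop_right": "cop_left"}
        assert {swap.get(f, f) for f in a.flags} == set(a_m.flags)
        assert a_m.displacement_norm == pytest.approx(a.displacement_norm, abs=1e-9)
        assert a_m.lean_direction[0] == pytest.approx(-a.lean_direction[0], abs=1e-9)


class TestSessionMachine:
    @staticmethod
    def _assessment(state, t_ms=0, flags=()):
        return mm.FrameAssessment(state=state, flags=frozenset(flags),
                                  lean_severity="balanced" if state == "Ms" else "broken",
                                  lean_direction=(0.0, 0.0),
                                  displacement_norm=0.0 if state == "Ms" else 1.5,
                                  timestamp_ms=t_ms)

    def _training_record(self, fps=20.0):
        return mm.SessionRecord(fps=fps, state="TRAINING")

    def test_600_good_frames_is_30_seconds(self):
        record = self._training_record()
        for k in range(600):
            mm.session_step(self._assessment("Ms", t_ms=50 * k), record)
        assert record.good_duration_s == 30.0
        assert record.state == "TRAINING"

    def test_first_poor_frame_breaks_and_freezes_timer(self):
        record = self._training_record()
        for k in range(100):
            mm.session_step(self._assessment("Ms", t_ms=50 * k), record)
        events = mm.session_step(self._assessment("Mp", t_ms=5000,
                                                  flags=["cop_overall"]), record)
        assert record.state == "BROKEN"
        assert record.break_time_s == 5.0
        assert any(e["event"] == "notification" for e in events)
        assert record.final_level == 0 and record.final_group == "beginner"
        # timer frozen: further steps are warnings, duration unchanged
        events = mm.session_step(self._assessment("Ms", t_ms=5050), record)
        assert events[0]["event"] == "warning"
        assert record.good_duration_s == 5.0

    def test_poor_on_first_frame_breaks_immediately(self):
        record = self._training_record()
        mm.session_step(self._assessment("Mp", flags=["cop_left"]), record)
        assert record.state == "BROKEN"
        assert record.break_time_s == 0.0

    def test_debounce_tolerates_short_excursions(self):
        params = mm.MonitorParams(debounce_frames=3)
        record = self._training_record()
        for state in ("Ms", "Mp", "Mp", "Ms", "Mp", "Mp"):
            mm.session_step(self._assessment(state), record, params)
        assert record.state == "TRAINING"  # never three poor frames in a row
        mm.session_step(self._assessment("Mp"), record, params)  # third in a row
        assert record.state == "BROKEN"


class TestRunSession:
    def test_scripted_hold_recovers_duration_and_breaks(self, thresholds, config):
        script = mm.SessionScript(fps=20.0, hold_s=10.0, break_at_s=6.0,
                                  break_mode="lean_out", seed=5)
        frames, truth = mm.synth_session(mm.StanceSpec(noise_sd=8.0, seed=5),
                                         script, config)
        record, events = mm.run_session(frames, thresholds, config)
        assert record.state == "BROKEN"
        assert record.break_time_s == pytest.approx(truth.break_at_s, abs=1 / 20.0)

    def test_stream_never_passing_entry_aborts(self, thresholds, config):
        frames = [mm.synth_frame(mm.StanceSpec(stance_width_mm=250.0,
                                               noise_sd=0.0), config)[0]
                  for _ in range(5)]
        record, events = mm.run_session(frames, thresholds, config)
        assert record.state == "ABORTED"
        assert events[-1]["event"] == "aborted"

    def test_replaying_stream_gives_byte_identical_logs(self, thresholds, config,
                                                        tmp_path):
        script = mm.SessionScript(fps=20.0, hold_s=6.0, break_at_s=3.0, seed=9)
        frames, _ = mm.synth_session(mm.StanceSpec(noise_sd=8.0, seed=9),
                                     script, config)
        p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        mm.run_session(frames, thresholds, config, log_path=p1)
        mm.run_session(frames, thresholds, config, log_path=p2)
        assert p1.read_bytes() == p2.read_bytes()
        lines = p1.read_text().splitlines()
        assert all(json.loads(line) for line in lines)
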