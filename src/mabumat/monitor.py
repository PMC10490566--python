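"""Real-time stance monitoring: good/poor classification, flags, feedback, timer.

Each training frame Mt is compared against the calibration profile.  The
stance is *good* (Ms) while every monitored quantity stays inside its valid
region and *poor* (Mp) as soon as any virtual flag is raised:

``cop_overall`` / ``cop_left`` / ``cop_right``
    the corresponding center of pressure left the region of radius alpha
    around its calibrated reference.  In box mode the region is the per-axis
    band ref - alpha < value < ref + alpha on x and y (strict bounds, so a
    displacement of exactly alpha is already outside); in circle mode it is
    the Euclidean disc of radius alpha.
``foot_position``
    a foot centroid drifted more than ``pos_drift_mm`` from its reference.
``foot_orientation``
    a toe angle left the allowed outward range or drifted more than
    ``angle_drift_deg`` from its calibrated value.
``lr_imbalance``
    the left/right load balance exceeded its threshold.

The normalised displacement d (max over the three COPs) drives the four-band
feedback: balanced (grey), slight lean (yellow), severe lean (red), broken
(the avatar falls).  The session state machine accumulates held time at the
stream's frame rate and freezes the timer at the first (debounced) poor
frame, which is terminal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .calibration import CalibrationProfile, calibrate, detect_feet, validate_entry_stance
from .config import (DEFAULT_ALPHA_MM, FilterParams, MonitorParams, SensorConfig,
                     ValidationThresholds)
from .errors import MissingFootError
from .foot import stance_metrics
from .frame import CopPoint, PressureFrame, compute_cop, filter_frame, split_left_right
from .gamification import group_for_level, level_for_duration

SEVERITIES = ("balanced", "slight", "severe", "broken")
FLAGS = ("cop_overall", "cop_left", "cop_right", "foot_position",
         "foot_orientation", "lr_imbalance")


@dataclass(frozen=True)
class RegionTest:
    inside: bool
    d: float  # normalised displacement; inside iff d < 1


def cop_region_test(cop_t: CopPoint, cop_ref: CopPoint, alpha_mm: float,
                    mode: str = "box") -> RegionTest:
    """Test a real-time COP against the valid region around its reference.

    Box mode applies the strict per-axis bounds (d = max(|dx|, |dy|) / alpha);
    circle mode uses the Euclidean distance (d = ||delta|| / alpha).  The
    point is inside iff d < 1, so d = 1 exactly falls outside.
    """
    if alpha_mm <= 0:
        raise ValueError("alpha_mm must be > 0")
    dx, dy = cop_t.displacement(cop_ref)
    if mode == "box":
        d = max(abs(dx), abs(dy)) / alpha_mm
    elif mode == "circle":
        d = math.hypot(dx, dy) / alpha_mm
    else:
        raise ValueError("mode must be 'box' or 'circle'")
    return RegionTest(inside=d < 1.0, d=d)


def lean_severity(d: float, params: MonitorParams = MonitorParams()) -> str:
    """Map normalised displacement onto the feedback bands.

    balanced (grey) for d <= balanced_max, slight (yellow) up to slight_max,
    severe (red) below 1, broken (the avatar falls) at d >= 1.
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    if d >= 1.0:
        return "broken"
    if d > params.slight_max:
        return "severe"
    if d > params.balanced_max:
        return "slight"
    return "balanced"


@dataclass(frozen=True)
class FrameAssessment:
    """Per-frame classification against the calibration profile."""

    state: str                      # "Ms" (good) | "Mp" (poor)
    flags: frozenset[str]
    lean_severity: str
    lean_direction: tuple[float, float]  # unit vector of COPo displacement
    displacement_norm: float        # max normalised displacement over the 3 COPs
    timestamp_ms: int = 0
    cop_o: CopPoint | None = None
    cop_l: CopPoint | None = None
    cop_r: CopPoint | None = None


def assess_frame(frame: PressureFrame, profile: CalibrationProfile,
                 thresholds: ValidationThresholds, config: SensorConfig,
                 params: MonitorParams = MonitorParams()) -> FrameAssessment:
    """Classify one filtered training frame as good (Ms) or poor (Mp).

    A frame on which a foot cannot be detected raises
    :class:`MissingFootError`; streaming callers treat that as a
    ``foot_position`` flag (the foot left its half of the mat).
    """
    flags: set[str] = set()
    left, right = detect_feet(frame, config)

    left_half, right_half = split_left_right(frame, config)
    cop_o = compute_cop(frame, config)
    cop_l = compute_cop(left_half, config)
    cop_r = compute_cop(right_half, config)

    tests = {
        "cop_overall": cop_region_test(cop_o, profile.cop_o_ref, profile.alpha_mm,
                                       params.region_mode),
        "cop_left": cop_region_test(cop_l, profile.cop_l_ref, profile.alpha_mm,
                                    params.region_mode),
        "cop_right": cop_region_test(cop_r, profile.cop_r_ref, profile.alpha_mm,
                                     params.region_mode),
    }
    for name, test in tests.items():
        if not test.inside:
            flags.add(name)

    for foot, ref in ((left, profile.foot_left), (right, profile.foot_right)):
        drift = math.hypot(*foot.centroid.displacement(ref.centroid))
        if drift > params.pos_drift_mm:
            flags.add("foot_position")
        in_range = thresholds.toe_angle_min_deg <= foot.toe_angle_deg <= thresholds.toe_angle_max_deg
        if not in_range or abs(foot.toe_angle_deg - ref.toe_angle_deg) > params.angle_drift_deg:
            flags.add("foot_orientation")

    if stance_metrics(left, right, config).lr_balance > thresholds.lr_balance_max:
        flags.add("lr_imbalance")

    d = max(t.d for t in tests.values())
    dx, dy = cop_o.displacement(profile.cop_o_ref)
    norm = math.hypot(dx, dy)
    direction = (dx / norm, dy / norm) if norm > 0 else (0.0, 0.0)
    return FrameAssessment(
        state="Ms" if not flags else "Mp",
        flags=frozenset(flags),
        lean_severity=lean_severity(d, params),
        lean_direction=direction,
        displacement_norm=d,
        timestamp_ms=frame.timestamp_ms,
        cop_o=cop_o, cop_l=cop_l, cop_r=cop_r,
    )


@dataclass
class SessionRecord:
    """One training session: timer, state trajectory, final reward standing."""

    participant_id: str = "anon"
    condition: str = "GFB"          # NFB | CFB | GFB
    fps: float = 20.0
    state: str = "ENTRY"            # ENTRY -> TRAINING -> BROKEN (terminal) | ABORTED
    n_good_frames: int = 0
    mp_streak: int = 0
    break_time_s: float | None = None
    terminal_flags: frozenset[str] = frozenset()
    states: list[str] = field(default_factory=list)
    final_level: int | None = None
    final_group: str | None = None
    recorded_at_ms: int = 0

    @property
    def good_duration_s(self) -> float:
        """Accumulated time correctly held, frozen once the stance breaks."""
        return self.n_good_frames / self.fps


def session_step(assessment: FrameAssessment, record: SessionRecord,
                 params: MonitorParams = MonitorParams()) -> list[dict]:
    """Advance the session by one assessed frame; returns emitted events.

    Good frames add one frame period to the held time.  The first poor frame
    (after ``debounce_frames`` consecutive poor frames) freezes the timer,
    records the break time, computes the final level/group and emits a
    notification event.  A broken session is terminal: further steps are
    no-ops that emit a warning.
    """
    events: list[dict] = []
    if record.state == "BROKEN":
        events.append({"event": "warning", "detail": "session already broken",
                       "t_ms": assessment.timestamp_ms})
        return events
    if record.state != "TRAINING":
        raise ValueError(f"session_step requires TRAINING state, not {record.state}")
    record.states.append(assessment.state)
    if assessment.state == "Ms":
        record.n_good_frames += 1
        record.mp_streak = 0
    else:
        record.mp_streak += 1
        if record.mp_streak >= params.debounce_frames:
            record.state = "BROKEN"
            record.break_time_s = record.good_duration_s
            record.terminal_flags = assessment.flags
            record.final_level = level_for_duration(record.good_duration_s)
            record.final_group = group_for_level(record.final_level)
            record.recorded_at_ms = assessment.timestamp_ms
            events.append({"event": "notification", "detail": "stance broken",
                           "t_ms": assessment.timestamp_ms,
                           "flags": sorted(assessment.flags),
                           "good_duration_s": record.good_duration_s})
    return events


def run_session(frames: Iterable[PressureFrame], thresholds: ValidationThresholds,
                config: SensorConfig, filter_params: FilterParams = FilterParams(),
                params: MonitorParams = MonitorParams(),
                profile: CalibrationProfile | None = None,
                alpha_mm: float = DEFAULT_ALPHA_MM,
                participant_id: str = "anon", condition: str = "GFB",
                log_path: str | Path | None = None) -> tuple[SessionRecord, list[dict]]:
    """Drive a full session over a frame stream.

    The stream opens with an entry phase: frames are validated against the
    five stance criteria until one passes, at which point that frame becomes
    the calibration frame (unless a profile was supplied) and training
    starts.  Training frames are assessed until the stance breaks.  If the
    stream ends while still in the entry phase the session is aborted.

    Returns the session record and the per-frame event log; given the same
    stream the log is byte-identical across runs.
    """
    record = SessionRecord(participant_id=participant_id, condition=condition,
                           fps=params.fps)
    events: list[dict] = []
    for raw in frames:
        f = filter_frame(raw, filter_params)
        if record.state == "ENTRY":
            try:
                report = validate_entry_stance(f, thresholds, config)
            except MissingFootError:
                events.append({"event": "entry", "t_ms": f.timestamp_ms,
                               "passed": False, "failed": ["missing_foot"]})
                continue
            if report.all_passed:
                if profile is None:
                    profile = calibrate(f, thresholds, config, alpha_mm)
                record.state = "TRAINING"
                events.append({"event": "entry", "t_ms": f.timestamp_ms,
                               "passed": True, "failed": []})
            else:
                events.append({"event": "entry", "t_ms": f.timestamp_ms,
                               "passed": False, "failed": report.failed()})
            continue
        try:
            assessment = assess_frame(f, profile, thresholds, config, params)
        except MissingFootError:
            # streaming convention: a vanished foot is a position break
            assessment = FrameAssessment(state="Mp",
                                         flags=frozenset({"foot_position"}),
                                         lean_severity="broken",
                                         lean_direction=(0.0, 0.0),
                                         displacement_norm=math.inf,
                                         timestamp_ms=f.timestamp_ms)
        step_events = session_step(assessment, record, params)
        events.append(_frame_event(assessment, record))
        events.extend(step_events)
        if record.state == "BROKEN":
            break
    if record.state == "ENTRY":
        record.state = "ABORTED"
        events.append({"event": "aborted",
                       "detail": "stream ended before a valid entry stance"})
    if log_path is not None:
        with Path(log_path).open("w") as fh:
            for ev in events:
                fh.write(json.dumps(ev, sort_keys=True) + "\n")
    return record, events


def _frame_event(a: FrameAssessment, record: SessionRecord) -> dict:
    return {
        "event": "frame",
        "t_ms": a.timestamp_ms,
        "state": a.state,
        "flags": sorted(a.flags),
        "severity": a.lean_severity,
        "d": None if math.isinf(a.displacement_norm) else round(a.displacement_norm, 6),
        "lean_direction": [round(c, 6) for c in a.lean_direction],
        "cop_o": None if a.cop_o is None else [round(a.cop_o.x, 3), round(a.cop_o.y, 3)],
        "good_duration_s": round(record.good_duration_s, 6),
    }
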