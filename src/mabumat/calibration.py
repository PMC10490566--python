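"""Calibration: capture the reference frame Mc and enforce the five entry criteria.

A training session only starts from a verified stance.  The five criteria are:

1. left/right pressure distribution equal and balanced;
2. both feet along the mat's horizontal center-line;
3. feet wider than shoulder-width apart;
4. each foot slightly pointing outwards, between 0 and 45 degrees;
5. sole (forefoot) and heel pressure balanced.

When all pass, the calibration profile stores the three reference centers of
pressure (overall, left, right), the detected foot geometry and the valid-
region radius alpha used by the monitor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .config import DEFAULT_ALPHA_MM, SensorConfig, ValidationThresholds
from .errors import CalibrationError, EmptyHalfError, MissingFootError
from .foot import FootRegion, StanceMetrics, detect_foot, stance_metrics
from .frame import CopPoint, PressureFrame, compute_cop, split_left_right

#: criterion keys, in the order they are reported
CRITERIA = ("lr_balance", "centerline", "stance_width", "toe_angle", "heel_fore")


@dataclass(frozen=True)
class CriteriaReport:
    """Pass/fail per criterion plus the measured quantities behind each."""

    passed: dict[str, bool]
    measured: dict[str, float]
    left: FootRegion
    right: FootRegion
    metrics: StanceMetrics

    @property
    def all_passed(self) -> bool:
        return all(self.passed.values())

    def failed(self) -> list[str]:
        return [k for k in CRITERIA if not self.passed[k]]


@dataclass(frozen=True)
class CalibrationProfile:
    """Reference stance captured from a valid calibration frame Mc."""

    cop_o_ref: CopPoint
    cop_l_ref: CopPoint
    cop_r_ref: CopPoint
    alpha_mm: float
    foot_left: FootRegion
    foot_right: FootRegion
    captured_at_ms: int = 0

    def to_dict(self) -> dict:
        def cop(c: CopPoint) -> dict:
            return {"x": c.x, "y": c.y, "total_pressure": c.total_pressure}

        def foot(f: FootRegion) -> dict:
            return {"side": f.side, "centroid": cop(f.centroid),
                    "toe_angle_deg": f.toe_angle_deg,
                    "heel_load_frac": f.heel_load_frac,
                    "fore_load_frac": f.fore_load_frac,
                    "total_pressure": f.total_pressure,
                    "bbox": list(f.bbox), "axis": list(f.axis)}

        return {"cop_o_ref": cop(self.cop_o_ref), "cop_l_ref": cop(self.cop_l_ref),
                "cop_r_ref": cop(self.cop_r_ref), "alpha_mm": self.alpha_mm,
                "foot_left": foot(self.foot_left), "foot_right": foot(self.foot_right),
                "captured_at_ms": self.captured_at_ms}

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationProfile":
        def cop(c: dict) -> CopPoint:
            return CopPoint(c["x"], c["y"], c.get("total_pressure", 0.0))

        def foot(f: dict) -> FootRegion:
            return FootRegion(side=f["side"], centroid=cop(f["centroid"]),
                              toe_angle_deg=f["toe_angle_deg"],
                              heel_load_frac=f["heel_load_frac"],
                              fore_load_frac=f["fore_load_frac"],
                              total_pressure=f["total_pressure"],
                              bbox=tuple(f["bbox"]), axis=tuple(f["axis"]))

        return cls(cop_o_ref=cop(d["cop_o_ref"]), cop_l_ref=cop(d["cop_l_ref"]),
                   cop_r_ref=cop(d["cop_r_ref"]), alpha_mm=d["alpha_mm"],
                   foot_left=foot(d["foot_left"]), foot_right=foot(d["foot_right"]),
                   captured_at_ms=d.get("captured_at_ms", 0))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationProfile":
        return cls.from_dict(json.loads(Path(path).read_text()))


def detect_feet(frame: PressureFrame, config: SensorConfig) -> tuple[FootRegion, FootRegion]:
    """Detect both feet of a filtered full frame; raises MissingFootError."""
    left_half, right_half = split_left_right(frame, config)
    try:
        left = detect_foot(left_half, config, "left")
        right = detect_foot(right_half, config, "right")
    except EmptyHalfError as exc:
        raise MissingFootError(str(exc)) from exc
    return left, right


def validate_entry_stance(frame: PressureFrame, thresholds: ValidationThresholds,
                          config: SensorConfig) -> CriteriaReport:
    """Evaluate the five entry criteria on a filtered frame.

    The report is scale-invariant in overall body weight: multiplying every
    cell by a positive constant changes no criterion outcome.
    """
    left, right = detect_feet(frame, config)
    m = stance_metrics(left, right, config)
    t = thresholds
    heel_fore_l = abs(left.heel_load_frac - left.fore_load_frac)
    heel_fore_r = abs(right.heel_load_frac - right.fore_load_frac)
    passed = {
        "lr_balance": m.lr_balance <= t.lr_balance_max,
        "centerline": (m.centerline_offset_left_mm <= t.centerline_tol_mm
                       and m.centerline_offset_right_mm <= t.centerline_tol_mm),
        "stance_width": m.stance_width_mm >= t.min_stance_width_mm,
        "toe_angle": (t.toe_angle_min_deg <= left.toe_angle_deg <= t.toe_angle_max_deg
                      and t.toe_angle_min_deg <= right.toe_angle_deg <= t.toe_angle_max_deg),
        "heel_fore": (heel_fore_l <= t.heel_fore_imbalance_max
                      and heel_fore_r <= t.heel_fore_imbalance_max),
    }
    measured = {
        "lr_balance": m.lr_balance,
        "centerline_offset_left_mm": m.centerline_offset_left_mm,
        "centerline_offset_right_mm": m.centerline_offset_right_mm,
        "stance_width_mm": m.stance_width_mm,
        "toe_angle_left_deg": left.toe_angle_deg,
        "toe_angle_right_deg": right.toe_angle_deg,
        "heel_fore_imbalance_left": heel_fore_l,
        "heel_fore_imbalance_right": heel_fore_r,
    }
    return CriteriaReport(passed=passed, measured=measured, left=left, right=right,
                          metrics=m)


def calibrate(frame: PressureFrame, thresholds: ValidationThresholds,
              config: SensorConfig, alpha_mm: float = DEFAULT_ALPHA_MM) -> CalibrationProfile:
    """Capture a calibration profile from a filtered frame Mc.

    Raises :class:`CalibrationError` (carrying the criteria report) when the
    stance is invalid, signalling the user to redo the calibration.
    """
    if alpha_mm <= 0:
        raise ValueError("alpha_mm must be > 0")
    report = validate_entry_stance(frame, thresholds, config)
    if not report.all_passed:
        raise CalibrationError(report)
    left_half, right_half = split_left_right(frame, config)
    return CalibrationProfile(
        cop_o_ref=compute_cop(frame, config),
        cop_l_ref=compute_cop(left_half, config),
        cop_r_ref=compute_cop(right_half, config),
        alpha_mm=alpha_mm,
        foot_left=report.left,
        foot_right=report.right,
        captured_at_ms=frame.timestamp_ms,
    )
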