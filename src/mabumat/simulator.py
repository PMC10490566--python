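"""Synthetic baropodometry: parametric stance frames and scripted sessions.

Every other module is testable without hardware because this generator
renders 12-bit pressure maps of a wide two-foot stance with known ground
truth.  Each foot is modelled as two anisotropic Gaussian pressure lobes
(heel and forefoot) placed +/- ``LOBE_OFFSET_MM`` along the foot's long
axis, which is rotated outward by the toe angle.  The model reproduces the
heel/sole hotspot structure seen on real mats while keeping every label
(COPs, toe angles, load splits) analytically controlled.

Leaning is imposed the way a standing human leans: by redistributing load
(left/right weight shift for medio-lateral lean, heel-to-forefoot shift for
antero-posterior lean) rather than by moving the feet, so a lean changes the
centers of pressure without triggering foot-position drift.

Model constants (documented design choices):

- ``LOBE_OFFSET_MM = 80``: lobe centers sit 160 mm apart along the foot axis,
  a typical adult heel-to-ball distance.
- ``SIGMA_ALONG = 24`` mm, ``SIGMA_ACROSS_HEEL = 20`` mm,
  ``SIGMA_ACROSS_FORE = 26`` mm: compact lobes whose overlap is small enough
  that the perpendicular-bisector heel/fore estimator can recover the lobe
  loading to a few percent.
- ``RAW_PER_KG = 680``: raw counts of total pressure per kilogram, placing an
  80 kg subject's peak cell near 60 % of 12-bit full scale (no saturation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .config import SensorConfig
from .errors import StanceOffMatError
from .frame import CopPoint, PressureFrame, compute_cop, split_left_right

LOBE_OFFSET_MM = 80.0
SIGMA_ALONG = 24.0
SIGMA_ACROSS_HEEL = 20.0
SIGMA_ACROSS_FORE = 26.0
RAW_PER_KG = 680.0


@dataclass(frozen=True)
class StanceSpec:
    """Parameters of one simulated stance."""

    body_mass_kg: float = 80.0
    stance_width_mm: float = 450.0
    toe_angle_left_deg: float = 18.0
    toe_angle_right_deg: float = 18.0
    lr_split: float = 0.5            # fraction of load on the left foot
    fore_frac_left: float = 0.5      # forefoot share of the left foot's load
    fore_frac_right: float = 0.5
    lean_vector_mm: tuple[float, float] = (0.0, 0.0)
    noise_sd: float = 0.0            # raw units, truncated-Gaussian additive noise
    seed: int = 0
    center_x_mm: float | None = None  # stance midpoint; defaults to mat center
    center_y_mm: float | None = None

    def __post_init__(self) -> None:
        if self.body_mass_kg < 0:
            raise ValueError("body_mass_kg must be >= 0")
        if not 0 < self.lr_split < 1:
            raise ValueError("lr_split must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.stance_width_mm <= 0:
            raise ValueError("stance_width_mm must be > 0")


@dataclass(frozen=True)
class FrameTruth:
    """Ground-truth labels attached to one synthetic frame."""

    cop_o: CopPoint
    cop_l: CopPoint
    cop_r: CopPoint
    toe_angle_left_deg: float
    toe_angle_right_deg: float
    fore_frac_left: float
    fore_frac_right: float
    lr_split: float
    stance_width_mm: float          # distance between noise-free foot COPs
    foot_center_left: tuple[float, float]
    foot_center_right: tuple[float, float]
    lean_vector_mm: tuple[float, float]


def _foot_lobes(center: tuple[float, float], phi_rad: float, mass: float,
                fore_frac: float) -> list[tuple[float, float, float, float, float]]:
    """Lobes of one foot: (cx, cy, mass, sigma_along, sigma_across)."""
    ux, uy = math.sin(phi_rad), math.cos(phi_rad)
    cx, cy = center
    return [
        (cx + LOBE_OFFSET_MM * ux, cy + LOBE_OFFSET_MM * uy,
         mass * fore_frac, SIGMA_ALONG, SIGMA_ACROSS_FORE),
        (cx - LOBE_OFFSET_MM * ux, cy - LOBE_OFFSET_MM * uy,
         mass * (1.0 - fore_frac), SIGMA_ALONG, SIGMA_ACROSS_HEEL),
    ]


def _render(spec: StanceSpec, config: SensorConfig,
            foot_shift_mm: tuple[float, float] = (0.0, 0.0),
            mass_scale: float = 1.0) -> tuple[np.ndarray, dict]:
    """Continuous (float) pressure field before noise and quantization.

    ``foot_shift_mm`` translates the *right* foot only (used by the
    foot-shift break mode).  Returns (field, geometry dict).
    """
    cx = spec.center_x_mm if spec.center_x_mm is not None else config.length_mm / 2.0
    cy = spec.center_y_mm if spec.center_y_mm is not None else config.width_mm / 2.0
    half_w = spec.stance_width_mm / 2.0
    center_l = (cx - half_w, cy)
    center_r = (cx + half_w + foot_shift_mm[0], cy + foot_shift_mm[1])
    phi_l = -math.radians(spec.toe_angle_left_deg)   # outward = toward -x
    phi_r = math.radians(spec.toe_angle_right_deg)   # outward = toward +x

    lx, ly = spec.lean_vector_mm
    # medio-lateral lean: shift weight between the feet
    w_left = float(np.clip(spec.lr_split - lx / spec.stance_width_mm, 0.02, 0.98))
    # antero-posterior lean: shift each foot's load between heel and forefoot
    fore_l = float(np.clip(spec.fore_frac_left
                           + ly / (2.0 * LOBE_OFFSET_MM * math.cos(phi_l)), 0.02, 0.98))
    fore_r = float(np.clip(spec.fore_frac_right
                           + ly / (2.0 * LOBE_OFFSET_MM * math.cos(phi_r)), 0.02, 0.98))

    lobes = (_foot_lobes(center_l, phi_l, w_left, fore_l)
             + _foot_lobes(center_r, phi_r, 1.0 - w_left, fore_r))
    for cx_lobe, cy_lobe, _m, _sa, _sc in lobes:
        if not (0 <= cx_lobe <= config.length_mm and 0 <= cy_lobe <= config.width_mm):
            raise StanceOffMatError(
                f"lobe center ({cx_lobe:.0f}, {cy_lobe:.0f}) mm off the "
                f"{config.length_mm:.0f} x {config.width_mm:.0f} mm mat")

    x = (np.arange(config.n_cols) + 0.5) * config.pitch_x
    y = (np.arange(config.n_rows) + 0.5) * config.pitch_y
    X, Y = np.meshgrid(x, y)
    density = np.zeros_like(X)
    for (lcx, lcy, mass, s_along, s_across), phi in zip(
            lobes, (phi_l, phi_l, phi_r, phi_r)):
        if mass <= 0:
            continue
        ux, uy = math.sin(phi), math.cos(phi)
        t = (X - lcx) * ux + (Y - lcy) * uy        # along-axis offset
        s = -(X - lcx) * uy + (Y - lcy) * ux       # across-axis offset
        # bivariate-normal amplitude, so each lobe's integral carries its mass
        amp = mass / (2.0 * math.pi * s_along * s_across)
        density += amp * np.exp(-0.5 * ((t / s_along) ** 2 + (s / s_across) ** 2))

    total_target = spec.body_mass_kg * RAW_PER_KG * mass_scale
    dsum = density.sum()
    field = density * (total_target / dsum) if dsum > 0 and total_target > 0 \
        else np.zeros_like(density)
    geom = {"center_l": center_l, "center_r": center_r,
            "w_left": w_left, "fore_l": fore_l, "fore_r": fore_r}
    return field, geom


def _quantize(field: np.ndarray, config: SensorConfig,
              noise_sd: float = 0.0, rng: np.random.Generator | None = None) -> np.ndarray:
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise requires an rng")
        field = field + rng.normal(0.0, noise_sd, size=field.shape)
    return np.clip(np.rint(field), 0, config.max_value).astype(np.int64)


def synth_frame(spec: StanceSpec, config: SensorConfig = SensorConfig(),
                timestamp_ms: int = 0,
                rng: np.random.Generator | None = None) -> tuple[PressureFrame, FrameTruth]:
    """Render one stance frame plus its ground-truth labels.

    Truth COPs are measured on the noise-free quantized field, so they are
    exactly what an ideal sensor would report for this stance; toe angles and
    load splits are the imposed parameters.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    field, geom = _render(spec, config)
    clean = _quantize(field, config)
    values = (_quantize(field, config, spec.noise_sd, rng)
              if spec.noise_sd > 0 else clean)
    frame = PressureFrame(values, timestamp_ms=timestamp_ms, role="Mt")

    clean_frame = PressureFrame(clean, timestamp_ms=timestamp_ms, role="Mt")
    if clean.sum() > 0:
        left_half, right_half = split_left_right(clean_frame, config)
        cop_o = compute_cop(clean_frame, config)
        cop_l = compute_cop(left_half, config)
        cop_r = compute_cop(right_half, config)
        width = math.hypot(cop_r.x - cop_l.x, cop_r.y - cop_l.y)
    else:
        cop_o = cop_l = cop_r = CopPoint(0.0, 0.0, 0.0)
        width = 0.0
    truth = FrameTruth(
        cop_o=cop_o, cop_l=cop_l, cop_r=cop_r,
        toe_angle_left_deg=spec.toe_angle_left_deg,
        toe_angle_right_deg=spec.toe_angle_right_deg,
        fore_frac_left=geom["fore_l"], fore_frac_right=geom["fore_r"],
        lr_split=geom["w_left"],
        stance_width_mm=width,
        foot_center_left=geom["center_l"], foot_center_right=geom["center_r"],
        lean_vector_mm=spec.lean_vector_mm,
    )
    return frame, truth


@dataclass(frozen=True)
class SessionScript:
    """Scripted trajectory of one simulated session.

    The practitioner holds the stance with natural postural sway (a bounded
    mean-reverting random walk of the COP) until ``break_at_s`` seconds of
    training, then breaks in one of three ways: ``lean_out`` (sudden sideways
    balance loss), ``foot_shift`` (a foot slides to an incorrect position) or
    ``rise`` (standing up out of the squat, unloading into the forefeet).
    """

    fps: float = 20.0
    hold_s: float = 30.0
    sway_amplitude_mm: float = 8.0
    sway_timescale_s: float = 1.0
    break_mode: str = "lean_out"
    break_at_s: float = 10.0
    seed: int = 0
    entry_s: float = 1.0
    break_ramp_s: float = 0.5
    break_onset_mm: float = 60.0     # first break-frame lean magnitude
    break_full_mm: float = 120.0     # lean magnitude at end of ramp
    foot_shift_mm: float = 80.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.break_mode not in ("lean_out", "foot_shift", "rise"):
            raise ValueError("break_mode must be lean_out | foot_shift | rise")
        if self.break_at_s > self.hold_s + 1.0 / self.fps:
            raise ValueError("break_at_s must not exceed hold_s (plus one frame)")


@dataclass(frozen=True)
class SessionTruth:
    break_mode: str
    break_at_s: float        # scripted training time of the first break frame
    n_entry_frames: int
    n_training_frames: int   # good frames scripted before the break
    fps: float


def synth_session(stance: StanceSpec, script: SessionScript,
                  config: SensorConfig = SensorConfig()) -> tuple[list[PressureFrame], SessionTruth]:
    """Generate the frame stream of one scripted session.

    The stream opens with ``entry_s`` seconds of the calm stance (the entry/
    calibration phase), then sways through ``break_at_s`` seconds of training,
    then executes the break trajectory for ``break_ramp_s`` seconds.
    Deterministic for a given script seed.
    """
    rng = np.random.default_rng(script.seed)
    fps = script.fps
    dt_ms = 1000.0 / fps
    frames: list[PressureFrame] = []
    k = 0

    def emit(spec: StanceSpec) -> None:
        nonlocal k
        frame, _ = synth_frame(spec, config, timestamp_ms=round(k * dt_ms), rng=rng)
        frames.append(frame)
        k += 1

    # entry/settling phase: the practitioner widens into the stance, so the
    # frames fail the minimum-width gate until the final (calibration) frame
    n_entry = max(1, round(script.entry_s * fps))
    for i in range(n_entry - 1):
        frac = 0.6 + 0.25 * i / max(n_entry - 2, 1)
        emit(replace(stance, stance_width_mm=frac * stance.stance_width_mm))
    emit(stance)  # first valid frame: passes the gate, becomes Mc

    # AR(1) mean-reverting sway with stationary sd = sway_amplitude_mm per axis
    a = math.exp(-1.0 / (fps * script.sway_timescale_s))
    step_sd = script.sway_amplitude_mm * math.sqrt(max(1.0 - a * a, 0.0))
    lean = np.zeros(2)
    n_train = round(script.break_at_s * fps)
    for _ in range(n_train):
        emit(replace(stance, lean_vector_mm=(float(lean[0]), float(lean[1]))))
        lean = a * lean + rng.normal(0.0, step_sd, size=2)

    n_break = max(1, round(script.break_ramp_s * fps))
    if script.break_mode == "lean_out":
        # sideways fall: direction within +/-30 degrees of the lateral axis
        side = rng.choice((-1.0, 1.0))
        ang = rng.uniform(-math.pi / 6, math.pi / 6)
        direction = (side * math.cos(ang), math.sin(ang))
        for i in range(n_break):
            frac = i / max(n_break - 1, 1)
            mag = script.break_onset_mm + frac * (script.break_full_mm - script.break_onset_mm)
            emit(replace(stance, lean_vector_mm=(mag * direction[0], mag * direction[1])))
    elif script.break_mode == "foot_shift":
        shift = (script.foot_shift_mm, 0.0)
        for _ in range(n_break):
            frame_field, _ = _render(stance, config, foot_shift_mm=shift)
            values = _quantize(frame_field, config, stance.noise_sd, rng)
            frames.append(PressureFrame(values, timestamp_ms=round(k * dt_ms), role="Mt"))
            k += 1
    else:  # rise: stand up out of the squat — load drops and rolls forward
        for _ in range(n_break):
            risen = replace(stance, fore_frac_left=0.88, fore_frac_right=0.88)
            field, _ = _render(risen, config, mass_scale=0.65)
            values = _quantize(field, config, stance.noise_sd, rng)
            frames.append(PressureFrame(values, timestamp_ms=round(k * dt_ms), role="Mt"))
            k += 1

    truth = SessionTruth(break_mode=script.break_mode,
                         break_at_s=n_train / fps,
                         n_entry_frames=n_entry,
                         n_training_frames=n_train,
                         fps=fps)
    return frames, truth


#: default condition medians (seconds) for the three-arm feedback design:
#: full game feedback > clock-only feedback > no feedback
DEFAULT_CONDITION_MEDIANS = {"NFB": 40.0, "CFB": 55.0, "GFB": 80.0}
DEFAULT_LOG_SIGMA = 0.45


def synth_condition_cohort(n_per_condition: int = 14,
                           medians: dict[str, float] | None = None,
                           log_sigma: float = DEFAULT_LOG_SIGMA,
                           seed: int = 0) -> list:
    """Draw per-participant held durations for a three-condition cohort.

    Durations are log-normal around each condition's median (hold times are
    positive and right-skewed), mirroring a study design of
    ``n_per_condition`` participants per feedback arm.  Returns lightweight
    :class:`~mabumat.monitor.SessionRecord` objects tagged with condition.
    """
    from .monitor import SessionRecord  # local import to avoid a cycle
    from .gamification import group_for_level, level_for_duration

    if n_per_condition < 2:
        raise ValueError("need n >= 2 per condition")
    if medians is None:
        medians = DEFAULT_CONDITION_MEDIANS
    rng = np.random.default_rng(seed)
    records = []
    fps = 20.0
    for condition in medians:
        mu = math.log(medians[condition])
        durations = rng.lognormal(mu, log_sigma, size=n_per_condition)
        for i, dur in enumerate(durations):
            n_good = int(round(dur * fps))
            rec = SessionRecord(participant_id=f"{condition}-{i:02d}",
                                condition=condition, fps=fps, state="BROKEN",
                                n_good_frames=n_good,
                                break_time_s=n_good / fps,
                                recorded_at_ms=i)
            rec.final_level = level_for_duration(rec.good_duration_s)
            rec.final_group = group_for_level(rec.final_level)
            records.append(rec)
    return records
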