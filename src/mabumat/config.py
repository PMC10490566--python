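"""Sensor geometry and algorithm parameters.

The default sensing surface is a 1000 mm x 500 mm mat with 924 piezoresistive
cells read at 12-bit resolution.  The cell grid realising those 924 points is
configurable; the default is 22 rows x 42 columns (22 * 42 = 924), giving a
column pitch of 1000/42 mm along the mat's long (x, medio-lateral) axis and a
row pitch of 500/22 mm along the short (y, posterior->anterior) axis.

Coordinate convention (used everywhere in the package): 0-based row/column
indices; x in mm along the 1000 mm axis increasing left->right from the
practitioner's perspective; y in mm along the 500 mm axis increasing
posterior->anterior; the center of cell (r, c) sits at
((c + 0.5) * pitch_x, (r + 0.5) * pitch_y).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path


@dataclass(frozen=True)
class SensorConfig:
    """Geometry and resolution of the pressure-sensing matrix."""

    n_rows: int = 22
    n_cols: int = 42
    length_mm: float = 1000.0
    width_mm: float = 500.0
    bit_depth: int = 12

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.length_mm <= 0 or self.width_mm <= 0:
            raise ValueError("mat dimensions must be positive")
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be >= 1")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def pitch_x(self) -> float:
        """mm per column step (along the 1000 mm axis)."""
        return self.length_mm / self.n_cols

    @property
    def pitch_y(self) -> float:
        """mm per row step (along the 500 mm axis)."""
        return self.width_mm / self.n_rows

    @property
    def max_value(self) -> int:
        """Largest representable raw reading, 2**bit_depth - 1 (4095 at 12-bit)."""
        return (1 << self.bit_depth) - 1


@dataclass(frozen=True)
class FilterParams:
    """High-pass (zeroing) filter threshold.

    Readings strictly below ``beta`` raw units are set to zero; this removes
    the preload of the mat's foam layers and baseline sensor noise.  The
    default is 2 % of 12-bit full scale.
    """

    beta: float = 81.9

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass(frozen=True)
class ValidationThresholds:
    """Thresholds for the five entry-stance (calibration) criteria.

    1. left/right load balance   |Pl - Pr| / (Pl + Pr) <= lr_balance_max
    2. both feet on the mat's horizontal center-line within centerline_tol_mm
    3. stance width >= min_stance_width_mm (wider than shoulder width)
    4. both toe-out angles within [toe_angle_min_deg, toe_angle_max_deg]
    5. heel/forefoot imbalance |heel - fore| <= heel_fore_imbalance_max
    """

    lr_balance_max: float = 0.15
    centerline_tol_mm: float = 40.0
    min_stance_width_mm: float = 400.0
    toe_angle_min_deg: float = 0.0
    toe_angle_max_deg: float = 45.0
    heel_fore_imbalance_max: float = 0.30

    def __post_init__(self) -> None:
        for name in ("lr_balance_max", "centerline_tol_mm", "min_stance_width_mm",
                     "heel_fore_imbalance_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.toe_angle_min_deg >= self.toe_angle_max_deg:
            raise ValueError("toe_angle_min_deg must be < toe_angle_max_deg")


@dataclass(frozen=True)
class MonitorParams:
    """Real-time monitoring parameters.

    region_mode selects how the valid region around each calibrated COP is
    tested: "box" applies the per-axis strict bounds, "circle" a Euclidean
    radius; both use the same radius alpha stored in the calibration profile.
    Severity bands map the normalised COP displacement d onto the in-game
    feedback colors: balanced (grey) for d <= balanced_max, slight (yellow)
    up to slight_max, severe (red) below 1, broken (fall) at d >= 1.
    """

    region_mode: str = "box"
    pos_drift_mm: float = 50.0
    angle_drift_deg: float = 15.0
    debounce_frames: int = 1
    fps: float = 20.0
    balanced_max: float = 0.4
    slight_max: float = 0.75

    def __post_init__(self) -> None:
        if self.region_mode not in ("box", "circle"):
            raise ValueError("region_mode must be 'box' or 'circle'")
        if self.debounce_frames < 1:
            raise ValueError("debounce_frames must be >= 1")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if not 0 <= self.balanced_max <= self.slight_max <= 1:
            raise ValueError("severity bands must satisfy 0 <= balanced <= slight <= 1")


DEFAULT_ALPHA_MM = 40.0


@dataclass
class MatConfig:
    """Aggregate of all tunables, loadable from a flat key-value file."""

    sensor: SensorConfig = field(default_factory=SensorConfig)
    filter: FilterParams = field(default_factory=FilterParams)
    thresholds: ValidationThresholds = field(default_factory=ValidationThresholds)
    monitor: MonitorParams = field(default_factory=MonitorParams)
    alpha_mm: float = DEFAULT_ALPHA_MM


_KEY_MAP = {
    "rows": ("sensor", "n_rows", int),
    "cols": ("sensor", "n_cols", int),
    "length_mm": ("sensor", "length_mm", float),
    "width_mm": ("sensor", "width_mm", float),
    "bit_depth": ("sensor", "bit_depth", int),
    "beta": ("filter", "beta", float),
    "lr_balance_max": ("thresholds", "lr_balance_max", float),
    "centerline_tol_mm": ("thresholds", "centerline_tol_mm", float),
    "min_stance_width_mm": ("thresholds", "min_stance_width_mm", float),
    "toe_angle_min_deg": ("thresholds", "toe_angle_min_deg", float),
    "toe_angle_max_deg": ("thresholds", "toe_angle_max_deg", float),
    "heel_fore_imbalance_max": ("thresholds", "heel_fore_imbalance_max", float),
    "region_mode": ("monitor", "region_mode", str),
    "pos_drift_mm": ("monitor", "pos_drift_mm", float),
    "angle_drift_deg": ("monitor", "angle_drift_deg", float),
    "debounce_frames": ("monitor", "debounce_frames", int),
    "fps": ("monitor", "fps", float),
    "balanced_max": ("monitor", "balanced_max", float),
    "slight_max": ("monitor", "slight_max", float),
    "alpha": ("", "alpha_mm", float),
}


def load_config(path: str | Path) -> MatConfig:
    """Read a flat ``key = value`` config file (``#`` starts a comment)."""
    groups: dict[str, dict] = {"sensor": {}, "filter": {}, "thresholds": {},
                               "monitor": {}, "": {}}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" in line:
            key, _, val = line.partition("=")
        else:
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = parts
        key, val = key.strip(), val.strip()
        if key not in _KEY_MAP:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        group, attr, conv = _KEY_MAP[key]
        groups[group][attr] = conv(val)

    return MatConfig(
        sensor=SensorConfig(**groups["sensor"]),
        filter=FilterParams(**groups["filter"]),
        thresholds=ValidationThresholds(**groups["thresholds"]),
        monitor=MonitorParams(**groups["monitor"]),
        alpha_mm=groups[""].get("alpha_mm", DEFAULT_ALPHA_MM),
    )


def save_config(cfg: MatConfig, path: str | Path) -> None:
    """Write ``cfg`` back as a flat key-value file (inverse of load_config)."""
    lines = []
    for key, (group, attr, _conv) in _KEY_MAP.items():
        obj = cfg if group == "" else getattr(cfg, group)
        lines.append(f"{key} = {getattr(obj, attr)}")
    Path(path).write_text("\n".join(lines) + "\n")


def asdict(cfg: MatConfig) -> dict:
    return dataclasses.asdict(cfg)
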