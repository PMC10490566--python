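"""Pressure-frame data model, file I/O, filtering, segmentation and COP.

A frame is one timestamped snapshot of the raw sensor matrix.  The processing
chain mirrors the deployed pipeline: the calibration frame Mc and every
training frame Mt are first high-pass filtered (cells below beta are zeroed),
then segmented into a left-foot matrix Ml (left half of the columns) and a
right-foot matrix Mr (right half), from which per-foot centers of pressure
COPl / COPr and the overall COPo are computed as pressure-weighted centroids
of the cell-center coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .config import FilterParams, SensorConfig
from .errors import FrameFormatError, ShapeMismatchError, ZeroPressureError

#: recognised frame roles: calibration, training, left half, right half
ROLES = ("Mc", "Mt", "Ml", "Mr")


@dataclass
class PressureFrame:
    """One raw pressure matrix.

    ``col_offset`` records, for a half-frame, which full-frame column its
    column 0 corresponds to, so that x coordinates computed from a half-frame
    stay in the full mat's frame of reference.
    """

    values: np.ndarray
    timestamp_ms: int = 0
    role: str = "Mt"
    col_offset: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ShapeMismatchError("frame values must be a 2-D matrix")
        if self.role not in ROLES:
            raise ValueError(f"unknown frame role {self.role!r}")
        if np.any(self.values < 0):
            raise FrameFormatError("negative pressure value")

    @property
    def total_pressure(self) -> int:
        return int(self.values.sum())

    def validate(self, config: SensorConfig) -> None:
        """Check shape and value range against a sensor configuration."""
        if self.role in ("Mc", "Mt") and self.values.shape != (config.n_rows, config.n_cols):
            raise ShapeMismatchError(
                f"frame shape {self.values.shape} != configured "
                f"({config.n_rows}, {config.n_cols})")
        if np.any(self.values > config.max_value):
            raise FrameFormatError(
                f"value exceeds {config.max_value} (2**{config.bit_depth} - 1)")


@dataclass(frozen=True)
class CopPoint:
    """A center of pressure in mat coordinates (mm), with the load behind it."""

    x: float
    y: float
    total_pressure: float = 0.0

    def displacement(self, other: "CopPoint") -> tuple[float, float]:
        """(dx, dy) from ``other`` to this point, in mm."""
        return (self.x - other.x, self.y - other.y)


def read_frame(path: str | Path, config: SensorConfig, role: str = "Mt") -> PressureFrame:
    """Read a whitespace-delimited integer matrix with a ``# rows cols timestamp_ms`` header."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise FrameFormatError(f"{path}: missing '# rows cols timestamp_ms' header")
        fields = header[1:].split()
        if len(fields) != 3:
            raise FrameFormatError(f"{path}: header must carry rows, cols, timestamp_ms")
        try:
            n_rows, n_cols, ts = (int(f) for f in fields)
        except ValueError as exc:
            raise FrameFormatError(f"{path}: non-integer header field") from exc
        try:
            values = np.loadtxt(fh, dtype=np.int64, ndmin=2)
        except ValueError as exc:
            raise FrameFormatError(f"{path}: non-integer cell value") from exc
    if values.shape != (n_rows, n_cols):
        raise ShapeMismatchError(
            f"{path}: body shape {values.shape} != header ({n_rows}, {n_cols})")
    frame = PressureFrame(values, timestamp_ms=ts, role=role)
    frame.validate(config)
    return frame


def write_frame(frame: PressureFrame, path: str | Path) -> None:
    """Write a frame in the text format accepted by :func:`read_frame`."""
    n_rows, n_cols = frame.values.shape
    with Path(path).open("w") as fh:
        fh.write(f"# {n_rows} {n_cols} {frame.timestamp_ms}\n")
        for row in frame.values:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def filter_frame(frame: PressureFrame, params: FilterParams) -> PressureFrame:
    """Zero every cell strictly below beta; cells at or above it pass unchanged.

    beta = 0 is the identity.  The operation is idempotent and never
    increases any cell.
    """
    filtered = np.where(frame.values < params.beta, 0, frame.values)
    return replace(frame, values=filtered)


def split_left_right(frame: PressureFrame, config: SensorConfig) -> tuple[PressureFrame, PressureFrame]:
    """Segment a filtered full frame into the half matrices Ml and Mr.

    Ml holds columns [0, n_cols // 2) and Mr the rest; with an odd column
    count the extra column goes to the right half.  Total pressure is
    conserved exactly.
    """
    split = config.n_cols // 2
    left = PressureFrame(frame.values[:, :split].copy(), frame.timestamp_ms, "Ml", 0)
    right = PressureFrame(frame.values[:, split:].copy(), frame.timestamp_ms, "Mr", split)
    return left, right


def cell_centers(frame: PressureFrame, config: SensorConfig) -> tuple[np.ndarray, np.ndarray]:
    """(X, Y) mm coordinates of each cell center, full-mat frame of reference."""
    n_rows, n_cols = frame.values.shape
    x = (frame.col_offset + np.arange(n_cols) + 0.5) * config.pitch_x
    y = (np.arange(n_rows) + 0.5) * config.pitch_y
    return np.meshgrid(x, y)


def compute_cop(frame: PressureFrame, config: SensorConfig) -> CopPoint:
    """Pressure-weighted centroid of the cell-center coordinates.

    Raises :class:`ZeroPressureError` when the frame carries no load.
    """
    values = frame.values.astype(float)
    total = values.sum()
    if total <= 0:
        raise ZeroPressureError("no load on the mat: COP undefined")
    X, Y = cell_centers(frame, config)
    return CopPoint(float((values * X).sum() / total),
                    float((values * Y).sum() / total),
                    float(total))


def mirror_frame(frame: PressureFrame) -> PressureFrame:
    """Reflect a full frame left<->right (columns reversed)."""
    return replace(frame, values=frame.values[:, ::-1].copy())
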