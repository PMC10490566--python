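"""Heat-map export of filtered frames as plain (P2) portable graymaps.

One gray level per cell, row-major, maxval equal to the sensor's full scale
(4095 at 12-bit), so the file round-trips losslessly with :func:`read_pgm`
and renders in any PGM viewer the way the deployed app visualises frames.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .config import SensorConfig
from .errors import FrameFormatError
from .frame import PressureFrame


def render_heatmap(frame: PressureFrame, path: str | Path,
                   config: SensorConfig = SensorConfig()) -> None:
    """Write a filtered frame as a P2 PGM with maxval 2**bit_depth - 1."""
    values = np.asarray(frame.values)
    if np.any(values > config.max_value):
        raise FrameFormatError("frame exceeds the configured full scale")
    n_rows, n_cols = values.shape
    lines = [f"P2", f"{n_cols} {n_rows}", str(config.max_value)]
    lines += [" ".join(str(int(v)) for v in row) for row in values]
    Path(path).write_text("\n".join(lines) + "\n")


def read_pgm(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a plain P2 PGM; returns (matrix, maxval)."""
    tokens: list[str] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0]
        tokens.extend(line.split())
    if not tokens or tokens[0] != "P2":
        raise FrameFormatError(f"{path}: not a plain (P2) PGM")
    n_cols, n_rows, maxval = int(tokens[1]), int(tokens[2]), int(tokens[3])
    data = np.array([int(t) for t in tokens[4:]], dtype=np.int64)
    if data.size != n_rows * n_cols:
        raise FrameFormatError(f"{path}: expected {n_rows * n_cols} samples, got {data.size}")
    if np.any(data > maxval) or np.any(data < 0):
        raise FrameFormatError(f"{path}: sample outside [0, {maxval}]")
    return data.reshape(n_rows, n_cols), maxval
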