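"""Foot-blob geometry: centroid, toe-out angle, heel/forefoot split, stance metrics.

The foot's long axis is estimated as the principal axis of the pressure-
weighted second central moments of the loaded cells (the standard image-
moments estimator).  The 180-degree axis ambiguity is resolved by orienting
the axis with a positive anterior (y) component; the toe angle is then the
axis' deviation from the anterior axis, reported outward-positive for the
given side (toes toward -x is outward for the left foot, toward +x for the
right).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .config import SensorConfig
from .errors import DegenerateBlobError, EmptyHalfError
from .frame import CopPoint, PressureFrame, cell_centers, compute_cop

_DEGENERACY_EPS = 1e-9
#: connected components below this fraction of the strongest component's
#: load are treated as residual sensor speckle, not part of the foot
_SPECKLE_FRAC = 0.05


@dataclass(frozen=True)
class FootRegion:
    """One detected foot blob on a half-frame."""

    side: str                      # "left" | "right"
    centroid: CopPoint             # full-mat mm coordinates
    toe_angle_deg: float           # outward-positive rotation from the anterior axis
    heel_load_frac: float
    fore_load_frac: float
    total_pressure: float
    bbox: tuple[int, int, int, int]  # (row_min, row_max, col_min, col_max), inclusive,
                                     # full-frame indices
    axis: tuple[float, float] = (0.0, 1.0)  # unit principal axis, anterior-positive


def principal_axis(x_mm: np.ndarray, y_mm: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """Unit major axis of a weighted point set, oriented anterior-positive.

    Raises :class:`DegenerateBlobError` for fewer than 3 loaded points or a
    collinear configuration (the minor second moment vanishing).
    """
    w = np.asarray(weights, float)
    loaded = w > 0
    if loaded.sum() < 3:
        raise DegenerateBlobError("need at least 3 loaded cells for an axis")
    x = np.asarray(x_mm, float)[loaded]
    y = np.asarray(y_mm, float)[loaded]
    w = w[loaded]
    total = w.sum()
    cx, cy = (w * x).sum() / total, (w * y).sum() / total
    dx, dy = x - cx, y - cy
    sxx = (w * dx * dx).sum() / total
    syy = (w * dy * dy).sum() / total
    sxy = (w * dx * dy).sum() / total
    # eigenvalues of [[sxx, sxy], [sxy, syy]]
    half_tr = 0.5 * (sxx + syy)
    disc = math.hypot(0.5 * (sxx - syy), sxy)
    lam_min = half_tr - disc
    if lam_min < _DEGENERACY_EPS * max(half_tr, 1.0):
        raise DegenerateBlobError("collinear blob: minor axis has no spread")
    theta = 0.5 * math.atan2(2.0 * sxy, sxx - syy)  # major axis angle from x-axis
    vx, vy = math.cos(theta), math.sin(theta)
    if vy < 0 or (vy == 0 and vx < 0):
        vx, vy = -vx, -vy
    return vx, vy


def foot_orientation(x_mm: np.ndarray, y_mm: np.ndarray, weights: np.ndarray,
                     side: str) -> float:
    """Outward-positive toe angle (degrees) of a weighted cell set.

    The angle is measured between the principal axis and the anterior (y)
    axis; a right foot rotated toward +x and a left foot rotated toward -x
    both report positive ("toes pointing outwards").
    """
    vx, vy = principal_axis(x_mm, y_mm, weights)
    angle = math.degrees(math.atan2(vx, vy))  # signed toward +x
    return angle if side == "right" else -angle


def heel_fore_split(x_mm: np.ndarray, y_mm: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """Fractions of load posterior/anterior of the principal-axis midpoint.

    The boundary is the perpendicular bisector of the blob's extent along
    its (anterior-oriented) principal axis.  Anchoring the boundary at the
    extent midpoint rather than the centroid keeps it between heel and
    forefoot even under strongly uneven loading, so a foot carrying all its
    load in the heel reports a heel fraction of 1.
    """
    vx, vy = principal_axis(x_mm, y_mm, weights)
    w = np.asarray(weights, float)
    total = w.sum()
    proj = np.asarray(x_mm, float) * vx + np.asarray(y_mm, float) * vy
    loaded = proj[w > 0]
    midpoint = 0.5 * (loaded.min() + loaded.max())
    fore = float(w[proj > midpoint].sum() / total)
    return 1.0 - fore, fore


def foot_mask(values: np.ndarray) -> np.ndarray:
    """Loaded-cell mask of the foot, with speckle components removed.

    The high-pass filter can leave isolated noise cells, and a foot itself
    splits into disconnected heel and forefoot components; so all
    8-connected components carrying at least ``_SPECKLE_FRAC`` of the
    strongest component's load are kept.
    """
    labels, n = ndimage.label(values > 0, structure=np.ones((3, 3), dtype=int))
    if n <= 1:
        return values > 0
    loads = ndimage.sum_labels(values, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(loads >= _SPECKLE_FRAC * loads.max()) + 1
    return np.isin(labels, keep)


def detect_foot(half: PressureFrame, config: SensorConfig, side: str) -> FootRegion:
    """Extract the single foot blob of a filtered half-frame.

    On a clean half the centroid equals :func:`~mabumat.frame.compute_cop`
    of the half-frame; residual speckle outside the blob is excluded.
    Raises :class:`EmptyHalfError` when no cell is loaded and
    :class:`DegenerateBlobError` when the blob cannot anchor an axis.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    if half.total_pressure <= 0:
        raise EmptyHalfError(f"no load on the {side} half: no foot present")
    masked = replace(half, values=np.where(foot_mask(half.values), half.values, 0))
    centroid = compute_cop(masked, config)
    X, Y = cell_centers(masked, config)
    w = masked.values.astype(float)
    vx, vy = principal_axis(X.ravel(), Y.ravel(), w.ravel())
    angle = math.degrees(math.atan2(vx, vy))
    toe = angle if side == "right" else -angle
    heel, fore = heel_fore_split(X.ravel(), Y.ravel(), w.ravel())
    rows, cols = np.nonzero(masked.values)
    bbox = (int(rows.min()), int(rows.max()),
            int(cols.min()) + half.col_offset, int(cols.max()) + half.col_offset)
    return FootRegion(side=side, centroid=centroid, toe_angle_deg=toe,
                      heel_load_frac=heel, fore_load_frac=fore,
                      total_pressure=float(masked.total_pressure), bbox=bbox,
                      axis=(vx, vy))


@dataclass(frozen=True)
class StanceMetrics:
    """Whole-stance geometry derived from the two detected feet."""

    stance_width_mm: float          # Euclidean distance between foot centroids
    centerline_offset_left_mm: float
    centerline_offset_right_mm: float
    lr_balance: float               # |Pl - Pr| / (Pl + Pr), in [0, 1]


def stance_metrics(left: FootRegion, right: FootRegion, config: SensorConfig) -> StanceMetrics:
    """Stance width, per-foot center-line offsets and left/right load balance."""
    dx = right.centroid.x - left.centroid.x
    dy = right.centroid.y - left.centroid.y
    mid_y = config.width_mm / 2.0
    p_l, p_r = left.total_pressure, right.total_pressure
    return StanceMetrics(
        stance_width_mm=math.hypot(dx, dy),
        centerline_offset_left_mm=abs(left.centroid.y - mid_y),
        centerline_offset_right_mm=abs(right.centroid.y - mid_y),
        lr_balance=abs(p_l - p_r) / (p_l + p_r),
    )
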