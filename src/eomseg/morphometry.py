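"""Per-muscle thickness and cross-sectional area from multiclass label volumes.

On each coronal slice the muscle cross-section is nearly elliptical, so its
thickness is taken as the short side of the minimum-area rotated rectangle
enclosing the segmented contour, and its area as the pixel count times the
pixel area.  The overall per-muscle thickness and area are the maxima of the
per-slice profiles across all coronal slices.

Geometry is computed on the set of pixel *corners* (pixels as unit squares)
scaled per axis to millimetres, so an axis-aligned w×h-pixel block on an
isotropic grid measures exactly w×h pixels, and anisotropic pixel spacing is
handled exactly rather than by resampling.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from skimage import measure as skmeasure

from .volume import LabelVolume

__all__ = ["MinAreaRect", "SizeReport", "min_area_rect", "slice_thickness",
           "slice_area", "measure_volume"]

log = logging.getLogger(__name__)


@dataclass
class MinAreaRect:
    """Minimum-area rotated rectangle in mm coordinates (row, col)."""

    center: tuple[float, float]
    long: float
    short: float
    angle_deg: float  # orientation of the long side, from the row axis

    def __post_init__(self) -> None:
        if not (0 < self.short <= self.long):
            raise ValueError(f"need 0 < short ≤ long, got {self.short}, {self.long}")


def _hull_points(points: np.ndarray) -> np.ndarray:
    if len(points) < 3:
        return points
    try:
        hull = ConvexHull(points)
        return points[hull.vertices]
    except QhullError:  # degenerate (collinear) point sets
        return points


def min_area_rect(points: np.ndarray) -> MinAreaRect:
    """Minimum-area enclosing rotated rectangle of a 2-D point set.

    Uses the rotating-calipers property: some side of the optimal rectangle
    is collinear with a convex-hull edge, so only hull-edge orientations need
    to be scanned.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("points must be a non-empty (n, 2) array")
    hull = _hull_points(pts)
    edges = np.diff(np.vstack([hull, hull[:1]]), axis=0)
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    edges = edges[lengths > 1e-12]
    if len(edges) == 0:  # all points coincide
        raise ValueError("degenerate point set (all points identical)")
    angles = np.unique(np.mod(np.arctan2(edges[:, 1], edges[:, 0]), np.pi / 2))

    best = None
    for th in angles:
        c, s = np.cos(th), np.sin(th)
        rot = hull @ np.array([[c, -s], [s, c]])
        mins, maxs = rot.min(axis=0), rot.max(axis=0)
        w0, w1 = maxs - mins
        area = w0 * w1
        # exact area ties happen on symmetric rasterisations; prefer the more
        # elongated rectangle — its short side is the meaningful thickness
        key = (round(float(area), 9), round(float(min(w0, w1)), 9))
        if best is None or key < best[0]:
            best = (key, th, mins, maxs, (w0, w1))
    _, th, mins, maxs, (w0, w1) = best
    c, s = np.cos(th), np.sin(th)
    mid = (mins + maxs) / 2.0
    centre = mid @ np.array([[c, s], [-s, c]])
    long_side, short_side = max(w0, w1), min(w0, w1)
    # angle of the long side in original coordinates
    axis = 0 if w0 >= w1 else 1
    direction = np.array([[c, s], [-s, c]])[axis]
    angle = float(np.degrees(np.arctan2(direction[1], direction[0])) % 180.0)
    return MinAreaRect(
        center=(float(centre[0]), float(centre[1])),
        long=float(long_side),
        short=float(max(short_side, 1e-12)),
        angle_deg=angle,
    )


def _corner_points(mask: np.ndarray, spacing: tuple[float, float]) -> np.ndarray:
    """Corners of all mask pixels (pixels as unit squares), scaled to mm."""
    rr, cc = np.nonzero(mask)
    sp_r, sp_c = spacing
    corners = np.concatenate(
        [
            np.stack([rr, cc], axis=1),
            np.stack([rr + 1, cc], axis=1),
            np.stack([rr, cc + 1], axis=1),
            np.stack([rr + 1, cc + 1], axis=1),
        ]
    ).astype(float)
    corners = np.unique(corners, axis=0)
    corners[:, 0] *= sp_r
    corners[:, 1] *= sp_c
    return corners


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = skmeasure.label(mask, connectivity=2, return_num=True)
    if n <= 1:
        return mask
    log.warning("mask has %d connected components; measuring the largest", n)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == sizes.argmax()


def slice_thickness(
    mask: np.ndarray, pixel_spacing: float | tuple[float, float]
) -> tuple[float, MinAreaRect] | tuple[None, None]:
    """Thickness (mm) of one muscle cross-section: min-area-rect short side.

    Empty masks signal an absent muscle with ``(None, None)`` rather than an
    exception.  Multiple connected components (anatomically spurious) are
    reduced to the largest before fitting.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return None, None
    if np.isscalar(pixel_spacing):
        spacing = (float(pixel_spacing), float(pixel_spacing))
    else:
        spacing = (float(pixel_spacing[0]), float(pixel_spacing[1]))
    mask = _largest_component(mask)
    rect = min_area_rect(_corner_points(mask, spacing))
    return rect.short, rect


def slice_area(
    mask: np.ndarray, pixel_spacing: float | tuple[float, float]
) -> float:
    """Cross-sectional area in mm²: pixel count × pixel area (0 if empty)."""
    mask = np.asarray(mask).astype(bool)
    if np.isscalar(pixel_spacing):
        px_area = float(pixel_spacing) ** 2
    else:
        px_area = float(pixel_spacing[0]) * float(pixel_spacing[1])
    return float(mask.sum()) * px_area


@dataclass
class SizeReport:
    """Per-muscle maximum thickness/area with per-slice profiles."""

    thickness_mm: dict[int, float] = field(default_factory=dict)
    thickness_slice: dict[int, int] = field(default_factory=dict)
    area_mm2: dict[int, float] = field(default_factory=dict)
    area_slice: dict[int, int] = field(default_factory=dict)
    thickness_profile: dict[int, list] = field(default_factory=dict)
    area_profile: dict[int, list] = field(default_factory=dict)
    absent: list[int] = field(default_factory=list)
    source_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in sorted(self.thickness_mm):
            rows.append(
                {
                    "class": c,
                    "thickness_mm": self.thickness_mm[c],
                    "thickness_slice": self.thickness_slice[c],
                    "area_mm2": self.area_mm2[c],
                    "area_slice": self.area_slice[c],
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self) -> str:
        return json.dumps(
            {
                "source_id": self.source_id,
                "thickness_mm": {str(k): v for k, v in self.thickness_mm.items()},
                "thickness_slice": {str(k): v for k, v in self.thickness_slice.items()},
                "area_mm2": {str(k): v for k, v in self.area_mm2.items()},
                "area_slice": {str(k): v for k, v in self.area_slice.items()},
                "thickness_profile": {
                    str(k): v for k, v in self.thickness_profile.items()
                },
                "area_profile": {str(k): v for k, v in self.area_profile.items()},
                "absent": self.absent,
            },
            indent=2,
        )


def measure_volume(labels: LabelVolume) -> SizeReport:
    """Per-class thickness/area profiles and their maxima over coronal slices.

    Classes absent from every slice are reported in ``absent`` rather than as
    zero-thickness muscles.
    """
    report = SizeReport(source_id=labels.source_id)
    spacing = labels.pixel_spacing
    arr = labels.labels
    for c in labels.scheme.muscle_classes():
        t_prof: list[float | None] = []
        a_prof: list[float] = []
        for sl in arr:
            m = sl == c
            t, _ = slice_thickness(m, spacing)
            t_prof.append(t)
            a_prof.append(slice_area(m, spacing))
        if all(t is None for t in t_prof):
            report.absent.append(c)
            continue
        t_arr = np.array([np.nan if t is None else t for t in t_prof])
        a_arr = np.asarray(a_prof)
        ti = int(np.nanargmax(t_arr))
        ai = int(np.argmax(a_arr))
        report.thickness_mm[c] = float(t_arr[ti])
        report.thickness_slice[c] = ti
        report.area_mm2[c] = float(a_arr[ai])
        report.area_slice[c] = ai
        report.thickness_profile[c] = [None if np.isnan(t) else float(t) for t in t_arr]
        report.area_profile[c] = [float(a) for a in a_arr]
    return report
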