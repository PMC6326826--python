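"""Band geometry: normalized coordinates, regions, thickness, DEJ frames.

Coordinates are image coordinates (``x`` = column, ``y`` = row, origin top
left).  Angles are in degrees, counterclockwise from the 3 o'clock direction
with the y axis pointing *up*, i.e. ``angle(v) = atan2(-vy, vx)``; axial
quantities (tangents, rod axes) live on [0, 180).  The x axis runs from the
lateral CEJ (left) to the mesial CEJ (right).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScaleInfo:
    """Image scale in pixels per micrometer."""

    pixels_per_um: float

    def __post_init__(self) -> None:
        if self.pixels_per_um <= 0:
            raise ValueError("pixels_per_um must be positive")


@dataclass
class EnamelMap:
    """Geometry (and optionally raster layers) of one enamel-band section.

    Polylines are ``(N, 2)`` float arrays of pixel coordinates ordered
    lateral to mesial.  ``layers`` maps category names to single-channel
    uint8 rasters sharing ``(height_px, width_px)``.
    """

    width_px: int
    height_px: int
    scale: ScaleInfo
    dej_polyline: np.ndarray
    surface_polyline: np.ndarray
    layer_boundary_polyline: np.ndarray
    cej_lateral: np.ndarray
    cej_mesial: np.ndarray
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("dej_polyline", "surface_polyline", "layer_boundary_polyline"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
                raise ValueError(f"{name} must be an (N>=2, 2) array")
            setattr(self, name, arr)
        self.cej_lateral = np.asarray(self.cej_lateral, dtype=float)
        self.cej_mesial = np.asarray(self.cej_mesial, dtype=float)

    # -- cached shapely accessors ------------------------------------------
    @property
    def dej_line(self) -> LineString:
        if not hasattr(self, "_dej_line"):
            self._dej_line = LineString(self.dej_polyline)
        return self._dej_line

    @property
    def surface_line(self) -> LineString:
        if not hasattr(self, "_surface_line"):
            self._surface_line = LineString(self.surface_polyline)
        return self._surface_line

    @property
    def boundary_line(self) -> LineString:
        if not hasattr(self, "_boundary_line"):
            self._boundary_line = LineString(self.layer_boundary_polyline)
        return self._boundary_line

    @property
    def band_polygon(self):
        if not hasattr(self, "_band_polygon"):
            ring = np.vstack([self.dej_polyline, self.surface_polyline[::-1]])
            self._band_polygon = shapely.Polygon(ring)
        return self._band_polygon

    @property
    def bounding_box(self) -> tuple[float, float, float, float]:
        """(min_x, min_y, max_x, max_y) of the enamel layer, in pixels."""
        pts = np.vstack([self.dej_polyline, self.surface_polyline])
        return (
            float(pts[:, 0].min()),
            float(pts[:, 1].min()),
            float(pts[:, 0].max()),
            float(pts[:, 1].max()),
        )


@dataclass(frozen=True)
class ThicknessMeasurement:
    total_um: float
    inner_um: float
    outer_um: float
    #: surface point (px) where the measurement was anchored
    location: tuple[float, float]


# ---------------------------------------------------------------------------
# normalized (virtual) coordinates and regions
# ---------------------------------------------------------------------------

def normalize_coords(profiles: pd.DataFrame, emap: EnamelMap) -> pd.DataFrame:
    """Append ``norm_x``/``norm_y`` columns from the layer bounding box.

    norm = (value - min) / (max - min) per axis, so the box corners map to
    0 and 1 exactly.
    """
    x0, y0, x1, y1 = emap.bounding_box
    if x1 - x0 <= 0 or y1 - y0 <= 0:
        raise ValueError("degenerate bounding box: zero extent")
    out = profiles.copy()
    out["norm_x"] = (out["centroid_x"] - x0) / (x1 - x0)
    out["norm_y"] = (out["centroid_y"] - y0) / (y1 - y0)
    return out


def denormalize_coords(norm_xy: np.ndarray, emap: EnamelMap) -> np.ndarray:
    x0, y0, x1, y1 = emap.bounding_box
    norm_xy = np.asarray(norm_xy, dtype=float)
    return np.column_stack(
        [x0 + norm_xy[..., 0] * (x1 - x0), y0 + norm_xy[..., 1] * (y1 - y0)]
    )


def assign_region(norm_x) -> np.ndarray | int:
    """Four equal half-open lateral-to-mesial bins; norm_x = 1 -> region 4."""
    arr = np.asarray(norm_x, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("norm_x outside [0, 1]")
    region = np.minimum(1 + np.floor(4 * arr).astype(int), 4)
    return int(region) if np.isscalar(norm_x) else region


# ---------------------------------------------------------------------------
# thickness at the point of maximum convexity
# ---------------------------------------------------------------------------

def _smooth_polyline(poly: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(poly) < 5:
        return poly
    from scipy.ndimage import uniform_filter1d

    w = min(window | 1, max(3, len(poly) // 2 | 1))
    return np.column_stack(
        [uniform_filter1d(poly[:, i], size=w, mode="nearest") for i in range(2)]
    )


def _curvature(poly: np.ndarray) -> np.ndarray:
    d = np.gradient(poly, axis=0)
    dd = np.gradient(d, axis=0)
    speed = np.hypot(d[:, 0], d[:, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (d[:, 0] * dd[:, 1] - d[:, 1] * dd[:, 0]) / speed**3
    return np.nan_to_num(kappa)


def _ray_intersection(origin: np.ndarray, direction: np.ndarray, line: LineString,
                      reach: float) -> np.ndarray | None:
    seg = LineString([origin - direction * reach, origin + direction * reach])
    hit = seg.intersection(line)
    if hit.is_empty:
        return None
    pts = shapely.get_coordinates(hit)
    d = np.hypot(pts[:, 0] - origin[0], pts[:, 1] - origin[1])
    return pts[np.argmin(d)]


def measure_thickness(emap: EnamelMap, smooth_window_px: int = 51) -> ThicknessMeasurement:
    """Total/inner/outer enamel thickness at the point of maximum convexity.

    The anchor is the point of largest absolute curvature of the smoothed
    outer-surface polyline; a flat surface (curvature below numerical noise)
    falls back to the mid-x point.  Thickness is measured along the local
    surface normal to its intersections with the DEJ and the inner/outer
    layer boundary.
    """
    smoothed = _smooth_polyline(emap.surface_polyline, smooth_window_px)
    kappa = np.abs(_curvature(smoothed))
    interior = slice(len(smoothed) // 10 + 1, -(len(smoothed) // 10 + 1) or None)
    if kappa[interior].max() < 1e-6:  # flat band
        idx = len(smoothed) // 2
    else:
        idx = int(np.argmax(kappa[interior])) + (len(smoothed) // 10 + 1)
    # anchor and tangent from the original polyline: smoothing is only used
    # to locate the convexity maximum (it shrinks curved arcs inward)
    surf = emap.surface_polyline
    p = surf[idx]
    lo, hi = max(idx - 3, 0), min(idx + 4, len(surf))
    tangent = surf[hi - 1] - surf[lo]
    tangent = tangent / np.hypot(*tangent)
    normal = np.array([-tangent[1], tangent[0]])
    reach = 10.0 * (emap.width_px + emap.height_px)
    dej_pt = _ray_intersection(p, normal, emap.dej_line, reach)
    if dej_pt is None:
        raise ValueError("surface normal does not intersect the DEJ")
    bnd_pt = _ray_intersection(p, normal, emap.boundary_line, reach)
    if bnd_pt is None:
        raise ValueError("surface normal does not intersect the layer boundary")
    s = emap.scale.pixels_per_um
    total = float(np.hypot(*(p - dej_pt))) / s
    inner = float(np.hypot(*(dej_pt - bnd_pt))) / s
    return ThicknessMeasurement(total, inner, total - inner, (float(p[0]), float(p[1])))


# ---------------------------------------------------------------------------
# depth fractions
# ---------------------------------------------------------------------------

def depth_fraction(profiles: pd.DataFrame, emap: EnamelMap,
                   tolerance_px: float = 3.0) -> pd.DataFrame:
    """Append ``depth_fraction``: 0 on the DEJ, 1 on the outer surface.

    Computed as d(DEJ) / (d(DEJ) + d(surface)) so the measurement is exact
    for both straight and curved bands.  Profiles outside the band (beyond
    ``tolerance_px``) raise with the offending ids.
    """
    pts = shapely.points(profiles[["centroid_x", "centroid_y"]].to_numpy())
    d_dej = shapely.distance(pts, emap.dej_line)
    d_surf = shapely.distance(pts, emap.surface_line)
    inside = shapely.dwithin(pts, emap.band_polygon, tolerance_px)
    if not inside.all():
        bad = profiles.index[~inside].tolist()[:10]
        raise ValueError(f"profiles outside the enamel band: {bad}")
    out = profiles.copy()
    out["depth_fraction"] = d_dej / (d_dej + d_surf)
    return out


# ---------------------------------------------------------------------------
# DEJ-relative angle frame
# ---------------------------------------------------------------------------

def angle_relative_to_dej(angle_section_deg, dej_tangent_deg):
    """Rotate section-frame axial angles into the local DEJ frame."""
    return np.mod(np.asarray(angle_section_deg, float) - dej_tangent_deg, 180.0)


def dej_tangent_angles(points_xy: np.ndarray, emap: EnamelMap,
                       window_um: float = 50.0) -> np.ndarray:
    """Local DEJ tangent direction (degrees, [0,180)) nearest each point.

    The tangent is the principal direction of a total-least-squares line fit
    to the DEJ polyline vertices inside a sliding arclength window centred
    on the projection of the query point.
    """
    poly = emap.dej_polyline
    seg = np.hypot(*np.diff(poly, axis=0).T)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    half = 0.5 * window_um * emap.scale.pixels_per_um

    # prefix sums for O(1) windowed covariance
    x, y = poly[:, 0], poly[:, 1]
    cums = np.column_stack([x, y, x * x, x * y, y * y])
    pref = np.vstack([np.zeros(5), np.cumsum(cums, axis=0)])

    from scipy.spatial import cKDTree

    _, nearest = cKDTree(poly).query(np.asarray(points_xy, dtype=float))
    lo = np.searchsorted(arclen, arclen[nearest] - half)
    hi = np.searchsorted(arclen, arclen[nearest] + half, side="right")
    hi = np.maximum(hi, lo + 2)

    n = (hi - lo).astype(float)
    sx, sy, sxx, sxy, syy = (pref[hi] - pref[lo]).T
    cxx = sxx / n - (sx / n) ** 2
    cxy = sxy / n - (sx / n) * (sy / n)
    cyy = syy / n - (sy / n) ** 2
    # principal axis of the 2x2 covariance; image y flipped into math frame
    theta = 0.5 * np.degrees(np.arctan2(2 * -cxy, cxx - cyy))
    return np.mod(theta, 180.0)
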