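"""Synthetic enamel-band maps with known ground truth.

The generator emulates the cross-sectional architecture of the mouse
mandibular incisor enamel band: a curved (or flat) band of configurable
thickness whose inner layer holds oval rod profiles chained into
alternating-tilt rows running from near the DEJ to the inner/outer layer
boundary, an outer layer of tightly packed diamond-shaped profiles, and
small disorganised blob zones abutting the two CEJs.  Every profile carries
a ground-truth category, centroid, axial angle, row membership and region,
so the measurement pipeline can be validated by parameter recovery.

Angular noise: each profile's axial angle is drawn around the
region-anchored circular mean of its category.  The default noise family is
a truncated normal on (0, 180) whose location is numerically calibrated so
that the *population circular mean* equals the configured anchor exactly
(folding a wrapped normal onto the axial half-turn would bias recovered
means by up to ~3 degrees at the configured SDs); a plain wrapped normal is
available via ``GeneratorConfig.angle_noise = "wrapped"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely import affinity
from scipy.spatial import cKDTree
from scipy.special import ndtr, ndtri
from skimage.draw import polygon as draw_polygon

from .config import (CATEGORY_COLORS, GenerationError, GeneratorConfig, apportion)
from .geometry import EnamelMap, ScaleInfo

logger = logging.getLogger(__name__)

_REGION_CENTERS = np.array([0.125, 0.375, 0.625, 0.875])
_MARGIN_UM = 4.0


class RenderError(RuntimeError):
    pass


@dataclass
class GroundTruthRecord:
    """Generator-side truth for one rod profile."""

    profile_id: int
    category: str
    tilt: str  # "mesial"/"lateral" for inner categories, "" otherwise
    x_px: float
    y_px: float
    angle_deg: float
    row_id: int  # 0 for non-inner profiles
    seq_index: int
    region: int
    shape: str
    polygon: shapely.Polygon  # pixel coordinates


# ---------------------------------------------------------------------------
# band frame
# ---------------------------------------------------------------------------

class BandFrame:
    """Maps band coordinates (arclength s along the DEJ, depth d) to the
    image plane (um, y down).  Arc mode bends the band on a circular DEJ of
    the configured radius with the outer surface on the convex side."""

    def __init__(self, cfg: GeneratorConfig):
        self.cfg = cfg
        self.W = float(cfg.band_length_um)
        self.T = float(cfg.thickness_um)
        self.flat = cfg.is_flat
        m = _MARGIN_UM
        if self.flat:
            self.width_um = self.W + 2 * m
            self.height_um = self.T + 2 * m
            self._x0 = m
            self._y0 = m
        else:
            self.R = float(cfg.curvature)
            self.delta = self.W / (2 * self.R)
            if self.delta >= np.pi / 2:
                raise GenerationError("band arc exceeds a half turn; increase the radius")
            rs = self.R + self.T
            self.width_um = 2 * rs * np.sin(self.delta) + 2 * m
            self.height_um = self.R * (1 - np.cos(self.delta)) + self.T + 2 * m
            self.cx = m + rs * np.sin(self.delta)
            self.cy = m - self.R * np.cos(self.delta)

    def point(self, s, d):
        """Image point (um) at arclength ``s`` along the DEJ and depth ``d``."""
        s, d = np.broadcast_arrays(np.asarray(s, dtype=float), np.asarray(d, dtype=float))
        if self.flat:
            return np.stack([self._x0 + s, self._y0 + d], axis=-1)
        phi = (s - self.W / 2) / self.R
        return np.stack(
            [self.cx + (self.R + d) * np.sin(phi), self.cy + (self.R + d) * np.cos(phi)],
            axis=-1,
        )

    def tangent_angle_deg(self, s):
        """DEJ tangent direction at arclength ``s`` (y-up angle convention)."""
        if self.flat:
            return np.zeros_like(np.asarray(s, dtype=float))
        return np.degrees((np.asarray(s, dtype=float) - self.W / 2) / self.R)

    def depth(self, xy):
        xy = np.asarray(xy, dtype=float)
        if self.flat:
            return xy[..., 1] - self._y0
        return np.hypot(xy[..., 0] - self.cx, xy[..., 1] - self.cy) - self.R

    def arclength(self, xy):
        xy = np.asarray(xy, dtype=float)
        if self.flat:
            return xy[..., 0] - self._x0
        phi = np.arctan2(xy[..., 0] - self.cx, xy[..., 1] - self.cy)
        return self.W / 2 + phi * self.R


# ---------------------------------------------------------------------------
# angle fields and calibrated angular noise
# ---------------------------------------------------------------------------

def _interp_anchor(anchors, norm_x, mode: str):
    anchors = np.asarray(anchors, dtype=float)
    nx = np.clip(np.asarray(norm_x, dtype=float), 0.0, 1.0)
    if mode == "step":
        region = np.minimum(np.floor(4 * nx).astype(int), 3)
        return anchors[region]
    return np.interp(nx, _REGION_CENTERS, anchors)


@lru_cache(maxsize=512)
def _calibrated_location(target: float, sd: float, family: str) -> float:
    """Location parameter whose population circular mean equals ``target``.

    For the truncated family the density is a normal truncated to (0, 180);
    for the wrapped family a normal folded mod 180.  The circular mean of
    either, with angles read as directions on the full circle, is computed
    by quadrature and inverted by bisection (the mean is monotone in the
    location).
    """
    if sd <= 1e-9:
        return target

    def circ_mean(mu: float) -> float:
        if family == "truncated":
            lo, hi = max(0.0, mu - 8 * sd), min(180.0, mu + 8 * sd)
            if hi <= lo:
                return 0.0 if mu < 90 else 180.0
            x = np.linspace(lo, hi, 3001)
            pdf = np.exp(-0.5 * ((x - mu) / sd) ** 2)
            ang = np.radians(x)
        else:  # wrapped
            x = np.linspace(mu - 8 * sd, mu + 8 * sd, 6001)
            pdf = np.exp(-0.5 * ((x - mu) / sd) ** 2)
            ang = np.radians(x % 180.0)
        c = np.trapezoid(np.cos(ang) * pdf, x)
        s = np.trapezoid(np.sin(ang) * pdf, x)
        return float(np.degrees(np.arctan2(s, c)) % 180.0)

    lo, hi = target - 8 * sd - 180.0, target + 8 * sd + 180.0
    if not (circ_mean(lo) <= target <= circ_mean(hi)):
        return target  # calibration infeasible; fall back to the anchor
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if circ_mean(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _sample_field_angles(rng: np.random.Generator, field, norm_x: np.ndarray,
                         interp_mode: str, family: str) -> np.ndarray:
    """Axial angles in [0, 180) whose population circular means follow the
    region-anchored field.  Locations are calibrated once per anchor and
    interpolated, so both interpolation modes stay cheap."""
    mus4 = tuple(
        _calibrated_location(round(float(a), 4), round(float(s), 4), family)
        for a, s in zip(field.anchors, field.sd)
    )
    mus = np.atleast_1d(_interp_anchor(mus4, norm_x, interp_mode))
    sds = np.atleast_1d(_interp_anchor(field.sd, norm_x, interp_mode))
    u = rng.uniform(size=len(mus))
    out = np.empty(len(mus))
    zero = sds <= 1e-9
    out[zero] = mus[zero]
    nz = ~zero
    if np.any(nz):
        if family == "truncated":
            a = ndtr((0.0 - mus[nz]) / sds[nz])
            b = ndtr((180.0 - mus[nz]) / sds[nz])
            out[nz] = mus[nz] + sds[nz] * ndtri(a + u[nz] * (b - a))
        else:
            z = ndtri(u[nz])
            out[nz] = np.mod(mus[nz] + sds[nz] * z, 180.0)
    return np.clip(out, 0.0, np.nextafter(180.0, 0.0))


# ---------------------------------------------------------------------------
# geometry construction
# ---------------------------------------------------------------------------

def build_band_geometry(config: GeneratorConfig) -> EnamelMap:
    """Band geometry only (polylines, CEJ endpoints); layers left empty."""
    frame = BandFrame(config)
    ppu = config.pixels_per_um
    n_pts = max(int(frame.W) + 1, 2)
    s = np.linspace(0.0, frame.W, n_pts)
    dej = frame.point(s, 0.0) * ppu
    surface = frame.point(s, frame.T) * ppu
    boundary = frame.point(s, float(config.inner_um)) * ppu
    emap = EnamelMap(
        width_px=int(np.ceil(frame.width_um * ppu)),
        height_px=int(np.ceil(frame.height_um * ppu)),
        scale=ScaleInfo(ppu),
        dej_polyline=dej,
        surface_polyline=surface,
        layer_boundary_polyline=boundary,
        cej_lateral=frame.point(0.0, frame.T / 2) * ppu,
        cej_mesial=frame.point(frame.W, frame.T / 2) * ppu,
    )
    return emap


# ---------------------------------------------------------------------------
# shape factories (um coordinates, y down; axial angle convention y-up)
# ---------------------------------------------------------------------------

def _axis_vectors(angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    t = np.radians(angle_deg)
    u = np.array([np.cos(t), -np.sin(t)])  # long axis, y-down image frame
    v = np.array([np.sin(t), np.cos(t)])
    return u, v


def _ellipse_poly(center, angle_deg, a, b, n=24) -> shapely.Polygon:
    u, v = _axis_vectors(angle_deg)
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = center + 0.5 * a * np.cos(t)[:, None] * u + 0.5 * b * np.sin(t)[:, None] * v
    return shapely.Polygon(pts)


def _lens_poly(center, angle_deg, a, b, n=32) -> shapely.Polygon:
    """Pointed oval (sharp-tipped ellipse) used for inner rod profiles.

    Sharp tips give the rendered profile a well-defined maximal Feret pair,
    as the etched rod profiles do; a blunt-ended digital ellipse leaves the
    maximum degenerate over several boundary pixels.
    """
    u, v = _axis_vectors(angle_deg)
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x = 0.5 * a * np.cos(t)
    y = 0.5 * b * np.sin(t) * np.sqrt(np.abs(np.sin(t)))
    pts = center + x[:, None] * u + y[:, None] * v
    return shapely.Polygon(pts)


def _rhombus_poly(center, angle_deg, d1, d2) -> shapely.Polygon:
    u, v = _axis_vectors(angle_deg)
    pts = np.array([center + 0.5 * d1 * u, center + 0.5 * d2 * v,
                    center - 0.5 * d1 * u, center - 0.5 * d2 * v])
    return shapely.Polygon(pts)


def _blob_poly(center, angle_deg, a, b, irregularity, harmonics) -> shapely.Polygon:
    """Randomly perturbed ellipse for disorganised CEJ profiles."""
    u, v = _axis_vectors(angle_deg)
    t = np.linspace(0, 2 * np.pi, 16, endpoint=False)
    c1, s1, c2, s2 = harmonics
    r = 1.0 + irregularity * (c1 * np.cos(t) + s1 * np.sin(t)
                              + c2 * np.cos(2 * t) + s2 * np.sin(2 * t))
    r = np.clip(r, 0.6, 1.4)
    pts = center + (0.5 * a * np.cos(t) * r)[:, None] * u + (0.5 * b * np.sin(t) * r)[:, None] * v
    return shapely.Polygon(pts)


# ---------------------------------------------------------------------------
# layout sampling
# ---------------------------------------------------------------------------

def _bbox_norm_x(emap: EnamelMap):
    x0, _, x1, _ = emap.bounding_box
    ppu = emap.scale.pixels_per_um

    def norm(x_um):
        return np.clip((np.asarray(x_um) * ppu - x0) / (x1 - x0), 0.0, 1.0)

    return norm


def _walk_row(frame: BandFrame, cfg: GeneratorConfig, norm_x, tilt: str,
              start_s: float, stretch: float = 1.0,
              jitter: np.ndarray | None = None, max_sites: int = 10**6,
              clip_x: bool = True):
    """Sites along one inner row path from the DEJ to the layer boundary.

    The path follows the tilt category's *mean* angle field evaluated at the
    local normalized x; step length is the local spacing-field value (times
    ``stretch`` and per-step ``jitter``)."""
    field = cfg.angle_fields["inner_mesial" if tilt == "mesial" else "inner_lateral"]
    spacing = cfg.spacing_fields["inner_mesial" if tilt == "mesial" else "inner_lateral"]
    d0, d_max = 2.6, float(cfg.inner_um) - 2.0
    x_lo, x_hi = 19.0, frame.W - 19.0
    p = frame.point(start_s, d0)
    sites = []
    k = 0
    while k < max_sites:
        d = float(frame.depth(p))
        s_here = float(frame.arclength(p))
        if d > d_max:
            break
        if clip_x and (s_here < x_lo or s_here > x_hi):
            break
        nx = float(norm_x(p[0]))
        sites.append((p[0], p[1], nx))
        # paths follow the smoothly interpolated mean field even when rod
        # angles are sampled from the per-region (step) field: a step field
        # would bend the chain ~30 deg at a region edge in a single link
        theta = float(_interp_anchor(field.anchors, nx, "linear"))
        step = float(_interp_anchor(spacing, nx, "step")) * stretch
        if jitter is not None:
            step *= jitter[min(k, len(jitter) - 1)]
        t = np.radians(theta)
        p = p + step * np.array([-np.cos(t), np.sin(t)])
        k += 1
    return sites


def _row_start_ranges(frame: BandFrame, cfg: GeneratorConfig, norm_x):
    """Per-tilt DEJ start ranges keeping whole row paths inside the band."""
    out = {}
    for tilt in ("mesial", "lateral"):
        lo, hi = 19.0, frame.W - 19.0
        for _ in range(4):
            sites = _walk_row(frame, cfg, norm_x, tilt, lo, clip_x=False)
            if sites:
                s_min = min(float(frame.arclength(np.array(s[:2]))) for s in sites)
                lo += max(0.0, 19.0 - s_min)
            sites = _walk_row(frame, cfg, norm_x, tilt, hi, clip_x=False)
            if sites:
                s_max = max(float(frame.arclength(np.array(s[:2]))) for s in sites)
                hi -= max(0.0, s_max - (frame.W - 19.0))
        if hi <= lo:
            raise GenerationError(f"no admissible {tilt}-tilt row starts; band too short")
        out[tilt] = (lo + 1.0, hi - 1.0)
    return out


def _apportion_capped(total: int, capacities: list[int], what: str, regions: list[int]):
    caps = np.asarray(capacities, dtype=int)
    if caps.sum() < total:
        by_region = {}
        for c, r in zip(caps, regions):
            by_region[r] = by_region.get(r, 0) + c
        limiting = min(by_region, key=by_region.get) if by_region else 0
        raise GenerationError(
            f"infeasible packing: requested {total} {what} profiles but capacity is "
            f"{int(caps.sum())}; limiting region {limiting}"
        )
    weights = caps / caps.sum()
    counts = np.asarray(apportion(total, weights), dtype=int)
    # repair any overfilled entries
    for _ in range(64):
        over = counts - caps
        excess = int(over[over > 0].sum())
        if excess == 0:
            break
        counts = np.minimum(counts, caps)
        slack = caps - counts
        order = np.argsort(-slack, kind="stable")
        for i in order:
            if excess == 0:
                break
            add = min(int(slack[i]), excess)
            counts[i] += add
            excess -= add
    return counts.tolist()


def sample_rod_layout(config: GeneratorConfig, geometry: EnamelMap) -> list[GroundTruthRecord]:
    """Place all rod profiles with ground truth; no two shapes overlap."""
    rng = np.random.default_rng(config.seed)
    frame = BandFrame(config)
    norm_x = _bbox_norm_x(geometry)
    ppu = config.pixels_per_um
    counts = config.category_counts()

    centers: list[np.ndarray] = []   # um
    cats: list[str] = []
    tilts: list[str] = []
    angles: list[float] = []
    row_ids: list[int] = []
    seqs: list[int] = []
    shapes: list[str] = []
    polys: list[shapely.Polygon] = []

    # ---------------- inner rows ----------------
    n_half = config.n_rows // 2
    ranges = _row_start_ranges(frame, config, norm_x)
    starts = []
    for tilt in ("mesial", "lateral"):
        lo, hi = ranges[tilt]
        pitch = (hi - lo) / n_half
        base = lo + (np.arange(n_half) + 0.5) * pitch
        base = base + rng.uniform(-0.02, 0.02, size=n_half) * pitch
        starts.extend((tilt, float(s)) for s in base)

    row_caps = []
    row_regions = []
    for tilt, s0 in starts:
        sites = _walk_row(frame, config, norm_x, tilt, s0)
        row_caps.append(len(sites))
        mid_nx = sites[len(sites) // 2][2] if sites else 0.0
        row_regions.append(int(min(1 + int(4 * mid_nx), 4)))
    row_counts = _apportion_capped(counts["inner"], row_caps, "inner", row_regions)

    a_long, a_short = config.inner_axes_um
    inner_meta = []  # (row_key, seq, tilt, center, nx)
    for row_key, ((tilt, s0), cap, k) in enumerate(zip(starts, row_caps, row_counts)):
        if k == 0:
            continue
        # rods are placed at the configured spacing from the DEJ end; rows
        # with fewer rods than path capacity simply stop short of the layer
        # boundary, keeping realised spacing equal to the spacing field
        jitter = 1.0 + np.clip(0.03 * rng.standard_normal(cap + 4), -0.06, 0.06)
        sites = []
        for shrink in (1.0, 0.97, 0.93):
            sites = _walk_row(frame, config, norm_x, tilt, s0, shrink, jitter,
                              max_sites=k)
            if len(sites) == k:
                break
        if len(sites) < k:
            raise GenerationError(
                f"row at s={s0:.1f} um lost capacity under jitter ({len(sites)}/{k})"
            )
        for seq, (x, y, nx) in enumerate(sites):
            inner_meta.append((row_key, seq, tilt, np.array([x, y]), nx))

    cat_of_tilt = {"mesial": "inner_mesial", "lateral": "inner_lateral"}
    nx_arr = np.array([m[4] for m in inner_meta])
    tilt_arr = np.array([m[2] for m in inner_meta])
    ang_arr = np.empty(len(inner_meta))
    for tilt in ("mesial", "lateral"):
        f = config.angle_fields[cat_of_tilt[tilt]]
        sel = tilt_arr == tilt
        ang_arr[sel] = _sample_field_angles(
            rng, f, nx_arr[sel], config.field_interpolation, config.angle_noise
        )

    for (row_key, seq, tilt, c, nx), ang in zip(inner_meta, ang_arr):
        centers.append(c)
        cats.append(cat_of_tilt[tilt])
        tilts.append(tilt)
        angles.append(float(ang))
        row_ids.append(row_key + 1)  # provisional; renumbered below
        seqs.append(seq)
        shapes.append(f"lens:{a_long}x{a_short}")
        polys.append(_lens_poly(c, ang, a_long, a_short))

    # ---------------- outer layer (staggered columns) ----------------
    spacing_outer = config.spacing_fields["outer"]
    d_lo, d_hi = float(config.inner_um) + 1.6, frame.T - 1.6
    col_x, col_caps, col_off = [], [], []
    s_here = 19.0
    i_col = 0
    while s_here <= frame.W - 19.0:
        nx = float(norm_x(frame.point(s_here, d_lo)[0]))
        sp = float(_interp_anchor(spacing_outer, nx, "step"))
        cap = max(1, int((d_hi - d_lo) / sp))
        col_x.append((s_here, sp))
        col_caps.append(cap)
        col_off.append(0.5 * sp if i_col % 2 else 0.0)
        s_here += sp
        i_col += 1
    col_regions = [int(min(1 + int(4 * float(norm_x(frame.point(s, d_lo)[0]))), 4))
                   for s, _ in col_x]
    col_counts = _apportion_capped(counts["outer"], col_caps, "outer", col_regions)
    d1, d2 = config.outer_diagonals_um
    outer_meta = []
    for i_col, ((s0, sp), cap, k) in enumerate(zip(col_x, col_caps, col_counts)):
        if k == 0:
            continue
        depths = d_lo + (np.arange(k) + (0.25 if i_col % 2 else 0.75)) * sp
        depths += np.clip(0.04 * sp * rng.standard_normal(k), -0.12 * sp, 0.12 * sp)
        depths = np.clip(depths, d_lo, d_hi)
        for d in depths:
            p = frame.point(s0, float(d))
            outer_meta.append((p, float(norm_x(p[0]))))
    f = config.angle_fields["outer"]
    nx_o = np.array([m[1] for m in outer_meta])
    ang_o = _sample_field_angles(rng, f, nx_o, config.field_interpolation,
                                 config.angle_noise)
    for (p, nx), ang in zip(outer_meta, ang_o):
        centers.append(p)
        cats.append("outer")
        tilts.append("")
        angles.append(float(ang))
        row_ids.append(0)
        seqs.append(0)
        shapes.append(f"rhombus:{d1}x{d2}")
        polys.append(_rhombus_poly(p, float(ang), d1, d2))

    # ---------------- CEJ zones ----------------
    n_mesial = int(round(counts["cej"] * config.cej_mesial_fraction))
    n_lateral = counts["cej"] - n_mesial
    sp = float(np.mean(config.spacing_fields["cej"]))
    ca, cb = config.cej_axes_um
    cej_meta = []
    for zone_n, (z_lo, z_hi) in ((n_lateral, (3.0, 17.0)),
                                 (n_mesial, (frame.W - 17.0, frame.W - 3.0))):
        if zone_n == 0:
            continue
        xs = np.arange(z_lo + sp / 2, z_hi - sp / 4, sp)
        zd_lo, zd_hi = 3.0, frame.T - 3.0
        caps = [max(1, int((zd_hi - zd_lo) / sp))] * len(xs)
        ks = _apportion_capped(zone_n, caps, "cej", [1] * len(xs))
        for x0, cap, k in zip(xs, caps, ks):
            if k == 0:
                continue
            depths = zd_lo + (np.arange(k) + 0.5) * sp
            for d in depths:
                jit = np.clip(0.15 * sp * rng.standard_normal(2), -0.3 * sp, 0.3 * sp)
                p = frame.point(float(x0 + jit[0]), float(min(d + jit[1], zd_hi)))
                cej_meta.append((p, float(norm_x(p[0]))))
    if cej_meta:
        f = config.angle_fields["cej"]
        nx_c = np.array([m[1] for m in cej_meta])
        ang_c = _sample_field_angles(rng, f, nx_c, config.field_interpolation,
                                     config.angle_noise)
        for (p, nx), ang in zip(cej_meta, ang_c):
            harmonics = rng.uniform(-1, 1, size=4)
            centers.append(p)
            cats.append("cej")
            tilts.append("")
            angles.append(float(ang))
            row_ids.append(0)
            seqs.append(0)
            shapes.append(f"blob:{ca}x{cb}")
            polys.append(_blob_poly(p, float(ang), ca, cb, config.cej_irregularity, harmonics))

    # ---------------- overlap resolution ----------------
    centers_arr = np.array([c for c in centers])
    polys_arr = np.array(polys, dtype=object)
    _resolve_overlaps(centers_arr, polys_arr, cats, angles, frame, config)

    # renumber inner rows by along-band midpoint position (analysis order)
    inner_idx = [i for i, c in enumerate(cats) if c.startswith("inner")]
    by_row: dict[int, list[float]] = {}
    for i in inner_idx:
        by_row.setdefault(row_ids[i], []).append(float(frame.arclength(centers_arr[i])))
    order = sorted(by_row, key=lambda r: float(np.median(by_row[r])))
    remap = {old: new for new, old in enumerate(order, start=1)}

    records = []
    for pid, i in enumerate(range(len(cats)), start=1):
        cen = shapely.centroid(polys_arr[i])
        records.append(
            GroundTruthRecord(
                profile_id=pid,
                category=cats[i],
                tilt=tilts[i],
                x_px=cen.x * ppu,
                y_px=cen.y * ppu,
                angle_deg=angles[i],
                row_id=remap.get(row_ids[i], 0) if cats[i].startswith("inner") else 0,
                seq_index=seqs[i],
                region=int(min(1 + int(4 * float(norm_x(centers_arr[i][0]))), 4)),
                shape=shapes[i],
                polygon=affinity.scale(polys_arr[i], ppu, ppu, origin=(0, 0)),
            )
        )
    assert len(records) == config.total_profiles
    return records


def _resolve_overlaps(centers, polys, cats, angles, frame: BandFrame,
                      cfg: GeneratorConfig) -> None:
    """Nudge conflicting profiles until all polygon gaps >= clearance.

    Earlier-placed profiles (inner rows, then outer, then CEJ) have
    priority; the later one of a conflicting pair is shifted
    perpendicular to (then along) its own axis by sub-spacing offsets.
    """
    clearance = cfg.clearance_um
    depth_windows = {
        "inner_mesial": (1.2, float(cfg.inner_um) - 1.2),
        "inner_lateral": (1.2, float(cfg.inner_um) - 1.2),
        "outer": (float(cfg.inner_um) + 1.2, frame.T - 1.2),
        "cej": (1.2, frame.T - 1.2),
    }
    tree = cKDTree(centers)
    pairs = np.array(sorted(tree.query_pairs(5.0)))
    if len(pairs) == 0:
        return

    def admissible(k: int, cnew: np.ndarray) -> bool:
        lo, hi = depth_windows[cats[k]]
        if not (lo <= float(frame.depth(cnew)) <= hi):
            return False
        return 2.0 <= float(frame.arclength(cnew)) <= frame.W - 2.0

    def clear_of_neighbors(k: int, cnew, trial, skip: int | None = None,
                           extra=None) -> bool:
        nbrs = [m for m in tree.query_ball_point(cnew, 4.5) if m != k and m != skip]
        if nbrs and float(np.min(shapely.distance(
                trial, polys[np.asarray(nbrs)]))) < clearance:
            return False
        if extra is not None and float(shapely.distance(trial, extra)) < clearance:
            return False
        return True

    def offsets_for(k: int):
        # moves of chained (inner) profiles are capped so neither the
        # within-row gap nor the chain-continuation angle can cross the
        # assembler's gates; free profiles (outer, CEJ) may move further
        u, v = _axis_vectors(angles[k])
        if cats[k].startswith("inner"):
            return ([s * v for s in (0.35, -0.35, 0.7, -0.7, 1.0, -1.0)]
                    + [s * u for s in (0.3, -0.3, 0.5, -0.5)]
                    + [s * (u + v) / np.sqrt(2) for s in (0.7, -0.7)])
        return [s * w for w in (v, u) for s in
                (0.35, -0.35, 0.7, -0.7, 1.0, -1.0)] + [
                    s * (u + v) / np.sqrt(2) for s in (0.8, -0.8, 1.4, -1.4)]

    def try_pair(i: int, j: int) -> bool:
        # single moves (later-placed first), then coordinated double moves,
        # then moves of a shrunken profile (a rod sectioned near its end)
        for scale in (1.0, 0.85, 0.72, 0.6):
            for mover, keeper in ((j, i), (i, j)):
                base = polys[mover] if scale == 1.0 else affinity.scale(
                    polys[mover], scale, scale, origin="centroid")
                offs = offsets_for(mover)
                if scale < 1.0:
                    offs = [np.zeros(2)] + offs
                for off in offs:
                    cnew = centers[mover] + off
                    if not admissible(mover, cnew):
                        continue
                    trial = affinity.translate(base, float(off[0]), float(off[1]))
                    if clear_of_neighbors(mover, cnew, trial):
                        centers[mover] = cnew
                        polys[mover] = trial
                        return True
            if _try_double(i, j, scale):
                return True
        return False

    def _try_double(i: int, j: int, scale: float = 1.0) -> bool:
        base_i = polys[i] if scale == 1.0 else affinity.scale(
            polys[i], scale, scale, origin="centroid")
        base_j = polys[j] if scale == 1.0 else affinity.scale(
            polys[j], scale, scale, origin="centroid")
        for off_i in offsets_for(i)[:8]:
            ci = centers[i] + off_i
            if not admissible(i, ci):
                continue
            ti = affinity.translate(base_i, float(off_i[0]), float(off_i[1]))
            if not clear_of_neighbors(i, ci, ti, skip=j):
                continue
            for off_j in offsets_for(j)[:8]:
                cj = centers[j] + off_j
                if not admissible(j, cj):
                    continue
                tj = affinity.translate(base_j, float(off_j[0]), float(off_j[1]))
                if not clear_of_neighbors(j, cj, tj, skip=i, extra=ti):
                    continue
                centers[i], polys[i] = ci, ti
                centers[j], polys[j] = cj, tj
                return True
        return False

    for sweep in range(6):
        d = shapely.distance(polys[pairs[:, 0]], polys[pairs[:, 1]])
        bad = pairs[d < clearance]
        if len(bad) == 0:
            return
        for i, j in bad:
            i, j = int(i), int(j)
            if shapely.distance(polys[i], polys[j]) >= clearance:
                continue
            if not try_pair(i, j):
                raise GenerationError(
                    f"could not resolve overlap between profiles {i} and {j}"
                )
    d = shapely.distance(polys[pairs[:, 0]], polys[pairs[:, 1]])
    if np.any(d < clearance):
        raise GenerationError("overlap resolution did not converge")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_color_maps(records: list[GroundTruthRecord], geometry: EnamelMap) -> EnamelMap:
    """Rasterise records into four binary category layers (uint8 0/255)."""
    h, w = geometry.height_px, geometry.width_px
    layers = {cat: np.zeros((h, w), dtype=np.uint8) for cat in CATEGORY_COLORS}
    band = shapely.Polygon(
        np.vstack([geometry.dej_polyline, geometry.surface_polyline[::-1]])
    ).buffer(1.5)
    shapely.prepare(band)
    if records:
        ok = shapely.covers(band, np.array([r.polygon for r in records], dtype=object))
        if not ok.all():
            bad = [records[i].profile_id for i in np.nonzero(~ok)[0][:10]]
            raise RenderError(f"profiles outside the enamel band: {bad}")
    for rec in records:
        coords = np.asarray(rec.polygon.exterior.coords)
        rr, cc = draw_polygon(coords[:, 1], coords[:, 0], shape=(h, w))
        layers[rec.category][rr, cc] = 255
    geometry.layers = layers
    return geometry


def composite_rgb(emap: EnamelMap) -> np.ndarray:
    """White-background RGB preview of the four category layers."""
    h, w = emap.height_px, emap.width_px
    rgb = np.full((h, w, 3), 255, dtype=np.uint8)
    for cat, color in CATEGORY_COLORS.items():
        mask = emap.layers.get(cat)
        if mask is not None:
            rgb[mask > 0] = color
    return rgb


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def records_to_frame(records: list[GroundTruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "profile_id": [r.profile_id for r in records],
            "category": [r.category for r in records],
            "tilt": [r.tilt for r in records],
            "x_px": [r.x_px for r in records],
            "y_px": [r.y_px for r in records],
            "angle_deg": [r.angle_deg for r in records],
            "row_id": [r.row_id for r in records],
            "seq_index": [r.seq_index for r in records],
            "region": [r.region for r in records],
            "shape": [r.shape for r in records],
        }
    )


def simulate(config: GeneratorConfig) -> tuple[EnamelMap, pd.DataFrame, list[GroundTruthRecord]]:
    """Generate a full synthetic map: geometry, rendered layers and truth."""
    emap = build_band_geometry(config)
    records = sample_rod_layout(config, emap)
    render_color_maps(records, emap)
    return emap, records_to_frame(records), records


def save_map(emap: EnamelMap, truth: pd.DataFrame, outdir: str | Path) -> list[Path]:
    """Write category layers (PNG), composite, truth CSV and geometry CSVs."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for cat, layer in emap.layers.items():
        p = outdir / f"layer_{cat}.png"
        iio.imwrite(p, layer)
        written.append(p)
    p = outdir / "composite.png"
    iio.imwrite(p, composite_rgb(emap))
    written.append(p)
    p = outdir / "ground_truth.csv"
    truth.to_csv(p, index=False)
    written.append(p)
    for name in ("dej_polyline", "surface_polyline", "layer_boundary_polyline"):
        p = outdir / f"{name}.csv"
        pd.DataFrame(getattr(emap, name), columns=["x_px", "y_px"]).to_csv(p, index=False)
        written.append(p)
    meta = pd.DataFrame(
        {
            "key": ["width_px", "height_px", "pixels_per_um",
                    "cej_lateral_x", "cej_lateral_y", "cej_mesial_x", "cej_mesial_y"],
            "value": [emap.width_px, emap.height_px, emap.scale.pixels_per_um,
                      *emap.cej_lateral, *emap.cej_mesial],
        }
    )
    p = outdir / "map_meta.csv"
    meta.to_csv(p, index=False)
    written.append(p)
    return written
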