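"""Circular statistics, decussation angles, spacing and DWLS smoothing.

Tilt angles are treated as directions on [0, 360) even though measured
Feret angles live on [0, 180): the plain (undoubled) circular mean is the
convention used for enamel-rod tilt data, e.g. the circular mean of
{30, 60, 80} degrees is ~57 degrees.  Circular SD follows the standard
sqrt(-2 ln R) definition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CircularSummary:
    n: int
    mean_deg: float
    circular_sd_deg: float
    resultant_length: float


def circular_mean(angles_deg) -> CircularSummary:
    """Mean direction, resultant length and circular SD of angle data."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("circular_mean of empty input")
    c, s = np.cos(a).mean(), np.sin(a).mean()
    r = min(float(np.hypot(c, s)), 1.0)
    mean = float(np.degrees(np.arctan2(s, c)) % 360.0)
    if mean >= 360.0:  # (-eps) % 360 rounds up to 360.0
        mean = 0.0
    sd = float("inf") if r <= 0 else float(np.degrees(np.sqrt(-2.0 * np.log(r))))
    return CircularSummary(int(a.size), mean, sd, r)


def decussation_from_means(mean_a_deg: float, mean_b_deg: float) -> float:
    """Smallest absolute angular difference of two mean directions, [0, 180]."""
    d = abs(mean_a_deg - mean_b_deg) % 360.0
    return float(min(d, 360.0 - d))


def inter_row_angle(row_a, row_b, transition: str | None = None) -> float:
    """Wide angle where two rows of opposite tilt abut: 180 deg minus the
    decussation angle of the pair.

    ``row_a``/``row_b`` are mappings with ``tilt`` and ``mean_angle_deg``
    fields (e.g. rows of the per-row summary table).  ``transition`` labels
    the a->b direction and is validated against the tilts when given.
    """
    tilt_a, tilt_b = row_a["tilt"], row_b["tilt"]
    if tilt_a == tilt_b:
        raise ValueError(f"inter_row_angle needs opposite tilts, got {tilt_a!r} twice")
    expected = f"{tilt_a}_to_{tilt_b}"
    if transition is not None and transition != expected:
        raise ValueError(f"transition {transition!r} does not match tilts ({expected})")
    return 180.0 - decussation_from_means(row_a["mean_angle_deg"], row_b["mean_angle_deg"])


def decussation_by_rows(rows: pd.DataFrame, profiles: pd.DataFrame | None = None,
                        region_restricted: bool = False,
                        min_members_per_region: int = 3) -> pd.DataFrame:
    """Per-adjacent-pair decussation and alternating inter-row angles.

    ``rows`` is a per-row summary table with ``row_id``, ``tilt``,
    ``mean_angle_deg``, ``midpoint_x`` and ``region``; pairs are formed
    between rows adjacent in along-band (midpoint x) order.  Pairs whose
    tilts do not alternate are skipped with a logged warning.

    With ``region_restricted=True`` (requires ``profiles`` carrying
    ``row_id``, ``feret_angle_deg`` and ``region``), each pair's row means
    are recomputed from members inside each region separately, reproducing
    the row-by-row regional measurement; otherwise each pair contributes a
    single angle computed from whole-row means and is binned by the pair's
    mean midpoint region.
    """
    cols = ["row_a", "row_b", "region", "transition",
            "decussation_deg", "inter_row_angle_deg"]
    if len(rows) < 2:
        return pd.DataFrame(columns=cols)
    ordered = rows.sort_values("midpoint_x", kind="stable").reset_index(drop=True)
    if region_restricted:
        if profiles is None:
            raise ValueError("region_restricted pairing needs the per-rod table")
        member_groups = {
            key: g for key, g in profiles.groupby(["row_id", "region"], observed=True)
        }
    out = []
    skipped = 0
    for a, b in zip(ordered.index[:-1], ordered.index[1:]):
        ra, rb = ordered.loc[a], ordered.loc[b]
        if ra["tilt"] == rb["tilt"]:
            skipped += 1
            continue
        transition = f"{ra['tilt']}_to_{rb['tilt']}"
        if region_restricted:
            for region in (1, 2, 3, 4):
                ga = member_groups.get((ra["row_id"], region))
                gb = member_groups.get((rb["row_id"], region))
                if ga is None or gb is None:
                    continue
                if len(ga) < min_members_per_region or len(gb) < min_members_per_region:
                    continue
                ma = circular_mean(ga["feret_angle_deg"]).mean_deg
                mb = circular_mean(gb["feret_angle_deg"]).mean_deg
                dec = decussation_from_means(ma, mb)
                out.append((ra["row_id"], rb["row_id"], region, transition, dec, 180.0 - dec))
        else:
            dec = decussation_from_means(ra["mean_angle_deg"], rb["mean_angle_deg"])
            region = int(round(0.5 * (ra["region"] + rb["region"])))
            out.append((ra["row_id"], rb["row_id"], region, transition, dec, 180.0 - dec))
    if skipped:
        logger.warning("decussation_by_rows: skipped %d non-alternating adjacent pairs", skipped)
    return pd.DataFrame(out, columns=cols)


def nearest_neighbor_distances(centroids: np.ndarray) -> np.ndarray:
    """Distance from each point to its closest other point."""
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("need at least 2 points")
    d, _ = cKDTree(pts).query(pts, k=2)
    return d[:, 1]


def spacing_summary(profiles: pd.DataFrame, scale_pixels_per_um: float) -> pd.DataFrame:
    """Regional spacing table.

    Inner-enamel spacing is the within-row sequential inter-centroid
    distance (each gap assigned to the region of the gap midpoint, keyed by
    tilt); outer and CEJ spacing are nearest-neighbour distances grouped by
    the rod's region.  Distances are reported in micrometers.  Empty groups
    are simply absent from the table.
    """
    s = scale_pixels_per_um
    rows_out = []
    inner = profiles[profiles["category"].isin(("inner_mesial", "inner_lateral"))]
    if len(inner):
        for (cat, row_id), g in inner.groupby(["category", "row_id"], observed=True):
            g = g.sort_values("seq_index", kind="stable")
            xy = g[["centroid_x", "centroid_y"]].to_numpy()
            if len(xy) < 2:
                continue
            gaps = np.hypot(*np.diff(xy, axis=0).T) / s
            mid_nx = 0.5 * (g["norm_x"].to_numpy()[:-1] + g["norm_x"].to_numpy()[1:])
            region = np.minimum(1 + np.floor(4 * np.clip(mid_nx, 0, 1)).astype(int), 4)
            for r, d in zip(region, gaps):
                rows_out.append((cat, r, d))
    for cat in ("outer", "cej"):
        g = profiles[profiles["category"] == cat]
        if len(g) < 2:
            continue
        nn = nearest_neighbor_distances(g[["centroid_x", "centroid_y"]].to_numpy()) / s
        for r, d in zip(g["region"], nn):
            rows_out.append((cat, int(r), d))
    long = pd.DataFrame(rows_out, columns=["category", "region", "spacing_um"])
    if long.empty:
        return pd.DataFrame(columns=["category", "region", "n", "mean_spacing_um", "sd_spacing_um"])
    out = (
        long.groupby(["category", "region"], observed=True)["spacing_um"]
        .agg(n="size", mean_spacing_um="mean", sd_spacing_um="std")
        .reset_index()
    )
    return out


def category_counts(profiles: pd.DataFrame, rows: pd.DataFrame | None = None) -> dict:
    """Counts and integer percentages per category, plus rows per tilt."""
    counts = profiles["category"].value_counts().to_dict()
    total = int(len(profiles))
    inner = counts.get("inner_mesial", 0) + counts.get("inner_lateral", 0)
    grouped = {"inner": inner, "outer": counts.get("outer", 0), "cej": counts.get("cej", 0)}
    pct = {
        k: (int(round(100.0 * v / total)) if total else 0) for k, v in grouped.items()
    }
    out = {
        "total": total,
        "counts": {**grouped,
                   "inner_mesial": counts.get("inner_mesial", 0),
                   "inner_lateral": counts.get("inner_lateral", 0)},
        "percent": pct,
    }
    if rows is not None:
        tilt_counts = rows["tilt"].value_counts().to_dict()
        out["n_rows"] = {
            "total": int(len(rows)),
            "mesial": int(tilt_counts.get("mesial", 0)),
            "lateral": int(tilt_counts.get("lateral", 0)),
        }
    return out


def dwls_surface(points: np.ndarray, values: np.ndarray, grid_x: np.ndarray,
                 grid_y: np.ndarray, bandwidth: float = 0.25) -> np.ndarray:
    """Distance-weighted least-squares surface on a rectangular grid.

    At each grid node a local *linear* fit is solved with Gaussian distance
    weights of bandwidth ``bandwidth`` times the larger data range.  Exact
    for planar inputs at any bandwidth.  Returns an array of shape
    ``(len(grid_y), len(grid_x))``.
    """
    pts = np.asarray(points, dtype=float)
    z = np.asarray(values, dtype=float)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if len(pts) < 10:
        raise ValueError("need at least 10 points")
    span = max(np.ptp(pts[:, 0]), np.ptp(pts[:, 1]))
    h = bandwidth * span
    out = np.empty((len(grid_y), len(grid_x)))
    design = np.column_stack([np.ones(len(pts)), pts])
    for iy, gy in enumerate(grid_y):
        for ix, gx in enumerate(grid_x):
            d2 = (pts[:, 0] - gx) ** 2 + (pts[:, 1] - gy) ** 2
            w = np.exp(-0.5 * d2 / h**2)
            sw = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(design * sw[:, None], z * sw, rcond=None)
            out[iy, ix] = coef[0] + coef[1] * gx + coef[2] * gy
    return out


def regional_circular_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Circular summaries per (category, region) plus per-category totals."""
    rows = []
    for (cat, region), g in profiles.groupby(["category", "region"], observed=True):
        cs = circular_mean(g["feret_angle_deg"])
        rows.append((cat, int(region), cs.n, cs.mean_deg, cs.circular_sd_deg, cs.resultant_length))
    for cat, g in profiles.groupby("category", observed=True):
        cs = circular_mean(g["feret_angle_deg"])
        rows.append((cat, 0, cs.n, cs.mean_deg, cs.circular_sd_deg, cs.resultant_length))
    return pd.DataFrame(
        rows, columns=["category", "region", "n", "mean_deg", "circular_sd_deg", "resultant_length"]
    ).sort_values(["category", "region"]).reset_index(drop=True)
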