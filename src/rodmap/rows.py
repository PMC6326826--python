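"""Automatic assembly of inner-enamel rod profiles into rows.

A row is a chain of same-tilt rod profiles running diagonally from near the
DEJ toward the inner/outer layer boundary.  The assembler replaces the
manual polygon outlining of rows: candidate links between profiles of one
tilt category are gated by distance (a multiple of the category's median
nearest-neighbour distance) and accepted greedily shortest-first under
three structural constraints — each profile joins at most two links, links
never close a cycle, and a new link must continue the chain direction at an
endpoint rather than fold back on it.  Connected components of the accepted
links are the rows.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import EnamelMap, ScaleInfo
from .stats import circular_mean, nearest_neighbor_distances

logger = logging.getLogger(__name__)


def order_profiles_by_x(profiles: pd.DataFrame) -> pd.DataFrame:
    """Sort by centroid x ascending, ties broken by centroid y ascending."""
    if len(profiles) == 0:
        raise ValueError("no profiles to order")
    return profiles.sort_values(["centroid_x", "centroid_y"], kind="stable")


def inter_centroid_distance(p1, p2) -> float:
    """Euclidean distance between two centroid coordinates."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    return float(np.hypot(*(p2 - p1)))


def _chain_components(n: int, links: list[tuple[int, int]]) -> list[list[int]]:
    """Connected components of a degree<=2 link set, each ordered end-to-end."""
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in links:
        adj[a].append(b)
        adj[b].append(a)
    seen = np.zeros(n, dtype=bool)
    chains = []
    for start in range(n):
        if seen[start]:
            continue
        if len(adj[start]) > 1:
            continue  # start traversal only from endpoints / singletons
        chain = [start]
        seen[start] = True
        prev, cur = -1, start
        while True:
            nxt = [v for v in adj[cur] if v != prev]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            seen[cur] = True
            chain.append(cur)
        chains.append(chain)
    # cycles cannot occur (rejected during linking) but guard anyway
    for start in range(n):
        if not seen[start]:
            chain = [start]
            seen[start] = True
            prev, cur = -1, start
            while True:
                nxt = [v for v in adj[cur] if v != prev and not seen[v]]
                if not nxt:
                    break
                prev, cur = cur, nxt[0]
                seen[cur] = True
                chain.append(cur)
            chains.append(chain)
    return chains


def _merge_fragments(chains: list[list[int]], xy: np.ndarray, gate: float,
                     max_link_deg: float = 60.0, max_dir_deg: float = 45.0) -> list[list[int]]:
    """End-to-end repair of over-segmented chains.

    A locally displaced member can defeat the continuation test and leave a
    short fragment between two chain pieces.  Chains whose endpoints lie
    within the gating distance are re-joined when the smoothed end
    directions are consistent with the bridging link; fragments too short
    to carry a direction (< 3 members) are joined on distance alone.
    """

    def angle_between(v1: np.ndarray, v2: np.ndarray) -> float:
        c = np.dot(v1, v2) / (np.hypot(*v1) * np.hypot(*v2) + 1e-12)
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    merged = True
    while merged and len(chains) > 1:
        merged = False
        ends = []  # (chain index, is_head, node)
        for ci, chain in enumerate(chains):
            ends.append((ci, True, chain[0]))
            if len(chain) > 1:
                ends.append((ci, False, chain[-1]))
        pts = xy[[node for _, _, node in ends]]
        tree = cKDTree(pts)
        cand = sorted(
            (np.hypot(*(pts[a] - pts[b])), a, b)
            for a, b in tree.query_pairs(gate)
            if ends[a][0] != ends[b][0]
        )
        for dist, a, b in cand:
            ca, head_a, na = ends[a]
            cb, head_b, nb = ends[b]
            A = chains[ca][::-1] if head_a else chains[ca]   # merge end last
            B = chains[cb] if head_b else chains[cb][::-1]   # merge end first
            link = xy[B[0]] - xy[A[-1]]
            # smoothed travel direction into A's tail / out of B's head
            da = (xy[A[-1]] - xy[A[-min(3, len(A) - 1) - 1]]) if len(A) >= 3 else None
            db = (xy[B[min(3, len(B) - 1)]] - xy[B[0]]) if len(B) >= 3 else None
            if da is not None and angle_between(da, link) > max_link_deg:
                continue
            if db is not None and angle_between(link, db) > max_link_deg:
                continue
            if da is not None and db is not None and angle_between(da, db) > max_dir_deg:
                continue
            chains[ca] = A + B
            chains.pop(cb)
            merged = True
            break
    return chains


def assemble_rows(profiles: pd.DataFrame, gating_factor: float = 2.5,
                  min_rods: int = 3, min_continuation_deg: float = 120.0,
                  max_neighbors: int = 10) -> pd.DataFrame:
    """Partition one tilt category into row chains.

    Returns a copy of ``profiles`` with ``row_id`` (ordered by along-band
    midpoint x, starting at 1), ``seq_index`` (order along the chain,
    oriented lateral to mesial) and ``row_orphan`` (chains shorter than
    ``min_rods``, flagged for review rather than dropped).
    """
    if len(profiles) == 0:
        raise ValueError("no profiles to assemble")
    out = profiles.copy()
    xy = out[["centroid_x", "centroid_y"]].to_numpy(dtype=float)
    n = len(xy)
    if n == 1:
        out["row_id"] = 1
        out["seq_index"] = 0
        out["row_orphan"] = True
        logger.warning("assemble_rows: single profile -> one orphan row")
        return out

    gate = gating_factor * float(np.median(nearest_neighbor_distances(xy)))
    tree = cKDTree(xy)
    dist, idx = tree.query(xy, k=min(max_neighbors + 1, n))
    cand = []
    for i in range(n):
        for d, j in zip(dist[i, 1:], idx[i, 1:]):
            if j < n and i < j and d <= gate:
                cand.append((d, i, j))
    cand.sort()

    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    degree = np.zeros(n, dtype=int)
    neighbor: list[list[int]] = [[] for _ in range(n)]

    def continues(at: int, new: int) -> bool:
        """New link at an occupied endpoint must extend, not fold back.

        The incoming chain direction is averaged over up to 3 links back so
        that a single laterally displaced member cannot fold the test.
        """
        if degree[at] == 0:
            return True
        prev, cur = neighbor[at][0], at
        for _ in range(2):
            back = [v for v in neighbor[prev] if v != cur]
            if not back:
                break
            cur, prev = prev, back[0]
        v1 = xy[prev] - xy[at]
        v2 = xy[new] - xy[at]
        cosang = np.dot(v1, v2) / (np.hypot(*v1) * np.hypot(*v2) + 1e-12)
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        return ang >= min_continuation_deg

    links = []
    for d, i, j in cand:
        if degree[i] >= 2 or degree[j] >= 2:
            continue
        if find(i) == find(j):
            continue
        if not (continues(i, j) and continues(j, i)):
            continue
        parent[find(i)] = find(j)
        degree[i] += 1
        degree[j] += 1
        neighbor[i].append(j)
        neighbor[j].append(i)
        links.append((i, j))

    chains = _chain_components(n, links)
    chains = _merge_fragments(chains, xy, gate)
    # orient each chain lateral->mesial and order rows along the band
    mid_x = []
    for chain in chains:
        if xy[chain[0], 0] > xy[chain[-1], 0]:
            chain.reverse()
        mid_x.append(float(np.median(xy[chain, 0])))
    order = np.argsort(mid_x, kind="stable")

    row_id = np.empty(n, dtype=int)
    seq = np.empty(n, dtype=int)
    orphan = np.zeros(n, dtype=bool)
    n_orphans = 0
    for new_id, ci in enumerate(order, start=1):
        chain = chains[ci]
        for k, node in enumerate(chain):
            row_id[node] = new_id
            seq[node] = k
        if len(chain) < min_rods:
            orphan[np.asarray(chain)] = True
            n_orphans += 1
    if n_orphans:
        logger.warning("assemble_rows: %d chains shorter than %d flagged as orphans",
                       n_orphans, min_rods)
    out["row_id"] = row_id
    out["seq_index"] = seq
    out["row_orphan"] = orphan
    return out


def summarize_row(members: pd.DataFrame, emap: EnamelMap | None,
                  scale: ScaleInfo) -> dict:
    """Per-row summary variables from chain-ordered members.

    RPR (rods per row), lateral/mesial endpoints, midpoint (middle member
    for odd RPR, mean of the two central centroids for even), perpendicular
    distance from the midpoint to the DEJ, row length as the sum of
    sequential inter-centroid distances, member means of area and Feret
    diameters, and the circular mean of member angles.
    """
    if len(members) == 0:
        raise ValueError("empty row")
    xy = members[["centroid_x", "centroid_y"]].to_numpy(dtype=float)
    k = len(xy)
    first, last = xy[0], xy[-1]
    lateral, mesial = (first, last) if first[0] <= last[0] else (last, first)
    if k % 2:
        midpoint = xy[k // 2]
    else:
        midpoint = 0.5 * (xy[k // 2 - 1] + xy[k // 2])
    s = scale.pixels_per_um
    length_um = float(np.hypot(*np.diff(xy, axis=0).T).sum()) / s
    cs = circular_mean(members["feret_angle_deg"])
    out = {
        "rpr": k,
        "lateral_x": float(lateral[0]), "lateral_y": float(lateral[1]),
        "midpoint_x": float(midpoint[0]), "midpoint_y": float(midpoint[1]),
        "mesial_x": float(mesial[0]), "mesial_y": float(mesial[1]),
        "row_length_um": length_um,
        "mean_area_um2": float(members["area"].mean()) / s**2,
        "mean_feret_max_um": float(members["feret_max"].mean()) / s,
        "mean_feret_min_um": float(members["feret_min"].mean()) / s,
        "mean_angle_deg": cs.mean_deg,
        "circular_sd_deg": cs.circular_sd_deg,
        "resultant_length": cs.resultant_length,
    }
    if emap is not None:
        from shapely.geometry import Point

        out["distance_from_dej_um"] = float(Point(midpoint).distance(emap.dej_line)) / s
    return out


def summarize_rows(profiles: pd.DataFrame, emap: EnamelMap | None,
                   scale: ScaleInfo) -> pd.DataFrame:
    """Per-row summary table from an assembled per-rod table.

    ``profiles`` must carry ``row_id``/``seq_index``/``tilt`` columns (and
    the morphometric fields); identifier columns present in the input
    (mouse/incisor/tooth ids) are propagated.
    """
    recs = []
    for (tilt, row_id), g in profiles.groupby(["tilt", "row_id"], observed=True):
        g = g.sort_values("seq_index", kind="stable")
        rec = {"row_id": row_id, "tilt": tilt,
               "row_orphan": bool(g["row_orphan"].any()) if "row_orphan" in g else False}
        for ident in ("mouse_id", "incisor_id", "tooth_id"):
            if ident in g:
                rec[ident] = g[ident].iloc[0]
        rec.update(summarize_row(g, emap, scale))
        if "norm_x" in g:
            k = len(g)
            mid_nx = (
                g["norm_x"].iloc[k // 2]
                if k % 2
                else 0.5 * (g["norm_x"].iloc[k // 2 - 1] + g["norm_x"].iloc[k // 2])
            )
            rec["region"] = int(min(1 + int(4 * np.clip(mid_nx, 0, 1)), 4))
        recs.append(rec)
    rows = pd.DataFrame.from_records(recs)
    if len(rows):
        rows = rows.sort_values("midpoint_x", kind="stable").reset_index(drop=True)
    return rows
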