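"""Multi-source cost-distance travel time and travel-time zone classes.

Travel time from every cell to its nearest facility is the shortest
accumulated traversal time over the pace surface: cells are 8-connected,
a step between adjacent cells costs
``distance * (pace_a + pace_b) / 2`` with distance = cell size for cardinal
moves and cell size * sqrt(2) for diagonal moves.  This matches standard
raster-GIS cost-distance semantics.  Barrier cells, and cells fully
enclosed by barriers, are unreachable (+inf) and classify as remote.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .grids import Grid
from .synthetic import FacilitySet

__all__ = ["snap_facilities", "cost_distance", "classify_zones",
           "ZONE_CODES", "ZONE_LABELS", "zone_of_minutes"]

#: travel-time class codes and labels (minutes, right-closed intervals)
ZONE_CODES = {"Z30": 1, "Z60": 2, "Z90": 3, "Z120": 4, "ZREMOTE": 5}
ZONE_LABELS = {1: "0-30", 2: "30-60", 3: "60-90", 4: "90-120", 5: ">120"}
_BOUNDS = np.array([30.0, 60.0, 90.0, 120.0])


def snap_facilities(facilities: FacilitySet, pace: Grid, max_snap: int = 3) -> list[tuple[int, int]]:
    """Map each facility to the nearest traversable cell, within ``max_snap``.

    A facility whose own cell is a barrier snaps to the closest (Euclidean
    centre distance, row-major tie-break) non-barrier cell within a
    Chebyshev radius of ``max_snap`` cells; beyond that the facility is
    reported unreachable by name.
    """
    traversable = np.isfinite(np.asarray(pace.data, dtype=float))
    nrows, ncols = pace.shape
    inside = pace.contains_points(facilities.points[:, 0], facilities.points[:, 1])
    if not np.all(inside):
        bad = int(np.flatnonzero(~inside)[0])
        raise ValueError(f"facility {bad} ({facilities.tiers[bad]}) lies outside the grid extent")
    out: list[tuple[int, int]] = []
    for i, (x, y) in enumerate(facilities.points):
        r0, c0 = (int(v) for v in pace.transform.world_to_cell(x, y))
        if traversable[r0, c0]:
            out.append((r0, c0))
            continue
        best = None
        for dr in range(-max_snap, max_snap + 1):
            for dc in range(-max_snap, max_snap + 1):
                r, c = r0 + dr, c0 + dc
                if 0 <= r < nrows and 0 <= c < ncols and traversable[r, c]:
                    key = (dr * dr + dc * dc, r * ncols + c)
                    if best is None or key < best[0]:
                        best = (key, (r, c))
        if best is None:
            raise ValueError(
                f"facility {i} ({facilities.tiers[i]}) has no traversable cell "
                f"within {max_snap} cells")
        out.append(best[1])
    return out


def _edge_list(pace: Grid):
    """Vectorised undirected 8-neighbour edges over traversable cells."""
    p = np.asarray(pace.data, dtype=float)
    nrows, ncols = p.shape
    idx = np.arange(nrows * ncols).reshape(p.shape)
    cell = pace.cell
    rows, cols, weights = [], [], []
    for (dr, dc), mult in (((0, 1), 1.0), ((1, 0), 1.0), ((1, 1), np.sqrt(2)), ((1, -1), np.sqrt(2))):
        a_r = slice(0, nrows - dr)
        b_r = slice(dr, nrows)
        a_c = slice(max(0, -dc), ncols - max(0, dc))
        b_c = slice(max(0, dc), ncols + min(0, dc) if dc < 0 else ncols)
        pa, pb = p[a_r, a_c], p[b_r, b_c]
        ok = np.isfinite(pa) & np.isfinite(pb)
        w = cell * mult * (pa[ok] + pb[ok]) / 2.0
        rows.append(idx[a_r, a_c][ok])
        cols.append(idx[b_r, b_c][ok])
        weights.append(w)
    return (np.concatenate(rows), np.concatenate(cols), np.concatenate(weights))


def cost_distance(pace: Grid, sources: list[tuple[int, int]]) -> Grid:
    """Minutes from every cell to the nearest source over the pace surface.

    Multi-source Dijkstra on the 8-connected cell graph.  Sources must sit
    on traversable cells (use :func:`snap_facilities`); source cells get 0,
    unreachable cells +inf.
    """
    p = np.asarray(pace.data, dtype=float)
    if np.any(p[np.isfinite(p)] <= 0):
        raise ValueError("pace must be positive minutes/metre on traversable cells")
    nrows, ncols = p.shape
    src = [r * ncols + c for r, c in sources]
    if not src:
        raise ValueError("at least one source cell is required")
    for (r, c), s in zip(sources, src):
        if not np.isfinite(p[r, c]):
            raise ValueError(f"source cell ({r}, {c}) is not traversable")
    i, j, w = _edge_list(pace)
    n = nrows * ncols
    graph = coo_matrix((w, (i, j)), shape=(n, n))
    t = dijkstra(graph, directed=False, indices=src, min_only=True)
    t = t.reshape(p.shape)
    t[~np.isfinite(p)] = np.inf
    return pace.like(t)


def zone_of_minutes(minutes) -> np.ndarray:
    """Zone code 1-5 for travel minutes; intervals closed on the right.

    [0,30] -> 1, (30,60] -> 2, (60,90] -> 3, (90,120] -> 4, (120,inf] -> 5.
    Exactly 120 minutes is *not* remote: remote means strictly more than
    two hours.  Unreachable (+inf) is remote.
    """
    m = np.asarray(minutes, dtype=float)
    if np.any(m[~np.isnan(m)] < 0):
        raise ValueError("negative travel time")
    return (np.searchsorted(_BOUNDS, m, side="left") + 1).astype(np.uint8)


def classify_zones(tt: Grid) -> Grid:
    """Reclassify a travel-time grid into the five travel-time zones."""
    return tt.like(zone_of_minutes(tt.data))
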