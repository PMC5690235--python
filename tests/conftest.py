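"""Shared fixtures and independent oracles.

The oracles here are deliberately naive re-implementations (explicit
edge-list Dijkstra, recursive Strahler ordering, per-cell upstream-set
counting) kept independent of the library's vectorised code paths, so
solver/oracle agreement is a real cross-check.
"""

from __future__ import annotations

import heapq

import numpy as np
import pytest

from emoc_access.grids import Grid, GridTransform
from emoc_access.hydrology import D8_OFFSETS, SINK


def make_grid(data, cell=50.0) -> Grid:
    data = np.asarray(data)
    return Grid(data, GridTransform(0.0, data.shape[0] * cell, cell))


@pytest.fixture
def grid_factory():
    return make_grid


def oracle_dijkstra(pace: np.ndarray, sources, cell: float) -> np.ndarray:
    """Brute-force multi-source Dijkstra over the explicit 8-neighbour edge list."""
    nrows, ncols = pace.shape
    dist = {}
    pq = []
    for s in sources:
        dist[s] = 0.0
        heapq.heappush(pq, (0.0, s))
    done = set()
    while pq:
        d, (r, c) = heapq.heappop(pq)
        if (r, c) in done:
            continue
        done.add((r, c))
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                nr, nc = r + dr, c + dc
                if not (0 <= nr < nrows and 0 <= nc < ncols):
                    continue
                if not (np.isfinite(pace[r, c]) and np.isfinite(pace[nr, nc])):
                    continue
                step = cell * (np.sqrt(2) if dr and dc else 1.0) * (pace[r, c] + pace[nr, nc]) / 2.0
                nd = d + step
                if nd < dist.get((nr, nc), np.inf):
                    dist[(nr, nc)] = nd
                    heapq.heappush(pq, (nd, (nr, nc)))
    out = np.full(pace.shape, np.inf)
    for (r, c), d in dist.items():
        out[r, c] = d
    return out


def downstream_of(flowdir: np.ndarray):
    """Map flat cell index -> downstream flat index (or None at sinks)."""
    nrows, ncols = flowdir.shape
    down = {}
    for r in range(nrows):
        for c in range(ncols):
            k = flowdir[r, c]
            if k == SINK:
                down[r * ncols + c] = None
            else:
                dr, dc = D8_OFFSETS[k]
                down[r * ncols + c] = (r + dr) * ncols + (c + dc)
    return down


def oracle_accumulation(flowdir: np.ndarray) -> np.ndarray:
    """O(n^2) accumulation: walk every cell's full downstream path."""
    nrows, ncols = flowdir.shape
    down = downstream_of(flowdir)
    acc = np.ones(nrows * ncols, dtype=int)
    for start in range(nrows * ncols):
        cur = down[start]
        while cur is not None:
            acc[cur] += 1
            cur = down[cur]
    return acc.reshape(flowdir.shape)


def oracle_strahler(flowdir: np.ndarray, stream: np.ndarray) -> np.ndarray:
    """Recursive textbook Strahler ordering over the upstream tree."""
    nrows, ncols = flowdir.shape
    down = downstream_of(flowdir)
    ups: dict[int, list[int]] = {i: [] for i in range(nrows * ncols)}
    for i, d in down.items():
        if d is not None:
            ups[d].append(i)
    flat_stream = stream.ravel()
    memo: dict[int, int] = {}

    def order(i: int) -> int:
        if i in memo:
            return memo[i]
        memo[i] = 0  # guard (acyclic anyway)
        if not flat_stream[i]:
            return 0
        inflows = [order(u) for u in ups[i]]
        inflows = [o for o in inflows if o > 0]
        if not inflows:
            res = 1
        else:
            mx = max(inflows)
            res = mx + 1 if inflows.count(mx) >= 2 else mx
        memo[i] = res
        return res

    return np.array([order(i) for i in range(nrows * ncols)]).reshape(flowdir.shape)


@pytest.fixture(scope="session")
def small_landscape():
    """One deterministic synthetic region shared by integration-style tests."""
    from emoc_access import (gen_census, gen_dem, gen_dwellings, gen_facilities,
                             gen_landcover, gen_roads, gen_zones)

    dem = gen_dem(40, seed=11, cell=250.0)
    landcover = gen_landcover(dem, seed=12)
    roads = gen_roads(dem, n_towns=4, seed=13)
    zones = gen_zones(dem.shape, 5, seed=14, transform=dem.transform)
    facilities = gen_facilities(roads, 2, 1, seed=15)
    dwellings, infra = gen_dwellings(roads, zones, n_points=600, seed=16)
    census = gen_census(zones, seed=17)
    return {
        "dem": dem, "landcover": landcover, "roads": roads, "zones": zones,
        "facilities": facilities, "dwellings": dwellings, "infrastructure": infra,
        "census": census,
    }
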