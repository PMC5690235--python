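"""Stream network derivation from a DEM.

Streams act as seasonal travel barriers in the accessibility model: high
Strahler-order channels are impassable.  The chain here is the classic
raster-hydrology one: fill pits so the surface drains, route flow with D8
(each cell drains to its steepest-descent neighbour of eight), accumulate
contributing area, then threshold and order the channel network.

Flow-direction grids store an index into :data:`D8_OFFSETS` (enumeration
order E, SE, S, SW, W, NW, N, NE — also the deterministic tie-break) or
:data:`SINK` (-1) where a cell drains off-grid.
"""

from __future__ import annotations

import heapq

import numpy as np

from .grids import Grid

__all__ = [
    "D8_OFFSETS", "SINK",
    "fill_pits", "d8_flow", "accumulate_flow", "strahler_order",
]

# E, SE, S, SW, W, NW, N, NE as (drow, dcol); row grows southward
D8_OFFSETS = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]
_D8_DIST = np.array([1.0, np.sqrt(2), 1.0, np.sqrt(2), 1.0, np.sqrt(2), 1.0, np.sqrt(2)])
SINK = -1


def fill_pits(dem: Grid, epsilon: float = 1e-6) -> Grid:
    """Raise internally drained depressions until the surface drains.

    Priority-flood from the grid border: cells are absorbed in order of
    elevation and lifted to at least ``epsilon`` above the cell they were
    reached from, so afterwards every non-border cell has a strictly
    descending path to the border.  Output elevations are >= input
    everywhere; an already-draining DEM passes through (almost) unchanged.
    """
    z = np.asarray(dem.data, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("DEM contains non-finite elevations")
    nrows, ncols = z.shape
    filled = np.full_like(z, np.inf)
    closed = np.zeros(z.shape, dtype=bool)
    heap: list[tuple[float, int]] = []
    for r in range(nrows):
        for c in range(ncols):
            if r in (0, nrows - 1) or c in (0, ncols - 1):
                filled[r, c] = z[r, c]
                closed[r, c] = True
                heapq.heappush(heap, (z[r, c], r * ncols + c))
    while heap:
        elev, idx = heapq.heappop(heap)
        r, c = divmod(idx, ncols)
        for dr, dc in D8_OFFSETS:
            nr, nc = r + dr, c + dc
            if 0 <= nr < nrows and 0 <= nc < ncols and not closed[nr, nc]:
                closed[nr, nc] = True
                filled[nr, nc] = max(z[nr, nc], elev + epsilon)
                heapq.heappush(heap, (filled[nr, nc], nr * ncols + nc))
    return dem.like(filled)


def d8_flow(dem_filled: Grid) -> Grid:
    """Steepest-descent direction of eight for every cell.

    The chosen neighbour maximises drop/distance (diagonal distance is
    sqrt(2) x cell size); exact ties resolve to the first direction in the
    E, SE, S, SW, W, NW, N, NE enumeration.  Cells with no downhill
    neighbour (only possible on the border after pit filling) are sinks.
    """
    z = np.asarray(dem_filled.data, dtype=float)
    grades = np.full((8,) + z.shape, -np.inf)
    for k, (dr, dc) in enumerate(D8_OFFSETS):
        src = (slice(max(0, -dr), z.shape[0] - max(0, dr)),
               slice(max(0, -dc), z.shape[1] - max(0, dc)))
        dst = (slice(max(0, dr), z.shape[0] + min(0, dr) or None),
               slice(max(0, dc), z.shape[1] + min(0, dc) or None))
        # grade toward neighbour k, defined where the neighbour exists
        grades[k][src] = (z[src] - z[dst]) / _D8_DIST[k]
    best = np.argmax(grades, axis=0).astype(np.int8)  # first max = tie-break order
    flowdir = np.where(np.max(grades, axis=0) > 0, best, np.int8(SINK))
    return dem_filled.like(flowdir)


def _downstream_index(flowdir: Grid) -> np.ndarray:
    """Flat index of each cell's downstream cell; -1 at sinks."""
    fd = np.asarray(flowdir.data)
    nrows, ncols = fd.shape
    rr, cc = np.indices(fd.shape)
    down = np.full(fd.shape, -1, dtype=np.int64)
    for k, (dr, dc) in enumerate(D8_OFFSETS):
        sel = fd == k
        nr, nc = rr[sel] + dr, cc[sel] + dc
        if np.any((nr < 0) | (nr >= nrows) | (nc < 0) | (nc >= ncols)):
            raise ValueError("flow direction points outside the grid")
        down[sel] = nr * ncols + nc
    return down.ravel()


def _topological_order(down: np.ndarray) -> np.ndarray:
    """Cells ordered upstream-to-downstream (Kahn); raises on cycles."""
    n = len(down)
    indeg = np.bincount(down[down >= 0], minlength=n)
    order = np.empty(n, dtype=np.int64)
    head = list(np.flatnonzero(indeg == 0))
    pos = 0
    while head:
        i = head.pop()
        order[pos] = i
        pos += 1
        d = down[i]
        if d >= 0:
            indeg[d] -= 1
            if indeg[d] == 0:
                head.append(d)
    if pos != n:
        raise ValueError("flow directions contain a cycle")
    return order


def accumulate_flow(flowdir: Grid) -> Grid:
    """Contributing area in cells: 1 (the cell itself) + all upstream cells.

    The total over sink cells equals the grid cell count (conservation).
    """
    down = _downstream_index(flowdir)
    order = _topological_order(down)
    acc = np.ones(len(down), dtype=np.int64)
    for i in order:
        d = down[i]
        if d >= 0:
            acc[d] += acc[i]
    return flowdir.like(acc.reshape(flowdir.shape))


def strahler_order(flowdir: Grid, accumulation: Grid, stream_threshold: int = 30) -> Grid:
    """Strahler stream order per cell; 0 marks non-stream cells.

    Cells whose contributing area reaches ``stream_threshold`` are stream
    cells.  Headwaters take order 1; where two (or more) inflows share the
    maximum order u the downstream cell takes u + 1; otherwise it takes the
    maximum inflowing order.
    """
    if stream_threshold < 1:
        raise ValueError("stream_threshold must be >= 1")
    down = _downstream_index(flowdir)
    order = _topological_order(down)
    stream = (np.asarray(accumulation.data) >= stream_threshold).ravel()
    strahler = np.zeros(len(down), dtype=np.int16)
    max_in = np.zeros(len(down), dtype=np.int16)  # max inflowing stream order
    n_at_max = np.zeros(len(down), dtype=np.int16)
    for i in order:
        if stream[i]:
            if max_in[i] == 0:
                strahler[i] = 1
            elif n_at_max[i] >= 2:
                strahler[i] = max_in[i] + 1
            else:
                strahler[i] = max_in[i]
            d = down[i]
            if d >= 0:
                if strahler[i] > max_in[d]:
                    max_in[d] = strahler[i]
                    n_at_max[d] = 1
                elif strahler[i] == max_in[d]:
                    n_at_max[d] += 1
    return flowdir.like(strahler.reshape(flowdir.shape))
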