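"""Dasymetric disaggregation of zone census totals onto the grid.

Two methods mirror the two population layers an accessibility study can
draw on: spreading each zone's total evenly over its built-infrastructure
cells, or splitting it equally across individually mapped dwelling points.
Populations stay real-valued throughout — the remoteness index is a
proportion, and rounding to whole persons would only add bias.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .grids import Grid, require_aligned
from .travel_time import ZONE_LABELS, zone_of_minutes

__all__ = ["disaggregate_infrastructure", "disaggregate_points", "join_population_traveltime"]


def _census_by_zone(census: pd.DataFrame) -> pd.Series:
    return census.set_index("zone")["population"].astype(float)


def disaggregate_infrastructure(census: pd.DataFrame, infra: Grid, zones: Grid,
                                fallback: str | None = None) -> Grid:
    """Population grid: each zone's total divided over its infrastructure cells.

    A populated zone with no infrastructure cells is an error by default;
    with ``fallback="uniform"`` its population is spread over all its cells
    (with a warning).  Per-zone sums equal the census totals exactly.
    """
    require_aligned(infra, zones)
    pop = _census_by_zone(census)
    zid = np.asarray(zones.data)
    mask = np.asarray(infra.data, dtype=bool)
    out = np.zeros(zones.shape, dtype=float)
    n_infra = pd.Series(zid[mask]).value_counts()
    for z, total in pop.items():
        if total == 0:
            continue
        n = int(n_infra.get(z, 0))
        zone_cells = zid == z
        if n > 0:
            out[zone_cells & mask] = total / n
        elif fallback == "uniform":
            warnings.warn(f"zone {z}: no infrastructure cells; spreading population uniformly")
            out[zone_cells] = total / zone_cells.sum()
        else:
            raise ValueError(
                f"zone {z} has population {total} but no infrastructure cells "
                "(pass fallback='uniform' to spread it over the whole zone)")
    return zones.like(out)


def disaggregate_points(census: pd.DataFrame, dwellings: np.ndarray, zones: Grid,
                        fallback: str | None = None) -> Grid:
    """Population grid: each zone's total split equally across its dwellings.

    Dwellings are assigned to zones by the cell containing them (half-open
    footprints: a point on a shared edge belongs to the south-east cell),
    then the per-dwelling share is accumulated into cells.
    """
    pts = np.atleast_2d(np.asarray(dwellings, dtype=float))
    pop = _census_by_zone(census)
    zid = np.asarray(zones.data)
    rr, cc = zones.transform.world_to_cell(pts[:, 0], pts[:, 1])
    nrows, ncols = zones.shape
    inside = (rr >= 0) & (rr < nrows) & (cc >= 0) & (cc < ncols)
    if not np.all(inside):
        raise ValueError(f"{int((~inside).sum())} dwelling(s) fall outside the grid")
    dw_zone = zid[rr, cc]
    counts = pd.Series(dw_zone).value_counts()
    out = np.zeros(zones.shape, dtype=float)
    for z, total in pop.items():
        if total == 0:
            continue
        n = int(counts.get(z, 0))
        if n == 0:
            if fallback == "uniform":
                warnings.warn(f"zone {z}: no dwellings; spreading population uniformly")
                out[zid == z] += total / (zid == z).sum()
                continue
            raise ValueError(f"zone {z} has population {total} but no dwellings")
        sel = dw_zone == z
        np.add.at(out, (rr[sel], cc[sel]), total / n)
    return zones.like(out)


def join_population_traveltime(pop: Grid, tt: Grid, zones: Grid) -> pd.DataFrame:
    """One record per populated cell: (zone, minutes, zone label, persons).

    Unreachable cells keep ``minutes = inf`` and the ">120" label; total
    persons are preserved exactly.
    """
    require_aligned(pop, tt, zones)
    p = np.asarray(pop.data, dtype=float)
    sel = p > 0
    minutes = np.asarray(tt.data, dtype=float)[sel]
    codes = zone_of_minutes(minutes)
    return pd.DataFrame({
        "zone": np.asarray(zones.data)[sel],
        "minutes": minutes,
        "zone_label": [ZONE_LABELS[c] for c in codes],
        "persons": p[sel],
    })
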