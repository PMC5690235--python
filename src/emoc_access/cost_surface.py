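"""Per-scenario travel-cost ("pace") surfaces.

A scenario is a transport mode (ambulance "car", or public-transport "bus"
with walking off the major roads) crossed with a season (dry or wet).  Each
land-cover or road class carries a scenario speed in km/h; the pace surface
converts that to minutes per metre (pace = 60 / (1000 * v)).  High-order
streams are burned in as absolute barriers.

Class codes: 0 grass, 1 forest, 2 scrub, 3 rocky (walking speeds), 4 local
road, 5 provincial road, 6 national road.  In the bus scenario local roads
take walking-equivalent speed: buses only run on provincial/national roads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import Grid, require_aligned
from .synthetic import RoadNetwork

__all__ = ["SpeedTable", "ScenarioConfig", "burn_roads", "apply_barriers", "build_pace",
           "CLASS_LABELS", "DEFAULT_SPEEDS"]

CLASS_LABELS = {
    0: "Grass", 1: "Forest", 2: "Scrub", 3: "Rocky",
    4: "Local Road", 5: "Provincial Road", 6: "National Road",
}

#: default speeds (km/h) per (class, mode, season)
DEFAULT_SPEEDS: dict[tuple[int, str, str], float] = {}
for _cls, (_wc, _wb, _dc, _db) in {
    0: (3, 3, 4, 4),
    1: (2, 2, 3.5, 3.5),
    2: (2, 2, 3.5, 3.5),
    3: (1, 1, 2.5, 2.5),
    4: (10, 3.5, 15, 4),
    5: (25, 10, 30, 10),
    6: (25, 40, 60, 40),
}.items():
    DEFAULT_SPEEDS[(_cls, "car", "wet")] = float(_wc)
    DEFAULT_SPEEDS[(_cls, "bus", "wet")] = float(_wb)
    DEFAULT_SPEEDS[(_cls, "car", "dry")] = float(_dc)
    DEFAULT_SPEEDS[(_cls, "bus", "dry")] = float(_db)


@dataclass
class SpeedTable:
    """Mapping (class code 0-6, mode, season) -> speed in km/h."""

    speeds: dict[tuple[int, str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_SPEEDS))

    def __post_init__(self) -> None:
        classes = {k[0] for k in self.speeds}
        if classes != set(range(7)):
            raise ValueError(f"speed table must cover class codes 0..6, has {sorted(classes)}")
        for key, v in self.speeds.items():
            if not v > 0:
                raise ValueError(f"speed for {key} must be positive, got {v}")

    @classmethod
    def default(cls) -> "SpeedTable":
        return cls()

    def speed(self, class_code: int, mode: str, season: str) -> float:
        try:
            return self.speeds[(int(class_code), mode, season)]
        except KeyError:
            raise KeyError(
                f"no speed for class={class_code}, mode={mode!r}, season={season!r}") from None

    def pace(self, class_code: int, mode: str, season: str) -> float:
        """Minutes per metre: 60 / (1000 * speed_kmh)."""
        return 60.0 / (1000.0 * self.speed(class_code, mode, season))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"class": c, "label": CLASS_LABELS[c], "mode": m, "season": s, "kmh": v}
            for (c, m, s), v in sorted(self.speeds.items())
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpeedTable":
        needed = {"class", "mode", "season", "kmh"}
        if not needed <= set(df.columns):
            raise ValueError(f"speed table needs columns {sorted(needed)}")
        return cls({(int(r["class"]), str(r["mode"]), str(r["season"])): float(r["kmh"])
                    for _, r in df.iterrows()})


@dataclass
class ScenarioConfig:
    """One travel-time scenario and the thresholds applied to it.

    ``remoteness_threshold`` is the minutes beyond which a person counts as
    remote (strictly more than two hours by default).  ``barrier_order_min``
    is the lowest Strahler order treated as impassable (default 7, i.e.
    order > 6).  ``barrier_overrides_roads`` decides whether a barrier
    stream crossing a road severs it (no bridges assumed).
    """

    mode: str = "car"
    season: str = "dry"
    remoteness_threshold: float = 120.0
    barrier_order_min: int = 7
    barrier_overrides_roads: bool = True
    barrier_seasons: tuple[str, ...] = ("wet", "dry")
    cell_size: float = 50.0

    def __post_init__(self) -> None:
        if self.mode not in ("car", "bus"):
            raise ValueError(f"mode must be 'car' or 'bus', got {self.mode!r}")
        if self.season not in ("wet", "dry"):
            raise ValueError(f"season must be 'wet' or 'dry', got {self.season!r}")
        if not self.remoteness_threshold > 0:
            raise ValueError("remoteness threshold must be positive minutes")
        if not self.cell_size > 0:
            raise ValueError("cell size must be positive metres")

    @property
    def name(self) -> str:
        return f"{self.mode}_{self.season}"


def _traverse_cells(p0, p1, grid: Grid):
    """Cells whose square footprint a segment passes through (supercover DDA)."""
    t = grid.transform
    nrows, ncols = grid.shape
    x0, y0 = float(p0[0]), float(p0[1])
    x1, y1 = float(p1[0]), float(p1[1])
    dx, dy = x1 - x0, y1 - y0
    row, col = (int(v) for v in t.world_to_cell(x0, y0))
    end_row, end_col = (int(v) for v in t.world_to_cell(x1, y1))
    step_col = 1 if dx > 0 else -1
    step_row = 1 if dy < 0 else -1  # row grows southward
    if dx != 0:
        next_vx = t.x0 + (col + (dx > 0)) * t.cell
        t_max_x = (next_vx - x0) / dx
        t_dx = abs(t.cell / dx)
    else:
        t_max_x, t_dx = np.inf, np.inf
    if dy != 0:
        next_hy = t.y0 - (row + (dy < 0)) * t.cell
        t_max_y = (next_hy - y0) / dy
        t_dy = abs(t.cell / dy)
    else:
        t_max_y, t_dy = np.inf, np.inf
    out = []
    for _ in range(4 * (nrows + ncols) + 4):
        if 0 <= row < nrows and 0 <= col < ncols:
            out.append((row, col))
        if row == end_row and col == end_col:
            break
        if t_max_x <= t_max_y:
            col += step_col
            t_max_x += t_dx
        else:
            row += step_row
            t_max_y += t_dy
    return out


def burn_roads(landcover: Grid, roads: RoadNetwork) -> Grid:
    """Rasterise roads over the cover grid; output codes 0-6.

    A cell takes a road class if the polyline crosses its square footprint
    (supercover traversal, so diagonal roads stay 8-connected); where
    several classes touch one cell the highest code — the fastest road —
    wins.  Roads wholly outside the grid are ignored with a warning.
    """
    burn = np.full(landcover.shape, -1, dtype=np.int16)
    xmin, ymin, xmax, ymax = landcover.transform.extent(landcover.shape)
    for i, road in enumerate(roads.roads):
        cx, cy = road.coords[:, 0], road.coords[:, 1]
        if cx.max() < xmin or cx.min() >= xmax or cy.max() <= ymin or cy.min() > ymax:
            warnings.warn(f"road {i} (class {road.road_class}) lies outside the grid; ignored")
            continue
        for a, b in zip(road.coords[:-1], road.coords[1:]):
            for r, c in _traverse_cells(a, b, landcover):
                if road.road_class > burn[r, c]:
                    burn[r, c] = road.road_class
    out = np.maximum(landcover.data.astype(np.int16), burn)
    return landcover.like(out)


def apply_barriers(class_grid: Grid, streams: Grid, config: ScenarioConfig) -> tuple[Grid, Grid]:
    """Mark impassable stream cells; returns (class grid, boolean barrier mask).

    Cells whose Strahler order reaches ``config.barrier_order_min`` become
    barriers.  With ``barrier_overrides_roads=False`` road cells (codes 4-6,
    i.e. bridges assumed) are exempt.  Seasons outside
    ``config.barrier_seasons`` get an empty mask.
    """
    require_aligned(class_grid, streams)
    if config.season in config.barrier_seasons:
        mask = np.asarray(streams.data) >= config.barrier_order_min
        if not config.barrier_overrides_roads:
            mask = mask & (np.asarray(class_grid.data) < 4)
    else:
        mask = np.zeros(class_grid.shape, dtype=bool)
    return class_grid, class_grid.like(mask)


def build_pace(class_grid: Grid, barrier_mask: Grid, speeds: SpeedTable,
               config: ScenarioConfig) -> Grid:
    """Pace surface in minutes/metre; barrier cells carry +inf."""
    require_aligned(class_grid, barrier_mask)
    codes = np.asarray(class_grid.data)
    if codes.min() < 0 or codes.max() > 6:
        raise ValueError(f"class codes outside 0..6: [{codes.min()}, {codes.max()}]")
    lut = np.array([speeds.pace(c, config.mode, config.season) for c in range(7)])
    pace = lut[codes]
    pace = np.where(np.asarray(barrier_mask.data, dtype=bool), np.inf, pace)
    return class_grid.like(pace)
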