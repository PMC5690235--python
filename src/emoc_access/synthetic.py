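"""Synthetic study regions with known ground truth.

Real inputs to the accessibility pipeline — a DEM, a four-class land cover
(grass, forest, scrub, rocky), a three-tier road network, administrative
zones, facility locations, dwellings, census and mortality tables — are
rarely shareable.  This module generates internally consistent stand-ins for
all of them, deterministically from a seed, so every downstream stage can be
tested end to end and the mortality regression can be checked against the
coefficients that actually generated the deaths.

Conventions: land-cover codes 0 grass, 1 forest, 2 scrub, 3 rocky; road
class codes 4 local, 5 provincial, 6 national (fastest); zone ids 1..K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, MultiLineString

from .grids import Grid, GridTransform

__all__ = [
    "Road",
    "RoadNetwork",
    "FacilitySet",
    "TruthRecord",
    "gen_dem",
    "gen_landcover",
    "gen_roads",
    "gen_zones",
    "gen_facilities",
    "gen_dwellings",
    "gen_census",
    "gen_mortality",
]

GRASS, FOREST, SCRUB, ROCKY = 0, 1, 2, 3
LOCAL_ROAD, PROVINCIAL_ROAD, NATIONAL_ROAD = 4, 5, 6

#: default fraction of women aged 15-45 among all women
DEFAULT_FERTILE_FRACTION = 0.43
DEFAULT_FEMALE_FRACTION = 0.5


@dataclass
class Road:
    road_class: int  # 4 local, 5 provincial, 6 national
    coords: np.ndarray  # (N, 2) world metres

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[0] < 2 or self.coords.shape[1] != 2:
            raise ValueError("road polyline needs >= 2 (x, y) vertices")
        if self.road_class not in (LOCAL_ROAD, PROVINCIAL_ROAD, NATIONAL_ROAD):
            raise ValueError(f"road class must be 4, 5 or 6, got {self.road_class}")

    def line(self) -> LineString:
        return LineString(self.coords)


@dataclass
class RoadNetwork:
    roads: list[Road]

    def classes(self) -> set[int]:
        return {r.road_class for r in self.roads}

    def multiline(self, min_class: int = LOCAL_ROAD) -> MultiLineString:
        lines = [r.line() for r in self.roads if r.road_class >= min_class]
        return MultiLineString(lines)

    def distance_to(self, x, y, min_class: int = LOCAL_ROAD) -> np.ndarray:
        """Euclidean distance from points to the nearest road of class >= min_class."""
        pts = shapely.points(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
        return shapely.distance(pts, self.multiline(min_class))


@dataclass
class FacilitySet:
    """EmOC facility point locations with service tier."""

    points: np.ndarray  # (N, 2) world metres
    tiers: list[str]  # "basic" | "comprehensive"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if len(self.points) != len(self.tiers):
            raise ValueError("points and tiers length mismatch")
        if len(self.points) == 0:
            raise ValueError("a facility set needs at least one facility")
        bad = set(self.tiers) - {"basic", "comprehensive"}
        if bad:
            raise ValueError(f"unknown facility tier(s): {bad}")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class TruthRecord:
    """Generating parameters stored beside every synthetic dataset."""

    beta0: float
    beta_remoteness: float
    beta_season: float
    zone_remoteness: dict[int, float]
    seed: int
    extra: dict = field(default_factory=dict)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def gen_dem(size: int, roughness: float = 0.5, seed: int = 0,
            cell: float = 50.0, relief: float = 600.0) -> Grid:
    """Synthetic terrain: Gaussian-smoothed white noise plus a gentle tilt.

    ``roughness`` in (0, 1] controls the smoothing kernel width (wider kernel
    for rougher... no: *smaller* roughness smooths more, giving gentler
    terrain).  Elevation spans [0, relief] metres.
    """
    if size < 8:
        raise ValueError(f"DEM size must be >= 8 cells, got {size}")
    if not 0 < roughness <= 1:
        raise ValueError(f"roughness must be in (0, 1], got {roughness}")
    rng = _rng(seed)
    noise = rng.standard_normal((size, size))
    sigma = max(0.5, (1.0 - roughness) * size / 8.0 + 1.0)
    z = gaussian_filter(noise, sigma=sigma, mode="nearest")
    # mild regional tilt so the landscape has a drainage direction
    rows = np.arange(size)[:, None] / (size - 1)
    z = z - z.min()
    if z.max() > 0:
        z = z / z.max()
    z = 0.85 * z + 0.15 * rows
    z = (z - z.min()) / (z.max() - z.min()) * relief
    transform = GridTransform(x0=0.0, y0=size * cell, cell=cell)
    return Grid(z, transform)


def gen_landcover(dem: Grid, seed: int = 0) -> Grid:
    """Four-class cover from elevation and a smoothed moisture field.

    Rocky caps the highest ground; forest and scrub follow a moisture
    gradient on the rest; grass elsewhere.  Quantile thresholds guarantee all
    four classes appear on any non-degenerate grid of at least 32x32.
    """
    if not np.all(np.isfinite(dem.data)):
        raise ValueError("DEM contains non-finite elevations")
    rng = _rng(seed)
    z = dem.data
    moisture = gaussian_filter(rng.standard_normal(z.shape), sigma=max(1.0, z.shape[0] / 16))
    cover = np.full(z.shape, GRASS, dtype=np.int16)
    m_hi, m_lo = np.quantile(moisture, [0.60, 0.30])
    cover[moisture > m_hi] = FOREST
    cover[(moisture <= m_hi) & (moisture > m_lo)] = SCRUB
    rocky_cut = np.quantile(z, 0.85)
    cover[z > rocky_cut] = ROCKY
    return dem.like(cover)


def gen_roads(dem: Grid, n_towns: int = 6, seed: int = 0) -> RoadNetwork:
    """Connected three-tier road network joining randomly placed towns.

    The national spine threads the towns in order of their projection onto
    the towns' first principal axis (guaranteeing a connected spine without
    route optimisation); interior towns sprout provincial branches and each
    branch a local feeder.
    """
    if n_towns < 2:
        raise ValueError(f"need at least 2 towns, got {n_towns}")
    rng = _rng(seed)
    xmin, ymin, xmax, ymax = dem.transform.extent(dem.shape)
    span = min(xmax - xmin, ymax - ymin)
    margin = 0.08 * span
    towns = np.column_stack([
        rng.uniform(xmin + margin, xmax - margin, n_towns),
        rng.uniform(ymin + margin, ymax - margin, n_towns),
    ])
    centred = towns - towns.mean(axis=0)
    # principal axis via SVD; order towns along it
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    order = np.argsort(centred @ vt[0])
    spine = towns[order]

    def _clip(p: np.ndarray) -> np.ndarray:
        return np.clip(p, [xmin + 1.0, ymin + 1.0], [xmax - 1.0, ymax - 1.0])

    roads = [Road(NATIONAL_ROAD, spine)]
    for town in spine[1:-1]:
        theta = rng.uniform(0, 2 * np.pi)
        tip = _clip(town + 0.22 * span * np.array([np.cos(theta), np.sin(theta)]))
        roads.append(Road(PROVINCIAL_ROAD, np.vstack([town, tip])))
        phi = rng.uniform(0, 2 * np.pi)
        feeder = _clip(tip + 0.10 * span * np.array([np.cos(phi), np.sin(phi)]))
        roads.append(Road(LOCAL_ROAD, np.vstack([tip, feeder])))
    return RoadNetwork(roads)


def gen_zones(grid_shape: tuple[int, int], k: int, seed: int = 0,
              transform: GridTransform | None = None) -> Grid:
    """Nearest-seed (Voronoi-style) partition of the grid into k zones, ids 1..k."""
    nrows, ncols = grid_shape
    ncells = nrows * ncols
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > ncells:
        raise ValueError(f"k={k} exceeds cell count {ncells}")
    rng = _rng(seed)
    seeds = rng.choice(ncells, size=k, replace=False)
    sr, sc = np.divmod(seeds, ncols)
    rr, cc = np.indices(grid_shape)
    d2 = (rr[..., None] - sr) ** 2 + (cc[..., None] - sc) ** 2
    zone = np.argmin(d2, axis=-1).astype(np.int32) + 1
    if transform is None:
        transform = GridTransform(0.0, nrows * 50.0, 50.0)
    return Grid(zone, transform)


def gen_facilities(roads: RoadNetwork, n_basic: int = 4, n_comprehensive: int = 1,
                   seed: int = 0) -> FacilitySet:
    """Place facilities on the provincial/national road network.

    The comprehensive facilities (hospitals) sit on the national spine;
    basic EmOC clinics on any provincial or national road.
    """
    if n_basic < 0 or n_comprehensive < 0 or n_basic + n_comprehensive < 1:
        raise ValueError("need at least one facility in total")
    rng = _rng(seed)

    def _sample_on(min_class: int, n: int) -> np.ndarray:
        line = roads.multiline(min_class)
        fracs = rng.uniform(0.02, 0.98, n)
        pts = [line.interpolate(f, normalized=True) for f in fracs]
        return np.array([[p.x, p.y] for p in pts])

    pts, tiers = [], []
    if n_comprehensive:
        pts.append(_sample_on(NATIONAL_ROAD, n_comprehensive))
        tiers += ["comprehensive"] * n_comprehensive
    if n_basic:
        pts.append(_sample_on(PROVINCIAL_ROAD, n_basic))
        tiers += ["basic"] * n_basic
    return FacilitySet(np.vstack(pts), tiers)


def gen_dwellings(roads: RoadNetwork, zones: Grid, n_points: int = 1598,
                  decay: float = 300.0, seed: int = 0, background: float = 0.1,
                  max_retries: int = 20) -> tuple[np.ndarray, Grid]:
    """Dwelling points clustered near roads, plus the infrastructure-cell grid.

    Most dwellings are exponential-decay offsets (scale ``decay`` metres)
    from random positions along the road network, so point density falls
    with distance to roads; a ``background`` fraction is uniform over the
    extent, standing in for the isolated dwellings found well away from any
    road.  The infrastructure grid marks cells containing at least one
    dwelling; generation is retried (bounded) until every zone holds at
    least one infrastructure cell.

    Returns ``(points (n, 2), infrastructure Grid of bool)``.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if decay <= 0:
        raise ValueError("decay must be positive metres")
    if not 0 <= background < 1:
        raise ValueError("background fraction must be in [0, 1)")
    line = roads.multiline()
    xmin, ymin, xmax, ymax = zones.transform.extent(zones.shape)
    k = int(zones.data.max())

    for attempt in range(max_retries):
        rng = _rng(seed + 100_003 * attempt)
        n_bg = int(round(background * n_points))
        bg = np.column_stack([rng.uniform(xmin, xmax, n_bg),
                              rng.uniform(ymin + 1e-9, ymax, n_bg)])
        pts = bg
        while len(pts) < n_points:
            m = 2 * (n_points - len(pts))
            fracs = rng.uniform(0, 1, m)
            base = shapely.line_interpolate_point(line, fracs, normalized=True)
            bx, by = shapely.get_x(base), shapely.get_y(base)
            theta = rng.uniform(0, 2 * np.pi, m)
            dist = rng.exponential(decay, m)
            cand = np.column_stack([bx + dist * np.cos(theta), by + dist * np.sin(theta)])
            ok = (cand[:, 0] >= xmin) & (cand[:, 0] < xmax) & (cand[:, 1] > ymin) & (cand[:, 1] <= ymax)
            pts = np.vstack([pts, cand[ok]])
        pts = pts[:n_points]
        rr, cc = zones.transform.world_to_cell(pts[:, 0], pts[:, 1])
        infra = np.zeros(zones.shape, dtype=bool)
        infra[rr, cc] = True
        present = np.unique(zones.data[infra])
        if len(present) == k:
            return pts, zones.like(infra)
    raise RuntimeError(
        f"could not cover all {k} zones with infrastructure cells in {max_retries} attempts; "
        "increase n_points or decrease zone count"
    )


def gen_census(zones: Grid, mean_pop: float = 10_000.0, seed: int = 0,
               female_fraction: float = DEFAULT_FEMALE_FRACTION,
               fertile_fraction: float = DEFAULT_FERTILE_FRACTION) -> pd.DataFrame:
    """Zone-level census: lognormal population totals and the two fractions."""
    rng = _rng(seed)
    k = int(zones.data.max())
    pops = np.round(rng.lognormal(np.log(mean_pop), 0.5, k)).astype(int)
    return pd.DataFrame({
        "zone": np.arange(1, k + 1),
        "population": pops,
        "female_fraction": female_fraction,
        "fertile_fraction": fertile_fraction,
    })


def gen_mortality(zone_remoteness, season_flag: int, births_per_zone,
                  coefficients: tuple[float, float, float], years: int = 5,
                  seed: int = 0) -> tuple[pd.DataFrame, TruthRecord]:
    """Maternal deaths per zone-year from a Poisson log-link model.

    deaths_zy ~ Poisson(births_zy * exp(b0 + b_r * r_z + b_s * s) / 100000),
    i.e. the expected maternal mortality ratio (deaths per 100,000 live
    births) is log-linear in the zone's remoteness index r_z and the season
    flag s (dry = 1, wet = 0).  Draws are capped at the birth count so the
    deaths <= births invariant always holds.
    """
    r = np.asarray(zone_remoteness, dtype=float)
    births = np.asarray(births_per_zone)
    if np.any(births < 0):
        raise ValueError("births must be non-negative")
    if years < 1:
        raise ValueError("years must be >= 1")
    if season_flag not in (0, 1):
        raise ValueError("season_flag must be 0 (wet) or 1 (dry)")
    b0, b_r, b_s = coefficients
    rng = _rng(seed)
    mmr = np.exp(b0 + b_r * r + b_s * season_flag)  # per 100,000 births
    rows = []
    for year in range(years):
        lam = births * mmr / 100_000.0
        deaths = np.minimum(rng.poisson(lam), births)
        for z in range(len(r)):
            rows.append((z + 1, year, season_flag, int(deaths[z]), int(births[z])))
    table = pd.DataFrame(rows, columns=["zone", "year", "season", "deaths", "births"])
    truth = TruthRecord(
        beta0=b0, beta_remoteness=b_r, beta_season=b_s,
        zone_remoteness={z + 1: float(r[z]) for z in range(len(r))},
        seed=seed,
    )
    return table, truth
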