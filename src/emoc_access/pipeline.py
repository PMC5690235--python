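"""End-to-end orchestration: one config in, all stage outputs out.

A run walks the full chain — generate or load inputs, derive streams from
the DEM, assemble a pace surface per scenario, solve travel time, spread the
census onto the grid, compute per-zone remoteness, and fit the mortality
GLM — writing every intermediate layer plus a manifest with checksums and
per-stage runtimes.  Runs are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .cost_surface import ScenarioConfig, SpeedTable, apply_barriers, build_pace, burn_roads
from .grids import Grid
from .hydrology import accumulate_flow, d8_flow, fill_pits, strahler_order
from .population import disaggregate_infrastructure, disaggregate_points, join_population_traveltime
from .stats import build_glm_dataset, fit_poisson_glm, remoteness_index, scenario_report
from .synthetic import (gen_census, gen_dem, gen_dwellings, gen_facilities, gen_landcover,
                        gen_mortality, gen_roads, gen_zones)
from .travel_time import classify_zones, cost_distance, snap_facilities

__all__ = ["SimulateConfig", "RunConfig", "run_pipeline"]

STAGES = ["inputs", "hydrology", "cost_surface", "travel_time",
          "population", "remoteness", "glm"]


@dataclass
class SimulateConfig:
    """Parameters of the synthetic study region."""

    #: 64 cells of 250 m span ~16 km — a scaled-down district in which the
    #: two-hour threshold genuinely bisects the walking population
    size: int = 64
    cell: float = 250.0
    zones: int = 32   # the modelled district's sub-district count
    towns: int = 5
    dwellings: int = 1598
    dwelling_decay: float = 300.0
    n_basic: int = 4
    n_comprehensive: int = 1
    roughness: float = 0.5
    mean_pop: float = 10_000.0
    birth_rate: float = 0.025    # live births per person per year
    beta0: float = 5.5           # log baseline MMR per 100,000
    beta_remoteness: float = 0.6
    beta_season: float = -0.2    # dry = 1: negative means wet season is worse
    years: int = 5


@dataclass
class RunConfig:
    out: Path
    seed: int = 0
    simulate: SimulateConfig | None = field(default_factory=SimulateConfig)
    inputs: dict | None = None   # paths: dem, landcover, roads, zones, facilities,
                                 # census, mortality, optional dwellings
    scenarios: list[dict] = field(default_factory=lambda: [
        {"mode": "car", "season": "dry"}, {"mode": "car", "season": "wet"},
        {"mode": "bus", "season": "dry"}, {"mode": "bus", "season": "wet"}])
    remoteness_threshold: float = 120.0
    stream_threshold: int = 30
    barrier_order_min: int = 7
    barrier_overrides_roads: bool = True
    population_method: str = "infrastructure"  # or "points"
    glm_mode: str = "car"        # scenario mode whose remoteness feeds the GLM
    response_mode: str = "mmr"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = pio.read_yaml(path)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        cfg = cls(out=Path(raw.pop("out")), **{k: v for k, v in raw.items() if k != "inputs"},
                  inputs=raw.get("inputs"))
        cfg.simulate = SimulateConfig(**sim) if isinstance(sim, dict) else (
            SimulateConfig() if cfg.inputs is None else None)
        if cfg.inputs is not None:
            missing = [p for p in cfg.inputs.values() if not Path(p).exists()]
            if missing:
                raise FileNotFoundError(f"input file(s) not found: {missing}")
        if not cfg.scenarios:
            raise ValueError("at least one scenario is required")
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage for every scenario; returns the manifest dict."""
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    stage = "inputs"
    try:
        t0 = time.perf_counter()
        layers = _stage_inputs(config, out)
        manifest["stages"]["inputs"] = round(time.perf_counter() - t0, 4)

        t0 = time.perf_counter()
        streams = _stage_hydrology(config, layers, out)
        manifest["stages"]["hydrology"] = round(time.perf_counter() - t0, 4)

        stage = "cost_surface"
        t0 = time.perf_counter()
        speeds = SpeedTable.default()
        class_grid = burn_roads(layers["landcover"], layers["roads"])
        scen_cfgs = [ScenarioConfig(mode=s["mode"], season=s["season"],
                                    remoteness_threshold=config.remoteness_threshold,
                                    barrier_order_min=config.barrier_order_min,
                                    barrier_overrides_roads=config.barrier_overrides_roads,
                                    cell_size=layers["landcover"].cell)
                     for s in config.scenarios]
        paces = {}
        for sc in scen_cfgs:
            _, barrier = apply_barriers(class_grid, streams, sc)
            pace = build_pace(class_grid, barrier, speeds, sc)
            paces[sc.name] = pace
            pio.write_raster(pace, out / f"pace_{sc.name}.asc", nodata=-1.0)
        pio.write_table(speeds.to_frame(), out / "speed_table.csv")
        manifest["stages"]["cost_surface"] = round(time.perf_counter() - t0, 4)

        stage = "travel_time"
        t0 = time.perf_counter()
        tts = {}
        for sc in scen_cfgs:
            srcs = snap_facilities(layers["facilities"], paces[sc.name])
            tt = cost_distance(paces[sc.name], srcs)
            tts[sc.name] = tt
            pio.write_raster(tt, out / f"traveltime_{sc.name}.asc", nodata=-1.0)
            pio.write_raster(classify_zones(tt), out / f"ttzones_{sc.name}.asc")
        manifest["stages"]["travel_time"] = round(time.perf_counter() - t0, 4)

        stage = "population"
        t0 = time.perf_counter()
        if config.population_method == "points":
            pop = disaggregate_points(layers["census"], layers["dwellings"], layers["zones"])
        else:
            pop = disaggregate_infrastructure(layers["census"], layers["infrastructure"],
                                              layers["zones"])
        pio.write_raster(pop, out / "population.asc")
        pats = {}
        for sc in scen_cfgs:
            pat = join_population_traveltime(pop, tts[sc.name], layers["zones"])
            pats[sc.name] = pat
            pio.write_table(pat, out / f"population_at_time_{sc.name}.csv")
        manifest["stages"]["population"] = round(time.perf_counter() - t0, 4)

        stage = "remoteness"
        t0 = time.perf_counter()
        zone_ids = sorted(layers["census"]["zone"])
        remote_frames = []
        for sc in scen_cfgs:
            rt = remoteness_index(pats[sc.name], threshold=sc.remoteness_threshold,
                                  zones=zone_ids)
            rt.insert(0, "scenario", sc.name)
            remote_frames.append(rt)
        remoteness = pd.concat(remote_frames, ignore_index=True)
        pio.write_table(remoteness, out / "remoteness.csv")
        report = scenario_report(pats)
        pio.write_table(report.reset_index(names="scenario"), out / "scenario_report.csv")
        manifest["stages"]["remoteness"] = round(time.perf_counter() - t0, 4)

        stage = "glm"
        t0 = time.perf_counter()
        glm_out = _stage_glm(config, layers, remoteness, out)
        manifest["stages"]["glm"] = round(time.perf_counter() - t0, 4)
        manifest.update(glm_out)
    except Exception as err:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for f in sorted(out.iterdir()):
            if f.is_file():
                shutil.move(str(f), failed / f.name)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest["outputs"] = {f.name: _sha256(f) for f in sorted(out.iterdir()) if f.is_file()}
    pio.write_yaml(manifest, out / "manifest.yaml")
    return manifest


def _stage_inputs(config: RunConfig, out: Path) -> dict:
    if config.inputs is not None:
        inp = config.inputs
        layers = {
            "dem": pio.read_raster(inp["dem"]),
            "landcover": pio.read_raster(inp["landcover"], dtype=np.int16),
            "roads": pio.read_roads(inp["roads"]),
            "zones": pio.read_raster(inp["zones"], dtype=np.int32),
            "facilities": pio.read_facilities(inp["facilities"]),
            "census": pio.read_table(inp["census"]),
            "mortality": pio.read_table(inp["mortality"]),
        }
        if "dwellings" in inp:
            layers["dwellings"] = pio.read_points(inp["dwellings"])
        if "infrastructure" in inp:
            layers["infrastructure"] = pio.read_raster(inp["infrastructure"], dtype=bool,
                                                       nodata_to=None)
        return layers

    sim = config.simulate
    seed = config.seed
    dem = gen_dem(sim.size, roughness=sim.roughness, seed=seed, cell=sim.cell)
    landcover = gen_landcover(dem, seed=seed + 1)
    roads = gen_roads(dem, n_towns=sim.towns, seed=seed + 2)
    zones = gen_zones(dem.shape, sim.zones, seed=seed + 3, transform=dem.transform)
    facilities = gen_facilities(roads, sim.n_basic, sim.n_comprehensive, seed=seed + 4)
    dwellings, infra = gen_dwellings(roads, zones, n_points=sim.dwellings,
                                     decay=sim.dwelling_decay, seed=seed + 5)
    census = gen_census(zones, mean_pop=sim.mean_pop, seed=seed + 6)
    pio.write_raster(dem, out / "dem.asc")
    pio.write_raster(landcover, out / "landcover.asc")
    pio.write_raster(zones, out / "zones.asc")
    pio.write_raster(infra.like(infra.data.astype(np.int16)), out / "infrastructure.asc")
    pio.write_roads(roads, out / "roads.geojson")
    pio.write_facilities(facilities, out / "facilities.geojson")
    pio.write_points(dwellings, out / "dwellings.geojson")
    pio.write_table(census, out / "census.csv")
    return {"dem": dem, "landcover": landcover, "roads": roads, "zones": zones,
            "facilities": facilities, "dwellings": dwellings, "infrastructure": infra,
            "census": census, "mortality": None}


def _stage_hydrology(config: RunConfig, layers: dict, out: Path) -> Grid:
    filled = fill_pits(layers["dem"])
    flowdir = d8_flow(filled)
    acc = accumulate_flow(flowdir)
    streams = strahler_order(flowdir, acc, stream_threshold=config.stream_threshold)
    pio.write_raster(streams, out / "streams.asc")
    return streams


def _stage_glm(config: RunConfig, layers: dict, remoteness: pd.DataFrame, out: Path) -> dict:
    # remoteness per zone per season, from the configured transport mode
    season_flag = {"dry": 1, "wet": 0}
    frames = []
    for season in ("wet", "dry"):
        name = f"{config.glm_mode}_{season}"
        sub = remoteness.loc[remoteness["scenario"] == name,
                             ["zone", "remoteness", "defined"]].copy()
        if sub.empty:
            return {"glm": None}  # GLM needs both seasons of the chosen mode
        sub["season"] = season_flag[season]
        frames.append(sub)
    rt = pd.concat(frames, ignore_index=True)

    mortality = layers.get("mortality")
    truth = None
    if mortality is None:
        # synthetic mortality generated from the *computed* remoteness
        sim = config.simulate
        census = layers["census"].set_index("zone")
        zone_ids = sorted(census.index)
        births = np.maximum(
            1, np.round(census.loc[zone_ids, "population"].to_numpy() * sim.birth_rate)
        ).astype(int)
        parts = []
        for s in (0, 1):
            r = (rt.loc[rt["season"] == s].set_index("zone")
                 .loc[zone_ids, "remoteness"].fillna(0.0).to_numpy())
            tab, truth = gen_mortality(r, s, births,
                                       (sim.beta0, sim.beta_remoteness, sim.beta_season),
                                       years=sim.years, seed=config.seed + 7 + s)
            parts.append(tab)
        mortality = pd.concat(parts, ignore_index=True)
        pio.write_table(mortality, out / "mortality.csv")
        pio.write_yaml({
            "beta0": truth.beta0, "beta_remoteness": truth.beta_remoteness,
            "beta_season": truth.beta_season, "seed": truth.seed,
            "zone_remoteness": {int(k): float(v) for k, v in truth.zone_remoteness.items()},
        }, out / "truth.yaml")

    data = build_glm_dataset(rt, mortality)
    pio.write_table(data, out / "glm_data.csv")
    try:
        fit = fit_poisson_glm(data, response_mode=config.response_mode)
    except ValueError as err:
        # e.g. constant remoteness on a landscape where nowhere is remote
        return {"glm": {"error": str(err)}}
    pio.write_yaml(fit.to_dict(), out / "glm_fit.yaml")
    return {"glm": fit.to_dict()}
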