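"""Reading and writing the pipeline's standard formats.

Rasters travel as ESRI ASCII grid (.asc) — the plain-text single-band grid
format every desktop GIS reads — with full float64 precision so write/read
round-trips are bitwise exact.  Vectors (roads, facilities, dwellings) are
GeoJSON feature collections; tables are CSV; configuration, fit results and
manifests are YAML.  All layers must share one planar metric frame: readers
return the transform and joins reject any mismatch.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grids import Grid, GridTransform
from .synthetic import FacilitySet, Road, RoadNetwork

__all__ = [
    "write_raster", "read_raster",
    "write_roads", "read_roads", "write_facilities", "read_facilities",
    "write_points", "read_points",
    "write_table", "read_table", "write_yaml", "read_yaml",
]

_FMT = "%.17g"  # round-trips float64 exactly


def write_raster(grid: Grid, path, nodata: float = -9999.0) -> None:
    """Write a single-band ESRI ASCII grid; non-finite cells become ``nodata``."""
    path = Path(path)
    data = np.asarray(grid.data, dtype=float)
    out = np.where(np.isfinite(data), data, nodata)
    nrows, ncols = grid.shape
    t = grid.transform
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {t.x0!r}\n"
        f"yllcorner {(t.y0 - nrows * t.cell)!r}\n"
        f"cellsize {t.cell!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt=_FMT)


def read_raster(path, dtype=float, nodata_to: float | None = np.inf) -> Grid:
    """Read an ESRI ASCII grid; nodata cells become ``nodata_to`` (default +inf)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(nrows, ncols)
    nodata = header.get("nodata_value")
    if nodata is not None and nodata_to is not None:
        data = np.where(data == nodata, nodata_to, data)
    cell = header["cellsize"]
    transform = GridTransform(header["xllcorner"], header["yllcorner"] + nrows * cell, cell)
    return Grid(data.astype(dtype), transform)


def _feature_collection(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def _dump_geojson(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)
        fh.write("\n")


def _load_features(path) -> list[dict]:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    return gj["features"]


def _require_property(feat: dict, idx: int, key: str):
    props = feat.get("properties") or {}
    if key not in props:
        raise ValueError(f"feature {idx}: missing required property {key!r}")
    return props[key]


def write_roads(roads: RoadNetwork, path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": {"type": "LineString",
                         "coordinates": [[float(x), float(y)] for x, y in r.coords]},
            "properties": {"class": int(r.road_class)},
        }
        for r in roads.roads
    ]
    _dump_geojson(_feature_collection(feats), path)


def read_roads(path) -> RoadNetwork:
    roads = []
    for i, feat in enumerate(_load_features(path)):
        cls = int(_require_property(feat, i, "class"))
        coords = np.asarray(feat["geometry"]["coordinates"], dtype=float)
        roads.append(Road(cls, coords))
    return RoadNetwork(roads)


def write_facilities(facilities: FacilitySet, path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
            "properties": {"tier": tier},
        }
        for (x, y), tier in zip(facilities.points, facilities.tiers)
    ]
    _dump_geojson(_feature_collection(feats), path)


def read_facilities(path) -> FacilitySet:
    pts, tiers = [], []
    for i, feat in enumerate(_load_features(path)):
        tiers.append(str(_require_property(feat, i, "tier")))
        pts.append(feat["geometry"]["coordinates"])
    return FacilitySet(np.asarray(pts, dtype=float), tiers)


def write_points(points: np.ndarray, path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
            "properties": {},
        }
        for x, y in np.atleast_2d(points)
    ]
    _dump_geojson(_feature_collection(feats), path)


def read_points(path) -> np.ndarray:
    return np.asarray(
        [f["geometry"]["coordinates"] for f in _load_features(path)], dtype=float)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
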