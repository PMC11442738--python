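"""On-disk formats: TIFF raster stacks, GeoJSON field boundaries, CSV tables.

Rasters are written one single-band TIFF per variable per day, named
``<variable>_<YYYY-MM-DD>.tif``, with nodata encoded as -9999 and the grid
geometry (rows, cols, pixel size) in a ``grid.json`` sidecar. Field
boundaries travel as GeoJSON FeatureCollections with ``field_id`` and
``crop`` properties; per-field daily statistics and flux tables are plain
CSV.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import Polygon, shape
from shapely.geometry import mapping as shapely_mapping

from .grid import NODATA, RasterGrid
from .ingest import FieldBoundary

__all__ = [
    "write_scene",
    "write_raster",
    "read_raster_dir",
    "write_field_geojson",
    "read_field_geojson",
]


def write_raster(path, array: np.ndarray) -> None:
    """Write a single-band float32 TIFF with NaN encoded as -9999."""
    data = np.asarray(array, dtype=np.float32).copy()
    data[~np.isfinite(data)] = NODATA
    tifffile.imwrite(path, data)


def _read_raster(path) -> np.ndarray:
    data = tifffile.imread(path).astype(np.float64)
    data[data == NODATA] = np.nan
    return data


def write_field_geojson(path, boundaries) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"field_id": b.field_id, "crop": b.crop},
            "geometry": shapely_mapping(b.polygon),
        }
        for b in boundaries
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_field_geojson(path) -> list[FieldBoundary]:
    doc = json.loads(Path(path).read_text())
    out = []
    for feat in doc["features"]:
        geom = shape(feat["geometry"])
        if not isinstance(geom, Polygon):
            raise ValueError(f"unsupported geometry type {geom.geom_type} in {path}")
        props = feat["properties"]
        out.append(FieldBoundary(props["field_id"], props["crop"], geom))
    return out


def write_scene(scene, out_dir) -> Path:
    """Persist a synthetic scene: rasters, fields, temperature, truth record."""
    out = Path(out_dir)
    raster_dir = out / "rasters"
    raster_dir.mkdir(parents=True, exist_ok=True)
    for date, layers in scene.daily_layers.items():
        for var, arr in layers.items():
            write_raster(raster_dir / f"{var}_{date.isoformat()}.tif", arr)
    (out / "grid.json").write_text(
        json.dumps(
            {"rows": scene.grid.rows, "cols": scene.grid.cols, "pixel_size_m": scene.grid.pixel_size_m}
        )
    )
    write_field_geojson(
        out / "fields.geojson",
        [FieldBoundary(r.field_id, r.crop, r.polygon) for r in scene.field_table.itertuples()],
    )
    temp = scene.temperature.rename("tair_c").rename_axis("date")
    temp.to_csv(out / "temperature.csv")

    profiles = [
        {k: (v.isoformat() if isinstance(v, dt.date) else v) for k, v in vars(p).items()}
        for p in scene.truth.get("profiles", [])
    ]
    (out / "truth.yaml").write_text(
        yaml.safe_dump({"seed": scene.truth.get("seed"), "profiles": profiles})
    )
    return out


def read_raster_dir(raster_dir, grid_path=None):
    """Read a raster directory back into (daily_layers, grid)."""
    raster_dir = Path(raster_dir)
    if grid_path is None:
        grid_path = raster_dir.parent / "grid.json"
    meta = json.loads(Path(grid_path).read_text())
    grid = RasterGrid(meta["rows"], meta["cols"], meta["pixel_size_m"])
    layers: dict[dt.date, dict[str, np.ndarray]] = {}
    for path in sorted(raster_dir.glob("*.tif")):
        var, datestr = path.stem.rsplit("_", 1)
        date = dt.date.fromisoformat(datestr)
        layers.setdefault(date, {})[var] = _read_raster(path)
    return layers, grid


def read_temperature_csv(path) -> pd.Series:
    df = pd.read_csv(path, parse_dates=["date"])
    return df.set_index("date")["tair_c"]
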