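"""Format adapters: CSV observation tables, GeoJSON plumes, NetCDF grids.

Round-trip fidelity is the contract: write-then-read reproduces values to
full float precision, GeoJSON polygons preserve ring order and properties,
and NetCDF grids keep the (day, y, x) dimension order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import Polygon, mapping, shape

from .world import PlumePolygon

__all__ = [
    "write_observations",
    "read_observations",
    "write_plumes_geojson",
    "read_plumes_geojson",
    "write_fields_netcdf",
    "read_fields_netcdf",
    "write_json",
    "read_json",
]


def write_observations(df: pd.DataFrame, path: str | Path) -> None:
    """Write an observation table to CSV.

    Floats are written with pandas' shortest round-trip representation, so
    read-back reproduces values bit for bit.
    """
    df.to_csv(path, index=False)


def read_observations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_plumes_geojson(plumes: Sequence[PlumePolygon], path: str | Path) -> None:
    """One GeoJSON feature per plume polygon, properties preserved."""
    features = []
    for p in plumes:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(p.polygon),
                "properties": {
                    "date": int(p.date),
                    "start_hour": int(p.start_hour),
                    "end_hour": int(p.end_hour),
                    "density_class": int(p.density_class),
                },
            }
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_plumes_geojson(path: str | Path) -> list[PlumePolygon]:
    """Parse plume polygons; malformed features are reported by index."""
    doc = json.loads(Path(path).read_text())
    plumes = []
    for i, feat in enumerate(doc.get("features", [])):
        try:
            geom = feat["geometry"]
            if geom["type"] != "Polygon":
                raise ValueError(f"geometry type {geom['type']!r}, expected Polygon")
            ring = geom["coordinates"][0]
            if len(ring) < 4 or ring[0] != ring[-1]:
                raise ValueError("polygon ring is not closed")
            props = feat["properties"]
            plumes.append(
                PlumePolygon(
                    date=int(props["date"]),
                    polygon=shape(geom),
                    start_hour=int(props["start_hour"]),
                    end_hour=int(props["end_hour"]),
                    density_class=int(props["density_class"]),
                )
            )
        except (KeyError, ValueError, TypeError) as e:
            raise ValueError(f"malformed plume feature at index {i}: {e}") from e
    return plumes


def write_fields_netcdf(fields: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write gridded fields to NetCDF with canonical dimension orders.

    3-D daily fields get dims (day, y, x); per-year layers (named
    ``population``) get (year, y, x); 2-D statics get (y, x); 2-D arrays
    whose name starts with ``coarse`` get (day, node) / (node, axis).
    """
    data = {}
    for name, arr in fields.items():
        arr = np.asarray(arr)
        if name == "population":
            data[name] = (("year", "y", "x"), arr)
        elif name == "coarse_aod":
            data[name] = (("day", "node"), arr)
        elif name == "coarse_aod_xy":
            data[name] = (("node", "axis"), arr)
        elif arr.ndim == 3:
            data[name] = (("day", "y", "x"), arr)
        elif arr.ndim == 2:
            data[name] = (("y", "x"), arr)
        else:
            raise ValueError(f"field {name!r} has unsupported ndim {arr.ndim}")
    xr.Dataset(data).to_netcdf(path)


def read_fields_netcdf(path: str | Path) -> dict[str, np.ndarray]:
    with xr.open_dataset(path) as ds:
        return {name: ds[name].to_numpy() for name in ds.data_vars}


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
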