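"""Minimal vector-layer I/O: pandas DataFrames with shapely geometry columns.

A "geotable" here is an ordinary :class:`pandas.DataFrame` holding one column
of shapely geometries (named ``geometry`` by convention).  Layers round-trip
through GeoJSON FeatureCollections; attribute-only tables go through CSV.
Coordinates are planar metres throughout — the synthetic study region lives in
a projected CRS, so no datum handling is needed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

GEOMETRY_COLUMN = "geometry"


def write_geojson(frame: pd.DataFrame, path: str | Path,
                  geometry_column: str = GEOMETRY_COLUMN) -> None:
    """Write a geotable as a GeoJSON FeatureCollection (one feature per row)."""
    features = []
    for _, row in frame.iterrows():
        props = {}
        for key, value in row.items():
            if key == geometry_column:
                continue
            if isinstance(value, (np.integer,)):
                value = int(value)
            elif isinstance(value, (np.floating,)):
                value = float(value)
            elif isinstance(value, (np.bool_,)):
                value = bool(value)
            props[key] = None if (isinstance(value, float) and np.isnan(value)) else value
        features.append({
            "type": "Feature",
            "geometry": mapping(row[geometry_column]),
            "properties": props,
        })
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def read_geojson(path: str | Path,
                 geometry_column: str = GEOMETRY_COLUMN) -> pd.DataFrame:
    """Read a GeoJSON FeatureCollection into a geotable."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    rows = []
    for feature in payload["features"]:
        row = dict(feature.get("properties") or {})
        row[geometry_column] = shape(feature["geometry"])
        rows.append(row)
    return pd.DataFrame(rows)


def geometry_array(frame: pd.DataFrame,
                   geometry_column: str = GEOMETRY_COLUMN) -> np.ndarray:
    """Geometry column as an object ndarray suitable for shapely-2 vectorized ops."""
    return np.asarray(frame[geometry_column].to_numpy(), dtype=object)


def make_valid_geometries(geoms: np.ndarray) -> np.ndarray:
    """Repair invalid polygons (self-intersections) via shapely make_valid."""
    invalid = ~shapely.is_valid(geoms)
    if invalid.any():
        geoms = geoms.copy()
        geoms[invalid] = shapely.make_valid(geoms[invalid])
    return geoms
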