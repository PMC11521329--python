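"""Text-format round-trips for every domain object.

Regions travel as a GeoJSON FeatureCollection of Polygons (properties:
region_id, name, population, dma_id; holes are rejected explicitly), posts
as JSON Lines, surveillance series as long-format CSV (region_id, date,
stream, value; missing encoded as an empty field), and reports as CSV/JSON.
All writers are deterministic (sorted keys, fixed float formatting) so a
rerun with the same seed reproduces files byte for byte.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping, shape

from .base import (
    PostRecord,
    SchemaError,
    SurveillanceSeries,
    frame_to_series,
    series_to_frame,
    validate_regions,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_regions_geojson",
    "write_regions_geojson",
    "read_posts_jsonl",
    "write_posts_jsonl",
    "read_series_csv",
    "write_series_csv",
]


# --------------------------------------------------------------------------
# regions ↔ GeoJSON

def write_regions_geojson(regions: pd.DataFrame, path: str | Path) -> None:
    validate_regions(regions)
    features = []
    for _, row in regions.iterrows():
        geom = mapping(row["geometry"])
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": geom["type"],
                    "coordinates": [
                        [[float(x), float(y)] for x, y in ring]
                        for ring in geom["coordinates"]
                    ],
                },
                "properties": {
                    "region_id": str(row["region_id"]),
                    "name": str(row["name"]),
                    "population": int(row["population"]),
                    "dma_id": str(row["dma_id"]),
                },
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_regions_geojson(path: str | Path) -> pd.DataFrame:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise SchemaError("type: expected a GeoJSON FeatureCollection")
    rows = []
    for i, feat in enumerate(doc.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise SchemaError(f"features[{i}].geometry.type: only Polygon is supported")
        if len(geom.get("coordinates", [])) != 1:
            raise SchemaError(
                f"features[{i}].geometry: polygons with holes are not supported"
            )
        props = feat.get("properties") or {}
        for key in ("region_id", "name", "population", "dma_id"):
            if key not in props:
                raise SchemaError(f"features[{i}].properties.{key}: missing")
        rows.append(
            {
                "region_id": str(props["region_id"]),
                "name": str(props["name"]),
                "population": int(props["population"]),
                "dma_id": str(props["dma_id"]),
                "geometry": shape(geom),
            }
        )
    return validate_regions(pd.DataFrame(rows))


# --------------------------------------------------------------------------
# posts ↔ JSON Lines

def write_posts_jsonl(posts: Iterable[PostRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for p in posts:
            rec = {
                "post_id": p.post_id,
                "timestamp": p.timestamp.isoformat(),
                "bbox": [float(v) for v in p.bbox],
                "text": p.text,
            }
            if p.label is not None:
                rec["label"] = p.label
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_posts_jsonl(path: str | Path) -> list[PostRecord]:
    posts = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            for key in ("post_id", "timestamp", "bbox", "text"):
                if key not in rec:
                    raise SchemaError(f"line {lineno}: missing field {key!r}")
            bbox = rec["bbox"]
            if len(bbox) != 4:
                raise SchemaError(f"line {lineno}: bbox must have 4 entries")
            posts.append(
                PostRecord(
                    post_id=str(rec["post_id"]),
                    timestamp=dt.datetime.fromisoformat(rec["timestamp"]),
                    bbox=tuple(float(v) for v in bbox),
                    text=str(rec["text"]),
                    label=rec.get("label"),
                )
            )
    return posts


# --------------------------------------------------------------------------
# series ↔ CSV

def write_series_csv(series: Sequence[SurveillanceSeries], path: str | Path) -> None:
    frame = series_to_frame(series).copy()
    frame["date"] = pd.to_datetime(frame["date"]).dt.strftime("%Y-%m-%d")
    frame = frame.sort_values(["region_id", "stream", "date"], kind="stable")
    with Path(path).open("w") as fh:
        fh.write("region_id,date,stream,value\n")
        for rid, date, stream, value in frame.itertuples(index=False):
            val = "" if pd.isna(value) else np.format_float_positional(value, trim="-")
            fh.write(f"{rid},{date},{stream},{val}\n")


def read_series_csv(path: str | Path, smoothed: bool = False) -> list[SurveillanceSeries]:
    frame = pd.read_csv(path, dtype={"region_id": str, "stream": str})
    for col in ("region_id", "date", "stream", "value"):
        if col not in frame.columns:
            raise SchemaError(f"series CSV: missing column {col!r}")
    frame["date"] = pd.to_datetime(frame["date"])
    out = frame_to_series(frame, smoothed=smoothed)
    n_rows = len(frame)
    n_cells = sum(len(s.values) for s in out)
    if n_cells != n_rows:
        warnings.warn(
            f"series CSV had {n_cells - n_rows} date gap(s); filled with explicit missing",
            stacklevel=2,
        )
    return out
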