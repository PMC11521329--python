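"""Shared domain types for the surveillance pipeline.

The pipeline moves three kinds of objects between stages:

* a region table — toy counties with polygons, populations and media-market
  (DMA) membership, held as a :class:`pandas.DataFrame` with a shapely
  geometry column;
* post records — individual geotagged social posts;
* surveillance series — one daily stream (ED visits, allergy posts, total
  posts, post probability, search probability) for one region.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "AerosurvError",
    "ConfigError",
    "SchemaError",
    "DegenerateInputError",
    "AmbiguousRegionError",
    "COUNT_STREAMS",
    "PROBABILITY_STREAMS",
    "STREAMS",
    "PostRecord",
    "SurveillanceSeries",
    "REGION_COLUMNS",
    "validate_regions",
    "series_to_frame",
    "frame_to_series",
]


class AerosurvError(Exception):
    """Base class for all package errors."""


class ConfigError(AerosurvError, ValueError):
    """Invalid configuration or parameter value."""


class SchemaError(AerosurvError, ValueError):
    """A file or table violates the expected schema; names the field."""


class DegenerateInputError(AerosurvError, ValueError):
    """Input is degenerate for the requested statistic (constant series,
    zero variance, exact collinearity)."""


class AmbiguousRegionError(AerosurvError, ValueError):
    """A point lies strictly inside more than one region polygon."""


#: streams holding non-negative integer counts
COUNT_STREAMS = frozenset({"ed_count", "allergy_posts", "total_posts"})
#: streams holding probabilities in [0, 1] (may be missing)
PROBABILITY_STREAMS = frozenset({"post_probability", "search_probability"})
STREAMS = COUNT_STREAMS | PROBABILITY_STREAMS


@dataclass(frozen=True)
class PostRecord:
    """One geotagged social post.

    ``bbox`` is the Twitter-style place bounding box
    ``(min_lon, min_lat, max_lon, max_lat)``; ``label`` is the ground-truth
    relevance label when known (``"relevant"`` / ``"irrelevant"``).
    """

    post_id: str
    timestamp: dt.datetime
    bbox: tuple[float, float, float, float]
    text: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        lo_x, lo_y, hi_x, hi_y = self.bbox
        if not (np.isfinite(lo_x) and np.isfinite(lo_y) and np.isfinite(hi_x) and np.isfinite(hi_y)):
            raise SchemaError("bbox: coordinates must be finite")
        if lo_x > hi_x or lo_y > hi_y:
            raise SchemaError("bbox: min corner must not exceed max corner")
        if self.label not in (None, "relevant", "irrelevant"):
            raise SchemaError("label: must be 'relevant', 'irrelevant' or absent")


@dataclass
class SurveillanceSeries:
    """A region-indexed daily time series of one stream type.

    ``values`` is indexed by consecutive calendar days; missing observations
    are explicit ``NaN``, never dropped. Counts are integer-valued,
    probabilities lie in [0, 1].
    """

    region_id: str
    stream: str
    values: pd.Series
    #: smoothed/derived series are real-valued even for count streams
    smoothed: bool = False

    def __post_init__(self) -> None:
        if self.stream not in STREAMS:
            raise SchemaError(f"stream: unknown stream type {self.stream!r}")
        if not isinstance(self.values.index, pd.DatetimeIndex):
            raise SchemaError("values: index must be a DatetimeIndex")
        idx = self.values.index
        if len(idx) == 0:
            raise SchemaError("values: series is empty")
        deltas = np.diff(idx.values).astype("timedelta64[D]").astype(int)
        if len(deltas) and not np.all(deltas == 1):
            raise SchemaError("values: dates must be consecutive calendar days")
        vals = self.values.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if self.stream in COUNT_STREAMS:
            if np.any(finite < 0):
                raise SchemaError(f"values: {self.stream} must be non-negative")
            if not self.smoothed and np.any(finite != np.round(finite)):
                raise SchemaError(f"values: {self.stream} must hold integer counts")
        else:
            if np.any((finite < 0) | (finite > 1)):
                raise SchemaError(f"values: {self.stream} must lie in [0, 1]")
        self.values = self.values.astype(float)
        self.values.name = self.stream

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.values.index

    def replace_values(self, values: pd.Series, smoothed: bool | None = None) -> "SurveillanceSeries":
        """Return a copy carrying ``values`` (same region and stream)."""
        smoothed = self.smoothed if smoothed is None else smoothed
        return SurveillanceSeries(self.region_id, self.stream, values, smoothed=smoothed)


#: required columns of a region table; ``geometry`` holds shapely Polygons
REGION_COLUMNS = ("region_id", "name", "population", "dma_id", "geometry")


def validate_regions(regions: pd.DataFrame) -> pd.DataFrame:
    """Validate a region table in place and return it.

    Checks column presence, unique region ids, positive populations and
    simple polygon geometry.
    """
    for col in REGION_COLUMNS:
        if col not in regions.columns:
            raise SchemaError(f"regions: missing column {col!r}")
    if regions["region_id"].duplicated().any():
        dupes = regions.loc[regions["region_id"].duplicated(), "region_id"].tolist()
        raise SchemaError(f"region_id: duplicate ids {dupes}")
    if (regions["population"] <= 0).any():
        raise ConfigError("population: all region populations must be positive")
    for geom in regions["geometry"]:
        if not geom.is_valid:
            raise SchemaError("geometry: polygon is not simple/valid")
    return regions


def series_to_frame(series: Iterable[SurveillanceSeries]) -> pd.DataFrame:
    """Stack series into a long table (region_id, date, stream, value)."""
    parts = []
    for s in series:
        parts.append(
            pd.DataFrame(
                {
                    "region_id": s.region_id,
                    "date": s.dates,
                    "stream": s.stream,
                    "value": s.values.to_numpy(),
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=["region_id", "date", "stream", "value"])
    return pd.concat(parts, ignore_index=True)


def frame_to_series(frame: pd.DataFrame, smoothed: bool = False) -> list[SurveillanceSeries]:
    """Inverse of :func:`series_to_frame`; gaps become explicit missing."""
    out: list[SurveillanceSeries] = []
    for (region_id, stream), grp in frame.groupby(["region_id", "stream"], sort=True):
        grp = grp.sort_values("date")
        idx = pd.DatetimeIndex(pd.to_datetime(grp["date"]))
        full = pd.date_range(idx.min(), idx.max(), freq="D")
        vals = pd.Series(grp["value"].to_numpy(dtype=float), index=idx).reindex(full)
        out.append(SurveillanceSeries(str(region_id), str(stream), vals, smoothed=smoothed))
    return out
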