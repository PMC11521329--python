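"""Geographic assignment of posts to regions and county→DMA reconciliation.

Geotagged posts carry a rectangular place bounding box rather than a point;
the box centroid is the post's location, and the post is attributed to the
region (toy county) whose polygon contains that centroid. Regions belong to
media-market groups (DMAs) — the coarser geography at which search-volume
data exist — and count/probability streams aggregate up to DMAs by summation
or population weighting respectively.

Geometry is planar on lon/lat (no spherical correction), which is adequate
at county scale and mirrors database point-in-polygon semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .base import (
    AmbiguousRegionError,
    COUNT_STREAMS,
    PostRecord,
    SchemaError,
    SurveillanceSeries,
    validate_regions,
)

__all__ = [
    "bbox_centroid",
    "assign_point_to_region",
    "assign_posts",
    "AssignmentLog",
    "aggregate_regions_to_dma",
]


def bbox_centroid(bbox: Sequence[float]) -> tuple[float, float]:
    """Arithmetic midpoint of a (min_lon, min_lat, max_lon, max_lat) box.

    Degenerate (point) boxes are allowed and return the point itself.
    """
    lo_x, lo_y, hi_x, hi_y = (float(v) for v in bbox)
    if not all(np.isfinite(v) for v in (lo_x, lo_y, hi_x, hi_y)):
        raise SchemaError("bbox: coordinates must be finite")
    return ((lo_x + hi_x) / 2.0, (lo_y + hi_y) / 2.0)


def assign_point_to_region(
    point: tuple[float, float], regions: pd.DataFrame
) -> Optional[str]:
    """Return the id of the region containing ``point``, or None.

    Containment uses the even-odd rule on polygon boundaries (shapely
    ``covers``, which includes the boundary). A point on a shared edge is
    assigned deterministically to the lexicographically smallest containing
    region id; a point strictly interior to two regions is an error because
    regions must partition the plane region they tile.
    """
    if len(regions) == 0:
        raise SchemaError("regions: table is empty")
    lon, lat = point
    if not (np.isfinite(lon) and np.isfinite(lat)):
        raise SchemaError("point: coordinates must be finite")
    p = Point(lon, lat)
    covering = []
    interior = []
    for region_id, geom in zip(regions["region_id"], regions["geometry"]):
        if geom.covers(p):
            covering.append(str(region_id))
            if geom.contains(p):
                interior.append(str(region_id))
    if len(interior) > 1:
        raise AmbiguousRegionError(
            f"point {point} lies strictly inside regions {sorted(interior)}"
        )
    if not covering:
        return None
    return min(covering)


@dataclass
class AssignmentLog:
    """Bookkeeping for post→region assignment; nothing is dropped silently."""

    n_input: int = 0
    n_assigned: int = 0
    unassigned: list[str] = field(default_factory=list)

    @property
    def n_unassigned(self) -> int:
        return len(self.unassigned)


def assign_posts(
    posts: Iterable[PostRecord], regions: pd.DataFrame
) -> tuple[pd.DataFrame, AssignmentLog]:
    """Assign each post's bbox centroid to a region.

    Returns a table (post_id, timestamp, region_id) of assigned posts and a
    log listing ids of posts whose centroid fell in no region.
    """
    import shapely

    validate_regions(regions)
    posts = list(posts)
    log = AssignmentLog(n_input=len(posts))
    if not posts:
        return pd.DataFrame(columns=["post_id", "timestamp", "region_id"]), log
    cx = np.empty(len(posts))
    cy = np.empty(len(posts))
    for i, p in enumerate(posts):
        cx[i], cy[i] = bbox_centroid(p.bbox)
    pts = shapely.points(cx, cy)
    # vectorized covers/contains per region; ties on shared edges resolve to
    # the lexicographically smallest region id, interior overlap is an error
    order = np.argsort(regions["region_id"].astype(str).to_numpy())
    assigned = np.full(len(posts), None, dtype=object)
    interior_hits = np.zeros(len(posts), dtype=int)
    for j in order:
        geom = regions["geometry"].iloc[j]
        rid = str(regions["region_id"].iloc[j])
        covers = shapely.covers(geom, pts)
        interior_hits += shapely.contains(geom, pts).astype(int)
        newly = covers & (assigned == None)  # noqa: E711 — elementwise
        assigned[newly] = rid
    over = np.nonzero(interior_hits > 1)[0]
    if len(over):
        i = int(over[0])
        raise AmbiguousRegionError(
            f"point ({cx[i]}, {cy[i]}) lies strictly inside multiple regions"
        )
    rows = []
    for i, p in enumerate(posts):
        if assigned[i] is None:
            log.unassigned.append(p.post_id)
        else:
            log.n_assigned += 1
            rows.append((p.post_id, p.timestamp, assigned[i]))
    table = pd.DataFrame(rows, columns=["post_id", "timestamp", "region_id"])
    return table, log


def aggregate_regions_to_dma(
    series: Iterable[SurveillanceSeries], regions: pd.DataFrame
) -> list[SurveillanceSeries]:
    """Aggregate region-level streams to DMA level.

    Count streams are summed within DMA per day; probability streams are
    population-weighted means (days where a region is missing drop that
    region from the day's weighting). All input series must share one stream
    type per call, and output dates equal input dates.
    """
    series = list(series)
    if not series:
        return []
    streams = {s.stream for s in series}
    if len(streams) > 1:
        raise SchemaError(f"stream: cannot mix stream types {sorted(streams)} in one aggregation")
    stream = series[0].stream
    validate_regions(regions)
    meta = regions.set_index("region_id")
    out: list[SurveillanceSeries] = []
    by_dma: dict[str, list[SurveillanceSeries]] = {}
    for s in series:
        if s.region_id not in meta.index:
            raise SchemaError(f"region_id: {s.region_id!r} not present in region table")
        by_dma.setdefault(str(meta.loc[s.region_id, "dma_id"]), []).append(s)
    for dma_id in sorted(by_dma):
        members = by_dma[dma_id]
        frame = pd.concat([m.values.rename(m.region_id) for m in members], axis=1)
        if stream in COUNT_STREAMS:
            # a day missing in any member makes the DMA total undefined
            agg = frame.sum(axis=1, min_count=len(members))
        else:
            pops = np.array([float(meta.loc[m.region_id, "population"]) for m in members])
            w = pd.DataFrame(
                np.tile(pops, (len(frame), 1)), index=frame.index, columns=frame.columns
            ).where(frame.notna())
            agg = (frame * w).sum(axis=1) / w.sum(axis=1)
        out.append(SurveillanceSeries(dma_id, stream, agg))
    return out
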