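"""Region-day series construction, normalization, denoising and QC.

Events (assigned posts or coded ED visits) become daily counts per region;
counts become per-capita rates or probabilities; a centered 7-day moving
average removes weekly periodicity; and data-sufficiency rules exclude
regions whose clinical or post volume is too thin to trust.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .base import (
    ConfigError,
    SchemaError,
    SurveillanceSeries,
    COUNT_STREAMS,
)

logger = logging.getLogger(__name__)

__all__ = [
    "QualityThresholds",
    "AggregationLog",
    "aggregate_daily",
    "post_probability",
    "rolling_mean_7d",
    "per_capita",
    "exclude_date_range",
    "quality_filter",
    "average_replicates",
]


@dataclass(frozen=True)
class QualityThresholds:
    """Data-sufficiency rules for including a region in validation/mapping.

    A region is kept only when, over the full analysis window, its
    population is at least ``min_population``, its allergy-coded ED
    encounters reach ``min_ed_per_100k`` per 100,000 people, and its allergy
    posts reach ``min_posts_per_100k`` per 100,000 people. Below those
    volumes the streams are too sparse for stable correlation estimates.
    """

    min_ed_per_100k: float = 450.0
    min_posts_per_100k: float = 80.0
    min_population: int = 500_000

    def __post_init__(self) -> None:
        if self.min_ed_per_100k < 0 or self.min_posts_per_100k < 0 or self.min_population < 0:
            raise ConfigError("QualityThresholds: thresholds must be non-negative")


@dataclass
class AggregationLog:
    n_input: int = 0
    n_binned: int = 0
    n_out_of_range: int = 0
    n_unknown_region: int = 0


def aggregate_daily(
    events: pd.DataFrame,
    region_ids: Sequence[str],
    start: dt.date,
    end: dt.date,
    stream: str = "allergy_posts",
) -> tuple[list[SurveillanceSeries], AggregationLog]:
    """Bin events into one count per region per calendar day.

    ``events`` needs columns ``region_id`` and ``timestamp``; timestamps are
    binned by (UTC) calendar date. Days without events are explicit zeros
    over [start, end]. Events outside the date range or naming an unknown
    region are logged and excluded, never dropped silently.
    """
    if stream not in COUNT_STREAMS:
        raise SchemaError(f"stream: {stream!r} is not a count stream")
    if end < start:
        raise ConfigError("aggregate_daily: end date precedes start date")
    for col in ("region_id", "timestamp"):
        if col not in events.columns:
            raise SchemaError(f"events: missing column {col!r}")
    log = AggregationLog(n_input=len(events))
    index = pd.date_range(start, end, freq="D")
    known = set(map(str, region_ids))
    counts: dict[str, pd.Series] = {
        rid: pd.Series(0.0, index=index) for rid in sorted(known)
    }
    if len(events):
        days = pd.to_datetime(events["timestamp"]).dt.normalize()
        if getattr(days.dt, "tz", None) is not None:
            days = days.dt.tz_localize(None)
        for rid, day in zip(events["region_id"].astype(str), days):
            if rid not in known:
                log.n_unknown_region += 1
                continue
            if day < index[0] or day > index[-1]:
                log.n_out_of_range += 1
                continue
            counts[rid][day] += 1
            log.n_binned += 1
    out = [SurveillanceSeries(rid, stream, counts[rid]) for rid in sorted(known)]
    return out, log


def post_probability(
    allergy_counts: SurveillanceSeries, total_counts: SurveillanceSeries
) -> SurveillanceSeries:
    """Daily probability that a post is allergy-related: allergy/total.

    Days with zero total posts are missing, not zero — no posts means the
    probability is unobserved.
    """
    if allergy_counts.region_id != total_counts.region_id:
        raise SchemaError("region_id: allergy and total series disagree")
    if not allergy_counts.dates.equals(total_counts.dates):
        raise SchemaError("dates: allergy and total series are not aligned")
    a = allergy_counts.values
    t = total_counts.values
    over = (a > t) & a.notna() & t.notna()
    if over.any():
        day = over.idxmax().date()
        raise SchemaError(f"allergy count exceeds total count on {day}")
    with np.errstate(invalid="ignore", divide="ignore"):
        p = a / t.where(t > 0)
    return SurveillanceSeries(allergy_counts.region_id, "post_probability", p)


def rolling_mean_7d(series: SurveillanceSeries) -> SurveillanceSeries:
    """Centered 7-day moving average (low-pass filter).

    Removes day-of-week periodicity exactly on interior days because each
    7-day window covers each weekday once. A day's value is the mean of the
    non-missing entries in its ±3-day window when at least 4 are present,
    else missing; the same rule covers the 3 edge days on each end.
    """
    sm = series.values.rolling(window=7, center=True, min_periods=4).mean()
    return series.replace_values(sm, smoothed=True)


def per_capita(
    series: SurveillanceSeries, population: float, per: float = 100_000.0
) -> pd.Series:
    """Scale a count series to a rate per ``per`` (default 100,000) people."""
    if population <= 0:
        raise ConfigError("population must be positive")
    return series.values * (per / float(population))


def exclude_date_range(
    series: SurveillanceSeries,
    ranges: Sequence[tuple[dt.date, dt.date]],
) -> SurveillanceSeries:
    """Mask values inside closed date intervals (index unchanged).

    Used to drop periods whose observation process broke down — e.g. a
    pandemic year during which care-seeking behavior changed — without
    shortening the series.
    """
    vals = series.values.copy()
    for rng in ranges:
        try:
            lo, hi = rng
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"malformed date range {rng!r}") from exc
        lo_ts, hi_ts = pd.Timestamp(lo), pd.Timestamp(hi)
        if hi_ts < lo_ts:
            raise ConfigError(f"malformed date range {rng!r}: end precedes start")
        vals[(vals.index >= lo_ts) & (vals.index <= hi_ts)] = np.nan
    return series.replace_values(vals)


def quality_filter(
    summaries: pd.DataFrame, thresholds: QualityThresholds = QualityThresholds()
) -> tuple[list[str], pd.DataFrame]:
    """Apply the population / ED-volume / post-volume sufficiency rules.

    ``summaries`` needs columns region_id, population, total_ed, total_posts
    (totals over the normalization window). Inclusion requires population ≥
    min_population AND ED per 100k ≥ min_ed_per_100k AND posts per 100k ≥
    min_posts_per_100k; regions with *fewer* than the thresholds are
    excluded, so exact boundary values pass. Returns included ids plus a
    per-region report with each criterion's value and verdict.
    """
    for col in ("region_id", "population", "total_ed", "total_posts"):
        if col not in summaries.columns:
            raise SchemaError(f"summaries: missing column {col!r}")
    if summaries[["population", "total_ed", "total_posts"]].isna().any(axis=None):
        raise SchemaError("summaries: missing summary field value")
    report = summaries.copy()
    report["ed_per_100k"] = report["total_ed"] * 1e5 / report["population"]
    report["posts_per_100k"] = report["total_posts"] * 1e5 / report["population"]
    report["pass_population"] = report["population"] >= thresholds.min_population
    report["pass_ed"] = report["ed_per_100k"] >= thresholds.min_ed_per_100k
    report["pass_posts"] = report["posts_per_100k"] >= thresholds.min_posts_per_100k
    report["included"] = (
        report["pass_population"] & report["pass_ed"] & report["pass_posts"]
    )
    included = sorted(report.loc[report["included"], "region_id"].astype(str))
    return included, report


def average_replicates(replicates: Sequence[SurveillanceSeries]) -> SurveillanceSeries:
    """Pointwise mean over replicate samples of the same series.

    Search-volume services return a different random subsample on every
    download; averaging repeated samples recovers a stable series. Missing
    values are skipped per day (mean of the remaining replicates).
    """
    if len(replicates) == 0:
        raise ConfigError("average_replicates: empty replicate list")
    first = replicates[0]
    for r in replicates[1:]:
        if not r.dates.equals(first.dates):
            raise SchemaError("dates: replicates are not aligned")
        if r.stream != first.stream or r.region_id != first.region_id:
            raise SchemaError("replicates must share region and stream")
    frame = pd.concat([r.values.reset_index(drop=True) for r in replicates], axis=1)
    mean = pd.Series(frame.mean(axis=1, skipna=True).to_numpy(), index=first.dates)
    return SurveillanceSeries(first.region_id, first.stream, mean)
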