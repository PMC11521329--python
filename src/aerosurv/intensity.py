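"""Allergy-intensity mapping: cross-region Z-scores and peak timing.

Once an internet stream is validated against the clinical stream, the post
probability itself becomes the surveillance signal. Intensity is expressed
relative to the other regions: each region's mean daily post probability
(annual, or pooled within a season across years) is standardized across
regions to a Z-score, so maps show *where* allergies run hot rather than
absolute post volumes. Peak timing is the day of year of the maximum
smoothed signal within a season window, which exposes geographic timing
gradients (e.g. southern regions peaking earlier in spring).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .base import ConfigError, DegenerateInputError, SchemaError, SurveillanceSeries
from .series import rolling_mean_7d

__all__ = [
    "SeasonWindows",
    "IntensityResult",
    "annual_intensity_z",
    "seasonal_intensity_z",
    "peak_date",
    "weekly_matrix",
    "compute_intensity",
    "save_weekly_heatmap",
    "save_choropleth",
]


@dataclass(frozen=True)
class SeasonWindows:
    """Day-of-year season windows covering the year without overlap.

    Spring (Mar–May) is the dominant allergy season and fall (Sep–Oct) the
    secondary one; summer and winter complete the partition. Winter spans
    the year boundary: winter of year Y runs Nov Y through Feb Y+1.
    """

    spring: tuple[tuple[int, int], tuple[int, int]] = ((3, 1), (5, 31))
    summer: tuple[tuple[int, int], tuple[int, int]] = ((6, 1), (8, 31))
    fall: tuple[tuple[int, int], tuple[int, int]] = ((9, 1), (10, 31))
    winter: tuple[tuple[int, int], tuple[int, int]] = ((11, 1), (2, 29))

    def names(self) -> tuple[str, ...]:
        return ("spring", "summer", "fall", "winter")

    def season_of(self, month: int, day: int) -> str:
        for name in self.names():
            (m0, d0), (m1, d1) = getattr(self, name)
            start = (m0, d0)
            end = (m1, d1)
            if start <= end:
                if start <= (month, day) <= end:
                    return name
            else:  # wraps the year boundary
                if (month, day) >= start or (month, day) <= end:
                    return name
        raise ConfigError(f"season windows do not cover {month:02d}-{day:02d}")

    def labels(self, index: pd.DatetimeIndex) -> pd.Series:
        return pd.Series(
            [self.season_of(ts.month, ts.day) for ts in index], index=index
        )


def _z_across_regions(means: pd.Series) -> pd.Series:
    if len(means) < 2:
        raise DegenerateInputError("Z-scores need at least 2 regions")
    sd = means.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("zero cross-region variance; Z-scores undefined")
    return (means - means.mean()) / sd


def annual_intensity_z(series_set: Sequence[SurveillanceSeries]) -> pd.Series:
    """Annualized intensity: per-region mean daily post probability over the
    full window, Z-scored across regions (sample sd)."""
    means = pd.Series(
        {s.region_id: s.values.mean(skipna=True) for s in series_set}
    ).sort_index()
    return _z_across_regions(means)


def seasonal_intensity_z(
    series_set: Sequence[SurveillanceSeries], windows: SeasonWindows = SeasonWindows()
) -> pd.DataFrame:
    """Per-season intensity: mean over all days of the season pooled across
    years, Z-scored across regions within each season.

    Returns a region × season frame; each column has mean 0 and sample sd 1.
    """
    rows = {}
    for s in series_set:
        labels = windows.labels(s.dates)
        rows[s.region_id] = s.values.groupby(labels.to_numpy()).mean()
    frame = pd.DataFrame(rows).T.sort_index()
    frame = frame[[n for n in windows.names() if n in frame.columns]]
    return frame.apply(_z_across_regions, axis=0)


def peak_date(
    series: SurveillanceSeries,
    window: tuple[tuple[int, int], tuple[int, int]],
    year: int,
) -> Optional[int]:
    """Day of year of the maximum smoothed value within a season window.

    For windows spanning the year boundary, ``year`` is the year the window
    starts. Ties break to the earliest day. Returns None (explicitly
    undefined) when the window holds no data.
    """
    (m0, d0), (m1, d1) = window
    start = pd.Timestamp(dt.date(year, m0, d0))
    end_year = year if (m0, d0) <= (m1, d1) else year + 1
    try:
        end = pd.Timestamp(dt.date(end_year, m1, d1))
    except ValueError:  # e.g. Feb 29 of a non-leap year
        end = pd.Timestamp(dt.date(end_year, m1, d1 - 1))
    vals = series.values[(series.dates >= start) & (series.dates <= end)]
    if len(vals) == 0 or vals.isna().all():
        return None
    peak_ts = vals.idxmax()  # first occurrence of the maximum
    return int(pd.Timestamp(peak_ts).dayofyear)


def weekly_matrix(
    series_set: Sequence[SurveillanceSeries],
    region_order: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """ISO-week mean of the raw post probability per region.

    Rows follow ``region_order`` when given (e.g. regions sorted north to
    south by centroid latitude); columns are (ISO year, ISO week).
    """
    rows = {}
    for s in series_set:
        iso = s.dates.isocalendar()
        key = list(zip(iso["year"].to_numpy(), iso["week"].to_numpy()))
        rows[s.region_id] = s.values.groupby(pd.Index(key)).mean()
    frame = pd.DataFrame(rows).T
    frame = frame[sorted(frame.columns)]
    if region_order is not None:
        missing = sorted(set(region_order) - set(frame.index))
        if missing:
            raise SchemaError(f"region_order names unknown regions {missing}")
        frame = frame.loc[list(region_order)]
    else:
        frame = frame.sort_index()
    return frame


@dataclass
class IntensityResult:
    """Mapping-stage output: Z-scores, peak dates and the weekly matrix."""

    annual_z: pd.Series
    seasonal_z: pd.DataFrame
    peak_dates: pd.DataFrame  # rows (region, year), columns seasons
    weekly: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"annual_z": self.annual_z})
        for season in self.seasonal_z.columns:
            out[f"{season}_z"] = self.seasonal_z[season]
        return out.rename_axis("region_id").reset_index()


def compute_intensity(
    probability_series: Sequence[SurveillanceSeries],
    windows: SeasonWindows = SeasonWindows(),
    regions: Optional[pd.DataFrame] = None,
    peak_seasons: Sequence[str] = ("spring", "fall"),
) -> IntensityResult:
    """Assemble the full mapping stage from per-region probability series.

    Peak detection runs on the 7-day-smoothed series (matching the
    denoising used everywhere else); Z-scores and the weekly matrix use the
    raw probabilities. When a region table is supplied, weekly-matrix rows
    are ordered north to south by polygon centroid latitude.
    """
    annual = annual_intensity_z(probability_series)
    seasonal = seasonal_intensity_z(probability_series, windows)
    order = None
    if regions is not None:
        lats = {
            str(row["region_id"]): row["geometry"].centroid.y
            for _, row in regions.iterrows()
        }
        known = [s.region_id for s in probability_series]
        order = sorted(known, key=lambda rid: -lats.get(rid, -np.inf))
    weekly = weekly_matrix(probability_series, region_order=order)
    rows = []
    for s in probability_series:
        sm = rolling_mean_7d(s)
        years = sorted(set(s.dates.year))
        for year in years:
            entry: dict = {"region_id": s.region_id, "year": year}
            for season in peak_seasons:
                entry[f"peak_{season}"] = peak_date(sm, getattr(windows, season), year)
            rows.append(entry)
    peaks = pd.DataFrame(rows)
    return IntensityResult(
        annual_z=annual, seasonal_z=seasonal, peak_dates=peaks, weekly=weekly
    )


def save_weekly_heatmap(weekly: pd.DataFrame, path) -> None:
    """Render the region × ISO-week matrix as a heatmap PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, weekly.shape[1] / 12), max(2, weekly.shape[0] / 2)))
    im = ax.imshow(weekly.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(weekly.index)), weekly.index)
    ax.set_xlabel("ISO week")
    ax.set_ylabel("region (north → south)")
    fig.colorbar(im, ax=ax, label="mean post probability")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def save_choropleth(regions: pd.DataFrame, values: pd.Series, path, label: str = "Z") -> None:
    """Fill each region polygon by its value (e.g. annual Z-score)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import PolyCollection

    verts, vals = [], []
    for _, row in regions.iterrows():
        rid = str(row["region_id"])
        if rid in values.index:
            verts.append(np.asarray(row["geometry"].exterior.coords))
            vals.append(float(values[rid]))
    fig, ax = plt.subplots(figsize=(6, 5))
    coll = PolyCollection(verts, array=np.array(vals), cmap="coolwarm", edgecolor="k")
    ax.add_collection(coll)
    ax.autoscale_view()
    ax.set_xlabel("lon")
    ax.set_ylabel("lat")
    fig.colorbar(coll, ax=ax, label=label)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
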