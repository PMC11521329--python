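"""Synthetic coupled surveillance streams with known ground truth.

The generator emulates the data-generating process the validation battery
assumes: an unobserved regional aeroallergen level — a deterministic annual
seasonal component plus a stochastic trend (random walk) plus a stationary
AR(1) anomaly — drives three observed streams in parallel:

* allergy-coded emergency-department visits (Poisson counts),
* allergy-related social posts (Binomial thinning of total post volume),
* a bounded search probability (logistic link plus bounded noise).

Because all three streams load on the *same* random-walk trend within a
region, any pair is cointegrated by construction, and the three together
have exactly one common stochastic trend (cointegrating rank 2). Setting
the couplings to zero and switching on independent per-stream walks gives
the matching null: three unrelated I(1) streams.

A companion post generator emits individually labeled post texts —
symptom-report templates plus confounder templates that share the retrieval
keywords ("a chicken sneezing…") — whose per-day relevant counts equal the
allergy-post count stream draw for draw, so the text stage and the
aggregation stage can be checked against each other exactly.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from shapely.geometry import Polygon

from .base import ConfigError, PostRecord, SurveillanceSeries, validate_regions

__all__ = [
    "SeasonalPeak",
    "SyntheticConfig",
    "LatentSeries",
    "generate_regions",
    "generate_latent",
    "generate_streams",
    "generate_posts",
    "resample_series_replicates",
    "null_config",
]

#: wrap length for circular day-of-year distance; keeps peak phases stable
#: across leap years
DOY_PERIOD = 365.25

# stable sub-stream tags so adding regions or streams never perturbs the
# draws of existing ones
_PURPOSE = {
    "trend": 1,
    "anomaly": 2,
    "ed": 3,
    "total_posts": 4,
    "allergy_posts": 5,
    "search": 6,
    "posts_text": 7,
    "walk_ed": 8,
    "walk_posts": 9,
    "walk_search": 10,
}


def _rng(seed: int, purpose: str, region_index: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), _PURPOSE[purpose], int(region_index)])
    )


@dataclass(frozen=True)
class SeasonalPeak:
    """One Gaussian bump in the annual aeroallergen cycle.

    ``peak_doy`` is the day of year of maximum release, ``amplitude`` the
    latent-level height, ``width_days`` the Gaussian σ in days.
    """

    peak_doy: float
    amplitude: float
    width_days: float

    def __post_init__(self) -> None:
        if self.width_days <= 0:
            raise ConfigError("SeasonalPeak: width_days must be positive")
        if self.amplitude < 0:
            raise ConfigError("SeasonalPeak: amplitude must be non-negative")


def _default_peaks(n_regions: int) -> tuple[tuple[SeasonalPeak, ...], ...]:
    """Spring-dominant pattern with a secondary fall season; the spring peak
    drifts a few days across regions, mimicking a geographic timing
    gradient."""
    out = []
    for i in range(n_regions):
        out.append(
            (
                SeasonalPeak(peak_doy=90.0 + 4.0 * i, amplitude=1.0, width_days=30.0),
                SeasonalPeak(peak_doy=270.0 + 2.0 * i, amplitude=0.4, width_days=20.0),
            )
        )
    return tuple(out)


def _default_populations(n_regions: int) -> tuple[int, ...]:
    """Deterministic log-spaced populations, 250k–2.5M; the smallest fall
    under the usual 500k inclusion threshold so quality filtering has work
    to do."""
    if n_regions == 1:
        return (1_000_000,)
    logs = np.linspace(np.log(250_000), np.log(2_500_000), n_regions)
    return tuple(int(round(v, -3)) for v in np.exp(logs))


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generative model; one seed drives everything.

    Rates are per 100,000 population per day. ``coupling_ed`` /
    ``coupling_posts`` / ``coupling_search`` link the latent level into the
    ED rate (additively), the relevant-post fraction (on the logit scale)
    and the search probability (on the logit scale). ``stream_walk_sd`` > 0
    adds an *independent* random walk per stream per region, which together
    with zero couplings yields the no-cointegration null.
    """

    n_regions: int = 8
    n_days: int = 1461  # four calendar years incl. one leap day
    start_date: dt.date = dt.date(2016, 1, 1)
    seasonal_peaks: Optional[tuple[tuple[SeasonalPeak, ...], ...]] = None
    trend_sd: float = 0.02
    anomaly_sd: float = 0.20
    anomaly_phi: float = 0.7
    shared_trend_across_regions: bool = False
    trend_scales: Optional[tuple[float, ...]] = None
    coupling_ed: float = 1.2
    coupling_posts: float = 0.8
    coupling_search: float = 1.0
    stream_walk_sd: float = 0.0
    baseline_ed_rate: float = 0.6
    baseline_post_rate: float = 30.0
    relevant_fraction_base: float = 0.02
    search_prob_base: float = 0.05
    search_noise: float = 0.01
    contamination: float = 0.2
    weekly_pattern: tuple[float, ...] = (0.95, 0.95, 0.95, 0.95, 0.95, 1.10, 1.15)
    populations: Optional[tuple[int, ...]] = None
    keywords: tuple[str, ...] = ("allergies", "pollen", "sneezing", "antihistamine", "hay fever")
    regions_per_dma: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ConfigError("n_regions must be ≥ 1")
        if self.n_days < 1:
            raise ConfigError("n_days must be ≥ 1")
        for name in (
            "trend_sd",
            "anomaly_sd",
            "coupling_ed",
            "coupling_posts",
            "coupling_search",
            "stream_walk_sd",
            "baseline_ed_rate",
            "baseline_post_rate",
            "search_noise",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not (0 <= self.anomaly_phi < 1):
            raise ConfigError("anomaly_phi must lie in [0, 1)")
        if not (0 <= self.contamination < 1):
            raise ConfigError("contamination must lie in [0, 1)")
        if not (0 < self.relevant_fraction_base < 1):
            raise ConfigError("relevant_fraction_base must lie in (0, 1)")
        if not (0 < self.search_prob_base < 1):
            raise ConfigError("search_prob_base must lie in (0, 1)")
        if len(self.weekly_pattern) != 7:
            raise ConfigError("weekly_pattern must have exactly 7 entries")
        wp = np.asarray(self.weekly_pattern, dtype=float)
        if np.any(wp < 0):
            raise ConfigError("weekly_pattern entries must be non-negative")
        if abs(wp.mean() - 1.0) > 1e-12:
            raise ConfigError("weekly_pattern must average to 1 (within 1e-12)")
        if self.regions_per_dma < 1:
            raise ConfigError("regions_per_dma must be ≥ 1")

    # --- resolved (defaulted) per-region attributes -------------------

    def resolved_peaks(self) -> tuple[tuple[SeasonalPeak, ...], ...]:
        peaks = self.seasonal_peaks
        if peaks is None:
            peaks = _default_peaks(self.n_regions)
        if len(peaks) != self.n_regions:
            raise ConfigError("seasonal_peaks must list one entry per region")
        return peaks

    def resolved_populations(self) -> tuple[int, ...]:
        pops = self.populations
        if pops is None:
            pops = _default_populations(self.n_regions)
        if len(pops) != self.n_regions:
            raise ConfigError("populations must list one entry per region")
        if any(p < 0 for p in pops):
            raise ConfigError("populations must be non-negative")
        return tuple(int(p) for p in pops)

    def resolved_trend_scales(self) -> tuple[float, ...]:
        scales = self.trend_scales
        if scales is None:
            scales = tuple(1.0 for _ in range(self.n_regions))
        if len(scales) != self.n_regions:
            raise ConfigError("trend_scales must list one entry per region")
        return tuple(float(s) for s in scales)

    def region_ids(self) -> list[str]:
        width = max(2, len(str(self.n_regions - 1)))
        return [f"r{i:0{width}d}" for i in range(self.n_regions)]

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.n_days, freq="D")


def null_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The matching no-cointegration null: zero couplings, no shared trend,
    independent per-stream random walks."""
    defaults = dict(
        coupling_ed=0.0,
        coupling_posts=0.0,
        coupling_search=0.0,
        trend_sd=0.0,
        stream_walk_sd=0.02,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@dataclass
class LatentSeries:
    """Latent aeroallergen level of one region with its components kept for
    parameter-recovery tests."""

    region_id: str
    dates: pd.DatetimeIndex
    values: np.ndarray
    seasonal: np.ndarray
    trend: np.ndarray
    anomaly: np.ndarray


def generate_regions(config: SyntheticConfig) -> pd.DataFrame:
    """Tile toy counties as axis-aligned rectangles on a lon/lat grid.

    Rows of the grid run north to south, so region index correlates with
    decreasing latitude. Consecutive regions are grouped into DMAs of
    ``regions_per_dma``; DMA groups partition the regions.
    """
    n = config.n_regions
    pops = config.resolved_populations()
    if any(p <= 0 for p in pops):
        raise ConfigError("populations must be positive to build regions")
    ncols = int(math.ceil(math.sqrt(n)))
    nrows = int(math.ceil(n / ncols))
    lon0, lat0 = -120.0, 42.0  # NW corner of the tiled block
    cell_w, cell_h = 2.0, 1.5
    rows = []
    ids = config.region_ids()
    for i in range(n):
        r, c = divmod(i, ncols)
        x0 = lon0 + c * cell_w
        y1 = lat0 - r * cell_h  # north edge
        poly = Polygon(
            [(x0, y1 - cell_h), (x0 + cell_w, y1 - cell_h), (x0 + cell_w, y1), (x0, y1)]
        )
        rows.append(
            {
                "region_id": ids[i],
                "name": f"County {i:02d}",
                "population": pops[i],
                "dma_id": f"d{i // config.regions_per_dma:02d}",
                "geometry": poly,
            }
        )
    return validate_regions(pd.DataFrame(rows))


def _circular_doy_distance(doy: np.ndarray, peak: float, period: float = DOY_PERIOD) -> np.ndarray:
    d = np.mod(doy - peak + period / 2.0, period) - period / 2.0
    return np.abs(d)


def seasonal_component(
    dates: pd.DatetimeIndex, peaks: Sequence[SeasonalPeak]
) -> np.ndarray:
    """Sum of circular Gaussian bumps evaluated at each date's day of year."""
    doy = dates.dayofyear.to_numpy(dtype=float)
    out = np.zeros(len(dates))
    for pk in peaks:
        d = _circular_doy_distance(doy, pk.peak_doy)
        out += pk.amplitude * np.exp(-(d**2) / (2.0 * pk.width_days**2))
    return out


def generate_latent(config: SyntheticConfig) -> list[LatentSeries]:
    """Latent level per region: seasonal + random-walk trend + AR(1) anomaly.

    The walk is per-region by default; with ``shared_trend_across_regions``
    one walk is drawn (sub-stream of region 0) and scaled per region.
    """
    dates = config.dates()
    peaks = config.resolved_peaks()
    scales = config.resolved_trend_scales()
    out: list[LatentSeries] = []
    shared_walk = None
    if config.shared_trend_across_regions:
        shared_walk = _random_walk(config, region_index=0)
    for i, rid in enumerate(config.region_ids()):
        seas = seasonal_component(dates, peaks[i])
        if shared_walk is not None:
            trend = scales[i] * shared_walk
        else:
            trend = scales[i] * _random_walk(config, region_index=i)
        anom = _ar1(config, region_index=i)
        values = seas + trend + anom
        out.append(
            LatentSeries(
                region_id=rid,
                dates=dates,
                values=values,
                seasonal=seas,
                trend=trend,
                anomaly=anom,
            )
        )
    return out


def _random_walk(config: SyntheticConfig, region_index: int) -> np.ndarray:
    if config.trend_sd == 0:
        return np.zeros(config.n_days)
    steps = _rng(config.seed, "trend", region_index).normal(0.0, config.trend_sd, config.n_days)
    steps[0] = 0.0
    return np.cumsum(steps)


def _ar1(config: SyntheticConfig, region_index: int) -> np.ndarray:
    if config.anomaly_sd == 0:
        return np.zeros(config.n_days)
    rng = _rng(config.seed, "anomaly", region_index)
    phi, sd = config.anomaly_phi, config.anomaly_sd
    innov_sd = sd * math.sqrt(1.0 - phi**2)
    eps = rng.normal(0.0, innov_sd, config.n_days)
    x = np.empty(config.n_days)
    x[0] = rng.normal(0.0, sd)
    for t in range(1, config.n_days):
        x[t] = phi * x[t - 1] + eps[t]
    return x


def _stream_walk(config: SyntheticConfig, purpose: str, region_index: int) -> np.ndarray:
    if config.stream_walk_sd == 0:
        return np.zeros(config.n_days)
    steps = _rng(config.seed, purpose, region_index).normal(
        0.0, config.stream_walk_sd, config.n_days
    )
    steps[0] = 0.0
    return np.cumsum(steps)


def _check_latent(latent: Sequence[LatentSeries], config: SyntheticConfig) -> None:
    ids = config.region_ids()
    have = [ls.region_id for ls in latent]
    if have != ids:
        raise ConfigError(f"latent series do not cover configured regions: {have} vs {ids}")
    for ls in latent:
        if np.any(~np.isfinite(ls.values)):
            raise ConfigError(f"latent series {ls.region_id} contains NaN/inf")


def _weekly_multiplier(config: SyntheticConfig) -> np.ndarray:
    dow = config.dates().dayofweek.to_numpy()  # Monday=0
    return np.asarray(config.weekly_pattern, dtype=float)[dow]


def _relevant_fraction(config: SyntheticConfig, a: np.ndarray, walk: np.ndarray) -> np.ndarray:
    return expit(logit(config.relevant_fraction_base) + config.coupling_posts * a + walk)


def _draw_post_counts(
    latent: Sequence[LatentSeries], config: SyntheticConfig
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Total and allergy post counts per region; a single code path shared
    by the stream generator and the post-text generator so both see the
    identical draws."""
    pops = config.resolved_populations()
    wk = _weekly_multiplier(config)
    totals, allergy = [], []
    for i, ls in enumerate(latent):
        rng_tot = _rng(config.seed, "total_posts", i)
        rng_all = _rng(config.seed, "allergy_posts", i)
        lam = pops[i] / 1e5 * config.baseline_post_rate * wk
        tot = rng_tot.poisson(lam)
        walk = _stream_walk(config, "walk_posts", i)
        p_rel = _relevant_fraction(config, ls.values, walk)
        alg = rng_all.binomial(tot, np.clip(p_rel, 0.0, 1.0))
        totals.append(tot)
        allergy.append(alg)
    return totals, allergy


def generate_streams(
    latent: Sequence[LatentSeries], config: SyntheticConfig
) -> list[SurveillanceSeries]:
    """Observe the latent levels through the five surveillance streams."""
    _check_latent(latent, config)
    dates = config.dates()
    pops = config.resolved_populations()
    wk = _weekly_multiplier(config)
    totals, allergy = _draw_post_counts(latent, config)
    out: list[SurveillanceSeries] = []
    for i, ls in enumerate(latent):
        rid = ls.region_id
        rng_ed = _rng(config.seed, "ed", i)
        rng_search = _rng(config.seed, "search", i)
        ed_rate = np.maximum(
            0.0,
            config.baseline_ed_rate
            + config.coupling_ed * ls.values
            + _stream_walk(config, "walk_ed", i),
        )
        ed = rng_ed.poisson(pops[i] / 1e5 * ed_rate * wk)
        search = expit(
            logit(config.search_prob_base)
            + config.coupling_search * ls.values
            + _stream_walk(config, "walk_search", i)
        )
        if config.search_noise > 0:
            search = search + rng_search.uniform(
                -config.search_noise, config.search_noise, config.n_days
            )
        search = np.clip(search, 0.0, 1.0)
        out.append(SurveillanceSeries(rid, "ed_count", pd.Series(ed.astype(float), index=dates)))
        out.append(
            SurveillanceSeries(rid, "total_posts", pd.Series(totals[i].astype(float), index=dates))
        )
        out.append(
            SurveillanceSeries(rid, "allergy_posts", pd.Series(allergy[i].astype(float), index=dates))
        )
        out.append(SurveillanceSeries(rid, "search_probability", pd.Series(search, index=dates)))
    return out


# post-text templates; the {kw} slot takes a configured keyword.  Relevant
# templates read like first-person symptom reports; confounders share the
# keywords but not the symptom context.
_RELEVANT_TEMPLATES = (
    "My {kw} are really acting up today, cannot stop sneezing!!",
    "ugh {kw} season is the worst, eyes itchy and nose running all day",
    "took an antihistamine this morning but the {kw} will not quit",
    "the pollen count must be off the charts, my {kw} are brutal right now",
    "woke up sneezing nonstop, {kw} hitting hard this week",
)
_IRRELEVANT_TEMPLATES = (
    "a chicken sneezing.... that is all",
    "Gluten and {kw} Free expo is downtown this weekend, free samples",
    "is the {kw} free menu at that cafe any good? asking for a friend",
    "COVID-19 or {kw}? new clinic chatbot claims it can tell the difference",
    "peanut brand settles {kw} label lawsuit for millions, stock up anyway",
)


def generate_posts(
    latent: Sequence[LatentSeries], config: SyntheticConfig
) -> list[PostRecord]:
    """Emit labeled keyword-matching posts day by day.

    Relevant post counts per region-day equal the allergy-post stream draws
    exactly (same sub-streams); irrelevant keyword-sharing posts arrive at a
    Poisson rate giving the configured contamination fraction. Each post's
    bounding box is centered at a point inside its region.
    """
    _check_latent(latent, config)
    if not config.keywords:
        raise ConfigError("keywords must be non-empty to generate posts")
    regions = generate_regions(config)
    dates = config.dates()
    _, allergy = _draw_post_counts(latent, config)
    c = config.contamination
    irr_factor = c / (1.0 - c) if c > 0 else 0.0
    posts: list[PostRecord] = []
    for i, ls in enumerate(latent):
        rid = ls.region_id
        rng = _rng(config.seed, "posts_text", i)
        bounds = regions.loc[regions["region_id"] == rid, "geometry"].iloc[0].bounds
        min_x, min_y, max_x, max_y = bounds
        w, h = max_x - min_x, max_y - min_y
        n_rel_days = allergy[i]
        n_irr_days = (
            rng.poisson(irr_factor * n_rel_days) if irr_factor > 0 else np.zeros_like(n_rel_days)
        )
        counter = 0
        for d_idx, day in enumerate(dates):
            for label, n in (("relevant", n_rel_days[d_idx]), ("irrelevant", n_irr_days[d_idx])):
                templates = _RELEVANT_TEMPLATES if label == "relevant" else _IRRELEVANT_TEMPLATES
                for _ in range(int(n)):
                    tpl = templates[rng.integers(len(templates))]
                    kw = config.keywords[rng.integers(len(config.keywords))]
                    text = tpl.format(kw=kw)
                    # bbox center strictly inside the region rectangle
                    cx = min_x + (0.05 + 0.9 * rng.random()) * w
                    cy = min_y + (0.05 + 0.9 * rng.random()) * h
                    half_w = 0.02 * w * rng.random()
                    half_h = 0.02 * h * rng.random()
                    ts = day.to_pydatetime() + dt.timedelta(seconds=int(rng.integers(86_400)))
                    posts.append(
                        PostRecord(
                            post_id=f"{rid}-{counter:07d}",
                            timestamp=ts,
                            bbox=(cx - half_w, cy - half_h, cx + half_w, cy + half_h),
                            text=text,
                            label=label,
                        )
                    )
                    counter += 1
    return posts


def resample_series_replicates(
    series: SurveillanceSeries, n_replicates: int, noise_sd: float, seed: int
) -> list[SurveillanceSeries]:
    """Independent noisy replicates of a series (additive Gaussian noise,
    clipped to the stream's valid range), emulating repeated downloads of a
    randomly subsampled search-volume service."""
    if n_replicates < 1:
        raise ConfigError("n_replicates must be ≥ 1")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 99]))
    vals = series.values.to_numpy()
    out = []
    for _ in range(n_replicates):
        noisy = vals + rng.normal(0.0, noise_sd, len(vals)) if noise_sd > 0 else vals.copy()
        if series.stream in ("post_probability", "search_probability"):
            noisy = np.clip(noisy, 0.0, 1.0)
        else:
            noisy = np.maximum(noisy, 0.0)
        out.append(
            series.replace_values(pd.Series(noisy, index=series.dates), smoothed=True)
        )
    return out
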