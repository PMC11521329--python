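"""Statistical validation battery for surveillance stream pairs/triples.

The logic of the validation: daily allergy streams are nonstationary (they
carry annual seasonality and a stochastic trend), so a naive correlation
between an internet stream and a clinical stream risks being spurious. The
battery therefore establishes, per region:

1. the seasonal structure of each stream (Canova–Hansen seasonal-stability
   test: stable deterministic seasonality vs. a seasonal unit root);
2. a long-run equilibrium between streams (two-step Engle–Granger
   cointegration test, run in both regression directions; Johansen trace
   test for the three-stream system);
3. a short-term linear relationship free of seasonal confounding
   (zero-lag Pearson correlation of the raw series and of two kinds of
   deseasonalized residuals — parametric seasonal-dummy regression
   residuals and nonparametric STL remainders — with ADF checks that the
   residuals are stationary).

Only when the streams are cointegrated is the zero-lag correlation of their
levels interpretable; the residual correlations then measure how tightly
short-term anomalies co-move.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from statsmodels.tsa.stattools import adfuller
from statsmodels.tsa.adfvalues import mackinnoncrit, mackinnonp
from statsmodels.tsa.seasonal import STL
from statsmodels.tsa.vector_ar.vecm import coint_johansen

from .base import (
    ConfigError,
    DegenerateInputError,
    SchemaError,
    SurveillanceSeries,
)
from .series import rolling_mean_7d

__all__ = [
    "UnitRootResult",
    "adf_test",
    "SeasonalStabilityResult",
    "canova_hansen",
    "EngleGrangerDirection",
    "EngleGrangerReport",
    "engle_granger",
    "JohansenResult",
    "johansen_trace",
    "seasonal_dummy_residuals",
    "stl_residuals",
    "PearsonResult",
    "pearson_zero_lag",
    "BatteryConfig",
    "PairResult",
    "RegionReport",
    "run_validation_battery",
    "battery_to_frame",
]

LEVELS = (0.01, 0.05, 0.10)


# --------------------------------------------------------------------------
# input plumbing

def _as_clean_array(series, allow_interior_nan: bool = False, name: str = "series") -> np.ndarray:
    """Coerce to 1-D float array, trimming missing edges; interior missing
    is an error unless explicitly allowed."""
    if isinstance(series, SurveillanceSeries):
        arr = series.values.to_numpy(dtype=float)
    elif isinstance(series, pd.Series):
        arr = series.to_numpy(dtype=float)
    else:
        arr = np.asarray(series, dtype=float)
    if arr.ndim != 1:
        raise SchemaError(f"{name}: expected a 1-D series")
    ok = np.isfinite(arr)
    if not ok.any():
        raise DegenerateInputError(f"{name}: all values missing")
    first, last = np.argmax(ok), len(arr) - 1 - np.argmax(ok[::-1])
    arr = arr[first : last + 1]
    if not np.isfinite(arr).all():
        if not allow_interior_nan:
            raise SchemaError(f"{name}: interior missing values are not supported here")
    return arr


def _schwert_maxlag(n: int) -> int:
    """Schwert's rule for the maximum ADF augmentation lag."""
    return int(math.floor(12.0 * (n / 100.0) ** 0.25))


# --------------------------------------------------------------------------
# unit-root testing

@dataclass(frozen=True)
class UnitRootResult:
    """Left-tailed unit-root (ADF) test outcome."""

    statistic: float
    pvalue: float
    lags_used: int
    nobs: int
    critical_values: dict[float, float]
    deterministic: str

    def rejects(self, level: float = 0.05) -> bool:
        return self.statistic < self.critical_values[level]


_DET_MAP = {"none": "n", "constant": "c", "constant+trend": "ct"}


def adf_test(
    series,
    max_lags: int | Literal["auto"] = "auto",
    deterministic: Literal["none", "constant", "constant+trend"] = "constant",
) -> UnitRootResult:
    """Augmented Dickey–Fuller test of a unit root.

    Lag order is chosen by AIC up to Schwert's rule when ``max_lags`` is
    ``"auto"``. Critical values come from the MacKinnon response-surface
    tabulation for the chosen deterministic term. Missing values are only
    tolerated at the series edges.
    """
    if deterministic not in _DET_MAP:
        raise ConfigError(f"deterministic must be one of {sorted(_DET_MAP)}")
    arr = _as_clean_array(series, name="series")
    if np.ptp(arr) == 0:
        raise DegenerateInputError("constant series has no unit-root hypothesis to test")
    maxlag = _schwert_maxlag(len(arr)) if max_lags == "auto" else int(max_lags)
    if len(arr) - maxlag - 1 < 30:
        raise SchemaError("need at least 30 observations after lagging")
    stat, pvalue, usedlag, nobs, crit, _ = adfuller(
        arr,
        maxlag=maxlag,
        regression=_DET_MAP[deterministic],
        autolag="AIC" if max_lags == "auto" else None,
    )
    return UnitRootResult(
        statistic=float(stat),
        pvalue=float(pvalue),
        lags_used=int(usedlag),
        nobs=int(nobs),
        critical_values={0.01: crit["1%"], 0.05: crit["5%"], 0.10: crit["10%"]},
        deterministic=deterministic,
    )


# --------------------------------------------------------------------------
# Canova–Hansen seasonal stability

# 5% critical values of the Cramér–von Mises distribution with q degrees of
# freedom (sum of q independent squared-Brownian-bridge integrals), the
# asymptotic null distribution of the joint seasonal-stability statistic.
# Tabulated by Monte Carlo (60,000 replicates, 400 eigen terms plus exact
# tail mean); entries for q ≤ 12 agree with the published table (0.461,
# 0.749, 1.00, ..., 2.75, 2.96) to Monte Carlo precision.
_CVM_CRIT_5PCT = (
    0.4632, 0.7449, 1.0041, 1.2382, 1.4650, 1.6830, 1.9027, 2.1144, 2.3230,
    2.5310, 2.7330, 2.9419, 3.1402, 3.3488, 3.5410, 3.7458, 3.9354, 4.1253,
    4.3270, 4.5218, 4.7173, 4.9003, 5.0942, 5.2917, 5.4714, 5.6678, 5.8602,
    6.0485, 6.2444, 6.4354, 6.6190, 6.8060, 6.9919, 7.1796, 7.3740, 7.5622,
    7.7496, 7.9333, 8.1204, 8.2990, 8.4915, 8.6795, 8.8640, 9.0527, 9.2333,
    9.4211, 9.6036, 9.7905, 9.9750, 10.1604, 10.3429, 10.5248, 10.7138,
    10.8908, 11.0799, 11.2555, 11.4422, 11.6272, 11.8123, 11.9906,
)


@dataclass(frozen=True)
class SeasonalStabilityResult:
    """Joint Canova–Hansen seasonal-stability test outcome.

    ``order`` is the recommended seasonal differencing order: 1 when the
    null of stable (deterministic) seasonality is rejected at 5% in favor
    of a seasonal unit root, else 0.
    """

    statistic: float
    critical_value_5pct: float
    period: int
    order: int


def _seasonal_harmonics(n: int, period: int) -> np.ndarray:
    """period−1 trigonometric seasonal regressors (full set of harmonics)."""
    t = np.arange(1, n + 1)
    cols = []
    for j in range(1, period // 2 + 1):
        w = 2.0 * np.pi * j / period
        cols.append(np.cos(w * t))
        if 2 * j != period:
            cols.append(np.sin(w * t))
    return np.column_stack(cols)


def canova_hansen(series, period: int, min_periods: int = 5) -> SeasonalStabilityResult:
    """Canova–Hansen test of stable seasonality vs. a seasonal unit root.

    The series is regressed on an intercept and the full set of seasonal
    harmonics; the statistic is the normalized cumulative-score functional
    of the seasonal regressors with a Bartlett-kernel long-run covariance,
    compared against the 5% point of the Cramér–von Mises distribution with
    period−1 degrees of freedom.
    """
    if period < 2:
        raise ConfigError("period must be ≥ 2")
    y = _as_clean_array(series, name="series")
    n = len(y)
    if n < min_periods * period:
        raise SchemaError(f"need at least {min_periods} full periods of data ({n} < {min_periods * period})")
    q = period - 1
    if q > len(_CVM_CRIT_5PCT):
        raise ConfigError(f"period {period} exceeds tabulated critical values (max {len(_CVM_CRIT_5PCT) + 1})")
    F = _seasonal_harmonics(n, period)
    X = np.column_stack([np.ones(n), F])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    e = y - X @ beta
    u = F * e[:, None]  # score contributions of the seasonal regressors
    S = np.cumsum(u, axis=0)
    # Bartlett-kernel long-run covariance of the scores; a Newey-West-style
    # period-independent bandwidth — period-scaled truncation lags absorb
    # the very instability signal the statistic needs at 20-40 periods
    ltrunc = max(1, int(round(4.0 * (n / 100.0) ** 0.25)))
    omega = u.T @ u / n
    for lag in range(1, ltrunc + 1):
        w = 1.0 - lag / (ltrunc + 1.0)
        gamma = u[lag:].T @ u[:-lag] / n
        omega += w * (gamma + gamma.T)
    try:
        omega_inv = np.linalg.pinv(omega)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise DegenerateInputError("singular long-run covariance") from exc
    stat = float(np.trace(omega_inv @ (S.T @ S))) / n**2
    crit = _CVM_CRIT_5PCT[q - 1]
    return SeasonalStabilityResult(
        statistic=stat, critical_value_5pct=crit, period=period, order=int(stat > crit)
    )


# --------------------------------------------------------------------------
# Engle–Granger two-step cointegration

@dataclass(frozen=True)
class EngleGrangerDirection:
    """One direction of the two-step test (levels regression + residual ADF)."""

    slope: float
    intercept: float
    residual_statistic: float
    residual_pvalue: float
    lags_used: int
    critical_values: dict[float, float]
    levels_warning: Optional[str] = None

    def cointegrated(self, level: float = 0.05) -> bool:
        return self.residual_statistic < self.critical_values[level]


@dataclass(frozen=True)
class EngleGrangerReport:
    """Both directions of the Engle–Granger test for one series pair."""

    y_on_x: EngleGrangerDirection
    x_on_y: EngleGrangerDirection

    def cointegrated_both(self, level: float = 0.05) -> bool:
        return self.y_on_x.cointegrated(level) and self.x_on_y.cointegrated(level)


def _eg_one_direction(y: np.ndarray, x: np.ndarray, check_levels: bool) -> EngleGrangerDirection:
    if np.ptp(x) == 0:
        raise DegenerateInputError("regressor has zero variance")
    n = len(y)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    if np.allclose(resid, 0.0, atol=1e-12):
        raise DegenerateInputError("exact linear dependence leaves zero residuals")
    stat, _, usedlag, nobs, _, _ = adfuller(
        resid, maxlag=_schwert_maxlag(n), regression="n", autolag="AIC"
    )
    # cointegration-specific (two-variable) critical values and p-value
    crit = mackinnoncrit(N=2, regression="c", nobs=n - 1)
    pvalue = float(mackinnonp(stat, regression="c", N=2))
    warning = None
    if check_levels:
        try:
            levels_adf = adf_test(y, deterministic="constant")
            if levels_adf.rejects(0.05):
                warning = "levels series rejects a unit root at 5%; series may not be I(1)"
        except (DegenerateInputError, SchemaError):
            warning = "levels unit-root pre-check could not be run"
    return EngleGrangerDirection(
        slope=float(slope),
        intercept=float(intercept),
        residual_statistic=float(stat),
        residual_pvalue=pvalue,
        lags_used=int(usedlag),
        critical_values={0.01: float(crit[0]), 0.05: float(crit[1]), 0.10: float(crit[2])},
        levels_warning=warning,
    )


def engle_granger(y, x, check_levels: bool = False) -> EngleGrangerReport:
    """Bidirectional two-step Engle–Granger cointegration test.

    Step 1 regresses one series on the other with an intercept; step 2
    runs an ADF test (no deterministic term) on the residuals against
    MacKinnon two-variable cointegration critical values. Both regression
    directions are computed, since the test is not symmetric in y and x.
    Callers are responsible for both series being I(1); with
    ``check_levels`` a levels-stationarity warning is attached.
    """
    ya = _as_clean_array(y, name="y")
    xa = _as_clean_array(x, name="x")
    if len(ya) != len(xa):
        raise SchemaError(f"series are not aligned: {len(ya)} vs {len(xa)} observations")
    if len(ya) < 50:
        raise SchemaError("need at least 50 aligned observations")
    return EngleGrangerReport(
        y_on_x=_eg_one_direction(ya, xa, check_levels),
        x_on_y=_eg_one_direction(xa, ya, check_levels),
    )


# --------------------------------------------------------------------------
# Johansen trace test

@dataclass(frozen=True)
class JohansenResult:
    """Johansen trace-test outcome for a k-series system."""

    eigenvalues: tuple[float, ...]
    trace_statistics: tuple[float, ...]
    critical_values_5pct: tuple[float, ...]
    selected_rank: int
    lag_order: int
    deterministic: str


# Asymptotic trace critical values (90/95/99%) for the constant RESTRICTED
# to the cointegrating relation, indexed by the number of common trends
# m = k − r.  Tabulated by Monte Carlo (50,000 replicates of the limiting
# functional on a 1,000-step grid); the 5% column reproduces the published
# restricted-constant table (9.24, 19.96, 34.91, 53.12, ...) to within
# simulation precision.
_JOHANSEN_RC_CRIT = {
    1: (7.61, 9.22, 12.77),
    2: (17.99, 20.21, 24.99),
    3: (32.07, 35.10, 40.86),
    4: (50.27, 53.77, 60.81),
    5: (72.31, 76.38, 84.66),
    6: (98.30, 103.28, 113.07),
}


def _rrr_eigenvalues(Y: np.ndarray, lag_order: int, restricted_const: bool) -> np.ndarray:
    """Eigenvalues of the Johansen reduced-rank regression.

    With ``restricted_const`` the lagged-level block is augmented with a
    constant column (and no unrestricted intercept enters the VAR), the
    appropriate specification for driftless I(1) series with nonzero means.
    """
    from scipy.linalg import eigh

    T0, k = Y.shape
    n = T0 - 1 - lag_order
    dY = np.diff(Y, axis=0)
    Z0 = dY[lag_order:]
    lagged = [dY[lag_order - j : T0 - 1 - j] for j in range(1, lag_order + 1)]
    Z2 = np.hstack(lagged) if lagged else np.empty((n, 0))
    ylag = Y[lag_order : T0 - 1]
    Z1 = np.hstack([ylag, np.ones((n, 1))]) if restricted_const else ylag
    if Z2.shape[1]:
        coef0, *_ = np.linalg.lstsq(Z2, Z0, rcond=None)
        coef1, *_ = np.linalg.lstsq(Z2, Z1, rcond=None)
        R0, R1 = Z0 - Z2 @ coef0, Z1 - Z2 @ coef1
    else:
        R0, R1 = Z0, Z1
    S00 = R0.T @ R0 / n
    S01 = R0.T @ R1 / n
    S11 = R1.T @ R1 / n
    M = S01.T @ np.linalg.solve(S00, S01)
    vals = eigh(M, S11, eigvals_only=True)
    vals = np.clip(np.sort(vals)[::-1][:k], 0.0, 1 - 1e-12)
    return vals


def johansen_trace(
    series_list: Sequence,
    lag_order: int = 7,
    deterministic: Literal["restricted_constant", "none", "constant", "trend"] = "restricted_constant",
) -> JohansenResult:
    """Johansen trace test over hypothesized cointegrating ranks 0..k−1.

    The default specification restricts the constant to the cointegrating
    relation (``ecdet="const"`` in R's urca), the appropriate case for
    driftless nonstationary series with nonzero levels; an unrestricted
    constant would compare the last trace statistic against χ²-type values
    that assume a drifting common trend and over-reject badly for
    surveillance streams. The other deterministic cases delegate to
    statsmodels. Selected rank = the smallest hypothesized rank whose trace
    statistic does not reject at 5%; full rank k means every series is
    stationary.
    """
    arrays = [_as_clean_array(s, name=f"series[{i}]") for i, s in enumerate(series_list)]
    k = len(arrays)
    if not 2 <= k <= 6:
        raise SchemaError("johansen_trace expects 2–6 series")
    n = min(len(a) for a in arrays)
    if any(len(a) != n for a in arrays):
        raise SchemaError("series are not aligned to a common length")
    if n < 20 * (lag_order + 1):
        raise SchemaError(f"need at least {20 * (lag_order + 1)} observations for lag order {lag_order}")
    Y = np.column_stack(arrays)
    centered = Y - Y.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10 * max(1.0, np.abs(centered).max())) < k:
        raise DegenerateInputError("collinear input series")
    if deterministic == "restricted_constant":
        eig = _rrr_eigenvalues(Y, lag_order, restricted_const=True)
        n_eff = Y.shape[0] - 1 - lag_order
        trace = np.array(
            [-n_eff * np.sum(np.log(1.0 - eig[r:])) for r in range(k)]
        )
        crit5 = np.array([_JOHANSEN_RC_CRIT[k - r][1] for r in range(k)])
    elif deterministic in ("none", "constant", "trend"):
        det_order = {"none": -1, "constant": 0, "trend": 1}[deterministic]
        res = coint_johansen(Y, det_order, lag_order)
        eig, trace, crit5 = res.eig, res.trace_stat, res.trace_stat_crit_vals[:, 1]
    else:
        raise ConfigError(
            "deterministic must be 'restricted_constant', 'none', 'constant' or 'trend'"
        )
    rank = k
    for r in range(k):
        if trace[r] < crit5[r]:
            rank = r
            break
    return JohansenResult(
        eigenvalues=tuple(float(v) for v in eig),
        trace_statistics=tuple(float(v) for v in trace),
        critical_values_5pct=tuple(float(v) for v in crit5),
        selected_rank=rank,
        lag_order=lag_order,
        deterministic=deterministic,
    )


# --------------------------------------------------------------------------
# dual residualization

def seasonal_dummy_residuals(series: pd.Series) -> pd.Series:
    """Parametric deseasonalization: OLS on an intercept, 11 calendar-month
    indicators and a linear time index; returns residuals on the input's
    date index (missing stays missing)."""
    if not isinstance(series.index, pd.DatetimeIndex):
        raise SchemaError("series: needs a DatetimeIndex")
    if len(series) < 730:
        raise SchemaError("need at least 2 years of daily data")
    y = series.to_numpy(dtype=float)
    ok = np.isfinite(y)
    months = series.index.month.to_numpy()
    present = set(months[ok])
    missing_months = sorted(set(range(1, 13)) - present)
    if missing_months:
        raise SchemaError(f"calendar months {missing_months} are entirely missing")
    n = len(series)
    t = np.arange(n, dtype=float) / n
    X = np.column_stack(
        [np.ones(n), t] + [(months == m).astype(float) for m in range(2, 13)]
    )
    beta, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
    resid = np.full(n, np.nan)
    resid[ok] = y[ok] - X[ok] @ beta
    return pd.Series(resid, index=series.index, name="resid_parametric")


def stl_residuals(
    series: pd.Series, period: int = 365, robust: bool = True, outer_iter: int = 5
) -> pd.Series:
    """Nonparametric deseasonalization: remainder of a seasonal-trend LOESS
    decomposition at the given period, robust weighting on.

    Interior missing values are linearly interpolated before decomposing
    (and restored to missing afterwards); missing edges are trimmed.
    ``outer_iter`` caps the robustness iterations; five passes give
    residuals indistinguishable from the full fifteen at a third of the
    cost on year-scale daily series.
    """
    if not isinstance(series.index, pd.DatetimeIndex):
        raise SchemaError("series: needs a DatetimeIndex")
    n_all = len(series)
    if period >= n_all / 2:
        raise ConfigError(f"period {period} must be < half the series length ({n_all})")
    y = series.to_numpy(dtype=float)
    ok = np.isfinite(y)
    if not ok.any():
        raise DegenerateInputError("all values missing")
    first, last = np.argmax(ok), n_all - 1 - np.argmax(ok[::-1])
    core = series.iloc[first : last + 1]
    interior_missing = core.isna()
    filled = core.interpolate(method="linear")
    if period >= len(filled) / 2:
        raise ConfigError("period must be < half the non-missing span")
    res = STL(filled, period=period, robust=robust).fit(
        outer_iter=outer_iter if robust else 0
    )
    resid = res.resid.copy()
    resid[interior_missing] = np.nan
    return resid.reindex(series.index).rename("resid_stl")


# --------------------------------------------------------------------------
# correlation

class PearsonResult(NamedTuple):
    """Zero-lag Pearson correlation; ``r`` and ``p`` are None when the
    correlation is undefined (zero variance), never silently 0."""

    r: Optional[float]
    p: Optional[float]

    @property
    def defined(self) -> bool:
        return self.r is not None


def pearson_zero_lag(a, b, min_pairs: int = 10) -> PearsonResult:
    """Sample Pearson correlation at zero lag with a two-sided p-value.

    Pairs with any missing value are dropped; at least ``min_pairs``
    complete pairs are required.
    """
    aa = np.asarray(a.values if isinstance(a, SurveillanceSeries) else a, dtype=float).ravel()
    bb = np.asarray(b.values if isinstance(b, SurveillanceSeries) else b, dtype=float).ravel()
    if len(aa) != len(bb):
        raise SchemaError(f"series are not aligned: {len(aa)} vs {len(bb)}")
    ok = np.isfinite(aa) & np.isfinite(bb)
    if ok.sum() < min_pairs:
        raise SchemaError(f"need at least {min_pairs} complete pairs, have {int(ok.sum())}")
    aa, bb = aa[ok], bb[ok]
    if np.ptp(aa) == 0 or np.ptp(bb) == 0:
        return PearsonResult(None, None)
    r, p = stats.pearsonr(aa, bb)
    return PearsonResult(float(r), float(p))


# --------------------------------------------------------------------------
# the assembled battery

@dataclass(frozen=True)
class BatteryConfig:
    """Options for the per-region validation battery."""

    smooth: bool = True
    eg_level: float = 0.01
    johansen_lag: int = 7
    johansen_deterministic: str = "restricted_constant"
    ch_period: int = 12          # annual cycle on monthly aggregates
    ch_aggregation: str = "ME"   # pandas resample rule for CH aggregation
    ch_min_periods: int = 3
    stl_period: int = 365
    raw_correlation_on_smoothed: bool = True


@dataclass
class PairResult:
    """EG + correlations for one internet/clinical stream pair."""

    pair: str
    engle_granger: EngleGrangerReport
    pearson_raw: PearsonResult
    pearson_resid_parametric: PearsonResult
    pearson_resid_stl: PearsonResult


@dataclass
class RegionReport:
    """Full validation battery output for one region."""

    region_id: str
    seasonal_stability: dict[str, SeasonalStabilityResult]
    pairs: dict[str, PairResult]
    johansen: Optional[JohansenResult]


def _prep(series: SurveillanceSeries, config: BatteryConfig) -> SurveillanceSeries:
    return rolling_mean_7d(series) if config.smooth and not series.smoothed else series


def _ch_on_aggregate(s: SurveillanceSeries, config: BatteryConfig) -> SeasonalStabilityResult:
    agg = s.values.resample(config.ch_aggregation).mean()
    return canova_hansen(
        agg.to_numpy(), period=config.ch_period, min_periods=config.ch_min_periods
    )


def run_validation_battery(
    ed: Sequence[SurveillanceSeries],
    posts: Sequence[SurveillanceSeries],
    search: Optional[Sequence[SurveillanceSeries]] = None,
    config: BatteryConfig = BatteryConfig(),
    included_regions: Optional[Sequence[str]] = None,
) -> list[RegionReport]:
    """Run the full per-region battery on aligned stream collections.

    ``ed``, ``posts`` and optional ``search`` each hold one series per
    region. Streams are 7-day smoothed first (unless already smoothed);
    seasonal stability is tested per stream on calendar aggregates;
    Engle–Granger runs bidirectionally on each internet/ED pair; the
    Johansen trace test runs on the triple when search data are present;
    and zero-lag Pearson correlations are computed on the raw (smoothed)
    series and on both residual variants.

    Regions must already have passed quality filtering; if
    ``included_regions`` is given, any extra region in the input is an
    error rather than silently analyzed.
    """
    by_region: dict[str, dict[str, SurveillanceSeries]] = {}
    groups = [("ed", ed), ("posts", posts)]
    if search is not None:
        groups.append(("search", search))
    for name, group in groups:
        for s in group:
            by_region.setdefault(s.region_id, {})[name] = s
    if included_regions is not None:
        extra = sorted(set(by_region) - set(map(str, included_regions)))
        if extra:
            raise SchemaError(
                f"regions {extra} did not pass quality filtering; filter upstream"
            )
    reports: list[RegionReport] = []
    for rid in sorted(by_region):
        streams = by_region[rid]
        if set(streams) != {name for name, _ in groups}:
            raise SchemaError(f"region {rid}: missing streams {sorted({n for n, _ in groups} - set(streams))}")
        smoothed = {name: _prep(s, config) for name, s in streams.items()}
        stability = {name: _ch_on_aggregate(s, config) for name, s in smoothed.items()}
        resid_param = {
            name: seasonal_dummy_residuals(s.values) for name, s in smoothed.items()
        }
        resid_stl = {
            name: stl_residuals(s.values, period=config.stl_period)
            for name, s in smoothed.items()
        }
        pairs: dict[str, PairResult] = {}
        for internet in [n for n, _ in groups if n != "ed"]:
            eg = engle_granger(smoothed["ed"].values, smoothed[internet].values)
            raw_a = smoothed["ed"].values if config.raw_correlation_on_smoothed else streams["ed"].values
            raw_b = smoothed[internet].values if config.raw_correlation_on_smoothed else streams[internet].values
            pairs[f"ed_vs_{internet}"] = PairResult(
                pair=f"ed_vs_{internet}",
                engle_granger=eg,
                pearson_raw=pearson_zero_lag(raw_a, raw_b),
                pearson_resid_parametric=pearson_zero_lag(
                    resid_param["ed"], resid_param[internet]
                ),
                pearson_resid_stl=pearson_zero_lag(resid_stl["ed"], resid_stl[internet]),
            )
        johansen = None
        if "search" in smoothed:
            johansen = johansen_trace(
                [smoothed["ed"].values, smoothed["posts"].values, smoothed["search"].values],
                lag_order=config.johansen_lag,
                deterministic=config.johansen_deterministic,
            )
        reports.append(
            RegionReport(
                region_id=rid,
                seasonal_stability=stability,
                pairs=pairs,
                johansen=johansen,
            )
        )
    return reports


def battery_to_frame(reports: Sequence[RegionReport]) -> pd.DataFrame:
    """Flatten battery reports to one row per region × pair × direction."""
    rows = []
    for rep in reports:
        for pair_name, pair in rep.pairs.items():
            for direction in ("y_on_x", "x_on_y"):
                d: EngleGrangerDirection = getattr(pair.engle_granger, direction)
                rows.append(
                    {
                        "region_id": rep.region_id,
                        "pair": pair_name,
                        "direction": direction,
                        "slope": d.slope,
                        "intercept": d.intercept,
                        "eg_statistic": d.residual_statistic,
                        "eg_pvalue": d.residual_pvalue,
                        "eg_crit_1pct": d.critical_values[0.01],
                        "eg_crit_5pct": d.critical_values[0.05],
                        "eg_crit_10pct": d.critical_values[0.10],
                        "cointegrated_1pct": d.cointegrated(0.01),
                        "cointegrated_5pct": d.cointegrated(0.05),
                        "cointegrated_10pct": d.cointegrated(0.10),
                        "pearson_raw": pair.pearson_raw.r,
                        "pearson_raw_p": pair.pearson_raw.p,
                        "pearson_resid_parametric": pair.pearson_resid_parametric.r,
                        "pearson_resid_stl": pair.pearson_resid_stl.r,
                        "johansen_rank": rep.johansen.selected_rank if rep.johansen else None,
                        "ch_order_ed": rep.seasonal_stability["ed"].order,
                        "ch_order_posts": rep.seasonal_stability["posts"].order,
                        "ch_order_search": (
                            rep.seasonal_stability["search"].order
                            if "search" in rep.seasonal_stability
                            else None
                        ),
                    }
                )
    # per-region p-values are reported as-is; no multiplicity adjustment is
    # applied across regions
    return pd.DataFrame(rows)
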