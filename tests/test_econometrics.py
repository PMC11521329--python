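"""Unit-root, seasonal-stability, cointegration and correlation machinery."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.tsa.stattools import coint
from statsmodels.tsa.vector_ar.vecm import coint_johansen

from aerosurv.base import ConfigError, DegenerateInputError, SchemaError
from aerosurv.econometrics import (
    _rrr_eigenvalues,
    adf_test,
    battery_to_frame,
    canova_hansen,
    engle_granger,
    johansen_trace,
    pearson_zero_lag,
    run_validation_battery,
    seasonal_dummy_residuals,
    stl_residuals,
)
from aerosurv.series import post_probability


def _ar1(rng, n, phi=0.7, sd=1.0):
    x = np.zeros(n)
    e = rng.normal(0, sd, n)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + e[i]
    return x


class TestAdf:
    def test_stationary_series_rejected_often(self):
        rng = np.random.default_rng(0)
        rej = sum(adf_test(rng.normal(0, 1, 500)).rejects(0.05) for _ in range(100))
        assert rej >= 90

    def test_random_walk_rarely_rejected(self):
        rng = np.random.default_rng(1)
        rej = sum(
            adf_test(np.cumsum(rng.normal(0, 1, 500))).rejects(0.05) for _ in range(100)
        )
        assert rej <= 10

    def test_trend_stationary_with_trend_term(self):
        rng = np.random.default_rng(2)
        y = 0.05 * np.arange(500) + rng.normal(0, 0.1, 500)
        assert adf_test(y, deterministic="constant+trend").rejects(0.05)

    def test_rejection_flags_are_nested(self):
        rng = np.random.default_rng(3)
        r = adf_test(_ar1(rng, 300, phi=0.9))
        assert (
            r.critical_values[0.01] < r.critical_values[0.05] < r.critical_values[0.10]
        )
        if r.rejects(0.01):
            assert r.rejects(0.05) and r.rejects(0.10)

    def test_constant_series_rejected_as_degenerate(self):
        with pytest.raises(DegenerateInputError):
            adf_test(np.ones(100))

    def test_interior_missing_rejected(self):
        x = np.random.default_rng(4).normal(0, 1, 100)
        x[50] = np.nan
        with pytest.raises(SchemaError):
            adf_test(x)


class TestCanovaHansen:
    def test_stable_seasonality_order_zero(self):
        rng = np.random.default_rng(5)
        t = np.arange(240)
        pat = np.sin(2 * np.pi * t / 12) + 0.5 * np.cos(4 * np.pi * t / 12)
        hits = sum(
            canova_hansen(pat + rng.normal(0, 1, 240), 12).order == 0 for _ in range(50)
        )
        assert hits >= 45

    def test_seasonal_random_walk_order_one(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(50):
            levels = np.column_stack(
                [np.cumsum(rng.normal(0, 1, 20)) for _ in range(12)]
            )
            y = levels.ravel() + rng.normal(0, 1, 240)
            hits += canova_hansen(y, 12).order == 1
        assert hits >= 40

    def test_white_noise_order_zero(self):
        rng = np.random.default_rng(7)
        assert canova_hansen(rng.normal(0, 1, 240), 12).order == 0

    def test_period_and_length_validation(self):
        with pytest.raises(ConfigError):
            canova_hansen(np.arange(100.0), period=1)
        with pytest.raises(SchemaError):
            canova_hansen(np.random.default_rng(0).normal(0, 1, 40), period=12)


class TestEngleGranger:
    def test_cointegrated_pair_slope_and_rejection(self):
        rng = np.random.default_rng(8)
        x = np.cumsum(rng.normal(0, 1, 1460))
        y = 2.0 * x + _ar1(rng, 1460)
        rep = engle_granger(y, x)
        assert rep.cointegrated_both(0.01)
        assert 1.8 <= rep.y_on_x.slope <= 2.2

    def test_statistic_matches_statsmodels_coint(self):
        rng = np.random.default_rng(9)
        x = np.cumsum(rng.normal(0, 1, 400))
        y = 1.5 * x + rng.normal(0, 1, 400)
        rep = engle_granger(y, x)
        stat, pvalue, crit = coint(y, x, trend="c", autolag="aic")
        assert rep.y_on_x.residual_statistic == pytest.approx(stat, abs=1e-6)
        assert rep.y_on_x.residual_pvalue == pytest.approx(pvalue, abs=1e-8)
        assert rep.y_on_x.critical_values[0.05] == pytest.approx(crit[1], abs=0.05)

    def test_exact_linear_dependence_degenerate(self):
        x = np.cumsum(np.random.default_rng(10).normal(0, 1, 200))
        with pytest.raises(DegenerateInputError):
            engle_granger(x, x)

    def test_zero_variance_regressor(self):
        y = np.random.default_rng(11).normal(0, 1, 200)
        with pytest.raises(DegenerateInputError):
            engle_granger(y, np.ones(200))

    def test_short_series_rejected(self):
        with pytest.raises(SchemaError):
            engle_granger(np.arange(30.0), np.arange(30.0) * 2 + 1)


class TestJohansen:
    def test_eigenvalues_match_statsmodels_without_deterministic(self):
        rng = np.random.default_rng(12)
        Y = np.column_stack([np.cumsum(rng.normal(0, 1, 400)) for _ in range(3)])
        mine = _rrr_eigenvalues(Y, lag_order=2, restricted_const=False)
        ref = np.sort(coint_johansen(Y, -1, 2).eig)[::-1]
        assert np.allclose(mine, ref, atol=1e-8)

    def test_restricted_constant_critical_values_match_published_table(self):
        r = johansen_trace(
            [np.cumsum(np.random.default_rng(0).normal(0, 1, 300)) + 5,
             np.cumsum(np.random.default_rng(1).normal(0, 1, 300))],
            lag_order=2,
        )
        # published 5% restricted-constant trace values: 19.96 (m=2), 9.24 (m=1)
        assert r.critical_values_5pct[0] == pytest.approx(19.96, abs=0.5)
        assert r.critical_values_5pct[1] == pytest.approx(9.24, abs=0.3)

    def test_stationary_triple_full_rank(self):
        rng = np.random.default_rng(13)
        hits = sum(
            johansen_trace([_ar1(rng, 1460) for _ in range(3)], lag_order=7).selected_rank == 3
            for _ in range(20)
        )
        assert hits >= 16

    def test_collinear_inputs_rejected(self):
        rng = np.random.default_rng(14)
        x = np.cumsum(rng.normal(0, 1, 400))
        with pytest.raises(DegenerateInputError):
            johansen_trace([x, 2 * x, x + rng.normal(0, 1, 400)], lag_order=2)

    def test_too_short_for_lag_order(self):
        rng = np.random.default_rng(15)
        with pytest.raises(SchemaError):
            johansen_trace([rng.normal(0, 1, 100), rng.normal(0, 1, 100)], lag_order=7)


class TestResidualization:
    def _daily(self, values, start="2016-01-01"):
        idx = pd.date_range(start, periods=len(values), freq="D")
        return pd.Series(np.asarray(values, dtype=float), index=idx)

    def test_month_step_signal_fully_absorbed(self):
        idx = pd.date_range("2016-01-01", periods=1461, freq="D")
        y = pd.Series(idx.month.astype(float) * 3.0, index=idx)
        resid = seasonal_dummy_residuals(y)
        assert resid.abs().max() < 1e-9

    def test_within_month_residual_means_vanish(self):
        rng = np.random.default_rng(16)
        y = self._daily(rng.normal(0, 1, 1461))
        resid = seasonal_dummy_residuals(y)
        by_month = resid.groupby(resid.index.month).mean()
        # orthogonality holds jointly with the trend regressor, so
        # per-month means are near but not exactly zero
        assert by_month.abs().max() < 1e-2

    def test_residual_variance_recovers_noise_level(self):
        rng = np.random.default_rng(17)
        idx = pd.date_range("2016-01-01", periods=1460, freq="D")
        y = pd.Series(
            idx.month / 2.0 + 0.002 * np.arange(1460) + rng.normal(0, 1, 1460), index=idx
        )
        assert seasonal_dummy_residuals(y).var() == pytest.approx(1.0, rel=0.1)

    def test_stl_recovers_smooth_components(self):
        rng = np.random.default_rng(18)
        t = np.arange(1460)
        y = self._daily(
            np.sin(2 * np.pi * t / 365.25) + 0.001 * t + rng.normal(0, 0.05, 1460)
        )
        resid = stl_residuals(y, period=365)
        assert resid.std() < 0.15
        assert abs(resid.mean()) < 0.05
        assert adf_test(resid).rejects(0.05)

    def test_stl_period_validation(self):
        y = self._daily(np.random.default_rng(19).normal(0, 1, 400))
        with pytest.raises(ConfigError):
            stl_residuals(y, period=365)

    def test_interior_missing_interpolated_and_restored(self):
        rng = np.random.default_rng(20)
        t = np.arange(1460)
        vals = np.sin(2 * np.pi * t / 365.25) + rng.normal(0, 0.05, 1460)
        vals[700:705] = np.nan
        resid = stl_residuals(self._daily(vals), period=365)
        assert resid.iloc[700:705].isna().all()
        assert resid.iloc[:700].notna().all()


class TestPearson:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([1, 2, 3] * 4, [2, 4, 6] * 4, 1.0),
            ([1, 2, 3] * 4, [6, 4, 2] * 4, -1.0),
        ],
    )
    def test_perfect_correlation(self, a, b, expected):
        assert pearson_zero_lag(a, b, min_pairs=3).r == pytest.approx(expected)

    def test_small_example_exact(self):
        r = pearson_zero_lag([1, 2, 3, 4], [1, 3, 2, 4], min_pairs=4)
        assert r.r == pytest.approx(0.8)

    def test_matches_direct_product_moment_formula(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            n = rng.integers(10, 40)
            a, b = rng.normal(0, 1, n), rng.normal(0, 1, n)
            r = pearson_zero_lag(a, b).r
            am, bm = a - a.mean(), b - b.mean()
            direct = (am @ bm) / np.sqrt((am @ am) * (bm @ bm))
            assert r == pytest.approx(direct, abs=1e-12)

    def test_missing_pairs_dropped(self):
        a = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10, np.nan, 12.0])
        b = np.arange(12.0)
        b[2] = np.nan
        assert pearson_zero_lag(a, b).r == pytest.approx(1.0)

    def test_zero_variance_undefined(self):
        res = pearson_zero_lag(np.ones(20), np.arange(20.0))
        assert res.r is None and res.p is None and not res.defined


@pytest.fixture(scope="module")
def coupled_region():
    from aerosurv.synthetic import SyntheticConfig, generate_latent, generate_streams

    cfg = SyntheticConfig(seed=1, n_regions=1, populations=(1_500_000,))
    streams = generate_streams(generate_latent(cfg), cfg)
    by = {s.stream: s for s in streams}
    prob = post_probability(by["allergy_posts"], by["total_posts"])
    return by["ed_count"], prob, by["search_probability"]


class TestBattery:
    def test_report_structure_and_strong_coupling(self, coupled_region):
        ed, prob, search = coupled_region
        (rep,) = run_validation_battery([ed], [prob], [search])
        pair = rep.pairs["ed_vs_posts"]
        assert pair.engle_granger.cointegrated_both(0.01)
        assert pair.pearson_resid_parametric.r > 0.5
        assert pair.pearson_resid_stl.r > 0.5
        assert rep.johansen is not None
        frame = battery_to_frame([rep])
        assert len(frame) == 4  # 2 pairs x 2 directions
        assert set(frame["direction"]) == {"y_on_x", "x_on_y"}

    def test_unfiltered_region_rejected(self, coupled_region):
        ed, prob, _ = coupled_region
        with pytest.raises(SchemaError):
            run_validation_battery([ed], [prob], included_regions=["somewhere_else"])

    def test_missing_stream_rejected(self, coupled_region):
        ed, _, _ = coupled_region
        with pytest.raises(SchemaError):
            run_validation_battery([ed], [])
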