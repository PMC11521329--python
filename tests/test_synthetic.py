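"""Generative model: determinism, component structure, and the statistical
properties downstream stages rely on (shared trend, contamination rate,
count conservation, null behavior)."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from aerosurv.base import ConfigError
from aerosurv.econometrics import engle_granger, johansen_trace, pearson_zero_lag
from aerosurv.geo import assign_posts
from aerosurv.series import aggregate_daily, post_probability, rolling_mean_7d
from aerosurv.synthetic import (
    SeasonalPeak,
    SyntheticConfig,
    generate_latent,
    generate_posts,
    generate_regions,
    generate_streams,
    null_config,
    resample_series_replicates,
)
from aerosurv.text import keyword_match, TermList


class TestConfigValidation:
    def test_weekly_pattern_must_average_one(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(weekly_pattern=(1.0,) * 6 + (1.5,))
        with pytest.raises(ConfigError):
            SyntheticConfig(weekly_pattern=(1.0,) * 6)

    def test_negative_rates_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(baseline_ed_rate=-1.0)
        with pytest.raises(ConfigError):
            SyntheticConfig(trend_sd=-0.1)

    def test_nonpositive_peak_width_rejected(self):
        with pytest.raises(ConfigError):
            SeasonalPeak(100, 1.0, 0.0)


class TestRegions:
    def test_four_regions_two_dmas(self):
        cfg = SyntheticConfig(n_regions=4, regions_per_dma=2)
        regions = generate_regions(cfg)
        assert len(regions) == 4
        groups = regions.groupby("dma_id")["region_id"].apply(list).to_dict()
        ids = cfg.region_ids()
        assert groups == {"d00": ids[:2], "d01": ids[2:]}

    def test_single_region(self):
        regions = generate_regions(SyntheticConfig(n_regions=1))
        assert len(regions) == 1 and regions["dma_id"].nunique() == 1

    def test_rectangles_do_not_overlap(self):
        regions = generate_regions(SyntheticConfig(n_regions=6))
        for i in range(len(regions)):
            for j in range(i + 1, len(regions)):
                inter = regions["geometry"].iloc[i].intersection(regions["geometry"].iloc[j])
                assert inter.area == 0.0

    def test_deterministic(self):
        cfg = SyntheticConfig(n_regions=5, seed=9)
        r1, r2 = generate_regions(cfg), generate_regions(cfg)
        pd.testing.assert_frame_equal(r1.drop(columns="geometry"), r2.drop(columns="geometry"))
        assert all(a.equals(b) for a, b in zip(r1["geometry"], r2["geometry"]))

    def test_nonpositive_population_rejected(self):
        with pytest.raises(ConfigError):
            generate_regions(SyntheticConfig(n_regions=2, populations=(0, 100)))


class TestLatent:
    def test_noise_free_peak_at_configured_day(self):
        cfg = SyntheticConfig(
            n_regions=1,
            trend_sd=0.0,
            anomaly_sd=0.0,
            seasonal_peaks=((SeasonalPeak(100, 1.0, 10.0),),),
        )
        (ls,) = generate_latent(cfg)
        peak_days = ls.dates[np.argsort(ls.values)[-4:]].dayofyear
        assert all(abs(int(d) - 100) <= 1 for d in peak_days)

    def test_trend_increment_variance_matches_generative_law(self):
        cfg = SyntheticConfig(n_regions=1, n_days=10_001, trend_sd=0.5, anomaly_sd=0.0)
        (ls,) = generate_latent(cfg)
        increments = np.diff(ls.trend)
        assert np.var(increments) == pytest.approx(0.25, rel=0.05)

    def test_shared_trend_identical_across_regions(self):
        cfg = SyntheticConfig(
            n_regions=2,
            shared_trend_across_regions=True,
            seasonal_peaks=((SeasonalPeak(90, 1, 20),),) * 2,
        )
        a, b = generate_latent(cfg)
        assert np.array_equal(a.trend, b.trend)
        assert np.array_equal(a.seasonal, b.seasonal)

    def test_same_seed_identical(self):
        cfg = SyntheticConfig(n_regions=2, seed=5)
        a = generate_latent(cfg)
        b = generate_latent(cfg)
        for x, y in zip(a, b):
            assert np.array_equal(x.values, y.values)


class TestStreams:
    def test_zero_population_zero_counts(self):
        cfg = SyntheticConfig(n_regions=1, populations=(0,), n_days=60)
        streams = generate_streams(generate_latent(cfg), cfg)
        for s in streams:
            if s.stream in ("ed_count", "total_posts", "allergy_posts"):
                assert s.values.sum() == 0

    def test_counts_conservation(self, small_config, small_streams):
        by = {(s.region_id, s.stream): s for s in small_streams}
        for rid in small_config.region_ids():
            assert (
                by[(rid, "allergy_posts")].values.sum()
                <= by[(rid, "total_posts")].values.sum()
            )
            assert (by[(rid, "allergy_posts")].values <= by[(rid, "total_posts")].values).all()

    def test_nan_latent_rejected(self, small_config):
        latent = generate_latent(small_config)
        latent[0].values[5] = np.nan
        with pytest.raises(ConfigError):
            generate_streams(latent, small_config)

    def test_determinism(self, small_config, small_streams):
        again = generate_streams(generate_latent(small_config), small_config)
        for s1, s2 in zip(small_streams, again):
            assert s1.values.equals(s2.values)

    def test_zero_coupling_streams_uncorrelated(self):
        """With all couplings zero the streams share only the weekly
        pattern; seasonally-adjusted pairwise correlations vanish."""
        rs = []
        for seed in range(30):
            cfg = SyntheticConfig(
                seed=seed, n_regions=1, n_days=731, populations=(1_000_000,),
                coupling_ed=0.0, coupling_posts=0.0, coupling_search=0.0,
            )
            streams = generate_streams(generate_latent(cfg), cfg)
            by = {s.stream: s for s in streams}
            sm = {
                k: rolling_mean_7d(by[k]).values.dropna()
                for k in ("ed_count", "allergy_posts", "search_probability")
            }
            rs.append(pearson_zero_lag(sm["ed_count"], sm["allergy_posts"]).r)
            rs.append(pearson_zero_lag(sm["ed_count"], sm["search_probability"]).r)
        assert abs(np.mean(rs)) < 0.05

    def test_engle_granger_size_on_null_config(self):
        """Zero couplings + independent per-stream walks: the EG test's
        empirical type-I error at nominal 5% stays near nominal
        (500 replicates)."""
        rej = 0
        for seed in range(500):
            cfg = null_config(seed=seed, n_regions=1, populations=(3_000_000,))
            streams = generate_streams(generate_latent(cfg), cfg)
            by = {s.stream: s for s in streams}
            prob = post_probability(by["allergy_posts"], by["total_posts"])
            eg = engle_granger(
                rolling_mean_7d(by["ed_count"]).values, rolling_mean_7d(prob).values
            )
            rej += eg.y_on_x.cointegrated(0.05)
        assert 0.02 <= rej / 500 <= 0.09

    def test_johansen_rank_two_by_construction(self):
        """One shared walk drives all three streams, so the triple has
        cointegrating rank 2 (50 replicates)."""
        hits = 0
        for seed in range(50):
            cfg = SyntheticConfig(seed=seed, n_regions=1, populations=(1_500_000,))
            streams = generate_streams(generate_latent(cfg), cfg)
            by = {s.stream: s for s in streams}
            prob = post_probability(by["allergy_posts"], by["total_posts"])
            vals = [
                rolling_mean_7d(s).values.dropna()
                for s in (by["ed_count"], prob, by["search_probability"])
            ]
            hits += johansen_trace(vals, lag_order=7).selected_rank == 2
        assert hits >= 45


class TestPosts:
    def test_every_relevant_post_contains_a_keyword(self, small_posts, small_config):
        terms = TermList(terms=small_config.keywords)
        assert all(
            keyword_match(p.text, terms) for p in small_posts if p.label == "relevant"
        )

    def test_contamination_rate(self):
        cfg = SyntheticConfig(
            n_regions=1, n_days=731, populations=(2_500_000,), contamination=0.2, seed=11
        )
        posts = generate_posts(generate_latent(cfg), cfg)
        assert len(posts) > 10_000
        frac_irr = sum(p.label == "irrelevant" for p in posts) / len(posts)
        assert frac_irr == pytest.approx(0.2, abs=0.02)

    def test_same_seed_identical_posts(self, small_config, small_posts):
        again = generate_posts(generate_latent(small_config), small_config)
        assert [(p.post_id, p.timestamp, p.bbox, p.text, p.label) for p in again] == [
            (p.post_id, p.timestamp, p.bbox, p.text, p.label) for p in small_posts
        ]

    def test_empty_keywords_rejected(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, keywords=())
        with pytest.raises(ConfigError):
            generate_posts(generate_latent(cfg), cfg)

    def test_aggregated_relevant_posts_recover_stream_exactly(
        self, small_config, small_posts, small_streams
    ):
        """aggregate_daily ∘ generate_posts equals the allergy-post count
        stream draw for draw (same seed, no discards)."""
        regions = generate_regions(small_config)
        relevant = [p for p in small_posts if p.label == "relevant"]
        assigned, log = assign_posts(relevant, regions)
        assert log.n_unassigned == 0
        series, _ = aggregate_daily(
            assigned,
            list(regions["region_id"]),
            small_config.start_date,
            small_config.dates()[-1].date(),
        )
        by = {(s.region_id, s.stream): s for s in small_streams}
        for s in series:
            expected = by[(s.region_id, "allergy_posts")]
            assert np.array_equal(s.values.to_numpy(), expected.values.to_numpy())


class TestReplicates:
    def test_zero_noise_identity(self, small_streams):
        src = next(s for s in small_streams if s.stream == "search_probability")
        reps = resample_series_replicates(src, 3, noise_sd=0.0, seed=0)
        for r in reps:
            assert np.array_equal(r.values.to_numpy(), src.values.to_numpy())

    def test_replicate_mean_near_input(self, small_streams):
        src = next(s for s in small_streams if s.stream == "search_probability")
        reps = resample_series_replicates(src, 100, noise_sd=0.02, seed=1)
        stacked = np.vstack([r.values.to_numpy() for r in reps])
        mid = (src.values.to_numpy() > 0.1) & (src.values.to_numpy() < 0.9)
        err = np.abs(stacked.mean(axis=0) - src.values.to_numpy())[mid]
        assert (err <= 3 * 0.02 / 10).mean() > 0.99

    def test_reproducible(self, small_streams):
        src = next(s for s in small_streams if s.stream == "search_probability")
        (a,) = resample_series_replicates(src, 1, noise_sd=0.05, seed=42)
        (b,) = resample_series_replicates(src, 1, noise_sd=0.05, seed=42)
        assert np.array_equal(a.values.to_numpy(), b.values.to_numpy())

    def test_negative_noise_rejected(self, small_streams):
        with pytest.raises(ConfigError):
            resample_series_replicates(small_streams[0], 2, noise_sd=-0.1, seed=0)
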