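"""End-to-end orchestration: simulate → filter → aggregate → QC → validate → map.

A pipeline run is driven by one :class:`PipelineConfig` (YAML-loadable) and
one seed, writes every intermediate product as a text file into the run
directory, and records a manifest (config hash, seed, library versions,
per-stage record counts) so that rerunning the same config and seed
reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from .base import AerosurvError, ConfigError, SchemaError
from .econometrics import BatteryConfig, battery_to_frame, run_validation_battery
from .geo import assign_posts
from .intensity import SeasonWindows, compute_intensity
from .series import (
    QualityThresholds,
    aggregate_daily,
    exclude_date_range,
    post_probability,
    quality_filter,
)
from .synthetic import (
    SyntheticConfig,
    generate_latent,
    generate_posts,
    generate_regions,
    generate_streams,
)
from .text import (
    DEFAULT_TERMS,
    TermList,
    evaluate_classifier,
    filter_posts,
    stratified_split,
    train_classifier,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Everything a reproducible end-to-end run needs."""

    out_dir: Path
    seed: int = 0
    simulate: Optional[SyntheticConfig] = None
    regions_path: Optional[Path] = None
    posts_path: Optional[Path] = None
    series_path: Optional[Path] = None
    terms: TermList = DEFAULT_TERMS
    thresholds: QualityThresholds = QualityThresholds()
    windows: SeasonWindows = SeasonWindows()
    battery: BatteryConfig = BatteryConfig()
    exclude_ranges: tuple[tuple[dt.date, dt.date], ...] = ()
    classifier_test_fraction: float = 0.3

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.simulate is None:
            for name in ("regions_path", "posts_path", "series_path"):
                if getattr(self, name) is None:
                    raise ConfigError(
                        f"{name} is required when no simulation stage is configured"
                    )


def load_config(path: str | Path, out_dir: Optional[str | Path] = None,
                seed: Optional[int] = None) -> PipelineConfig:
    """Load a PipelineConfig from YAML; CLI-supplied out_dir/seed override."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = None
    if "simulate" in raw and raw["simulate"] is not None:
        sim_raw = dict(raw["simulate"])
        if "start_date" in sim_raw and isinstance(sim_raw["start_date"], str):
            sim_raw["start_date"] = dt.date.fromisoformat(sim_raw["start_date"])
        for tup_key in ("weekly_pattern", "populations", "keywords", "trend_scales"):
            if tup_key in sim_raw and sim_raw[tup_key] is not None:
                sim_raw[tup_key] = tuple(sim_raw[tup_key])
        sim = SyntheticConfig(**sim_raw)
    terms = DEFAULT_TERMS
    if "terms" in raw and raw["terms"] is not None:
        terms = TermList(
            terms=tuple(raw["terms"].get("terms", ())),
            hashtags=tuple(raw["terms"].get("hashtags", ())),
        )
    thresholds = QualityThresholds(**raw.get("thresholds", {}))
    battery = BatteryConfig(**raw.get("battery", {}))
    excl = []
    for rng in raw.get("exclude_ranges", []) or []:
        lo, hi = rng
        excl.append((dt.date.fromisoformat(str(lo)), dt.date.fromisoformat(str(hi))))
    return PipelineConfig(
        out_dir=Path(out_dir if out_dir is not None else raw.get("out_dir", "run")),
        seed=int(seed if seed is not None else raw.get("seed", 0)),
        simulate=sim,
        regions_path=Path(raw["regions_path"]) if raw.get("regions_path") else None,
        posts_path=Path(raw["posts_path"]) if raw.get("posts_path") else None,
        series_path=Path(raw["series_path"]) if raw.get("series_path") else None,
        terms=terms,
        thresholds=thresholds,
        battery=battery,
        exclude_ranges=tuple(excl),
        classifier_test_fraction=float(raw.get("classifier_test_fraction", 0.3)),
    )


def _config_hash(config: PipelineConfig) -> str:
    def default(obj):
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, (dt.date, dt.datetime)):
            return obj.isoformat()
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        return repr(obj)

    payload = dataclasses.asdict(config)
    payload.pop("out_dir", None)  # where outputs land is not a parameter
    blob = json.dumps(payload, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _versions() -> dict[str, str]:
    import scipy
    import shapely
    import sklearn
    import statsmodels

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
        "sklearn": sklearn.__version__,
        "shapely": shapely.__version__,
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Any stage failure raises with the stage name attached; counts of
    records seen so far are already persisted in ``stages.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    def record(stage: str, **counts) -> None:
        stages.append({"stage": stage, **counts})
        (out / "stages.json").write_text(json.dumps(stages, indent=1, sort_keys=True) + "\n")
        logger.info("stage %s: %s", stage, counts)

    def fail(stage: str, exc: Exception) -> AerosurvError:
        return AerosurvError(
            f"stage {stage!r} failed after {len(stages)} completed stage(s): {exc}"
        )

    # ---- simulate (optional) -----------------------------------------
    try:
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate, seed=config.seed)
            regions = generate_regions(sim)
            latent = generate_latent(sim)
            streams = generate_streams(latent, sim)
            posts = generate_posts(latent, sim)
            aio.write_regions_geojson(regions, out / "regions.geojson")
            aio.write_posts_jsonl(posts, out / "posts.jsonl")
            aio.write_series_csv(streams, out / "streams.csv")
            record("simulate", regions=len(regions), posts=len(posts), series=len(streams))
        else:
            regions = aio.read_regions_geojson(config.regions_path)
            posts = aio.read_posts_jsonl(config.posts_path)
            streams = aio.read_series_csv(config.series_path)
            record("load", regions=len(regions), posts=len(posts), series=len(streams))
    except AerosurvError as exc:
        raise fail("simulate/load", exc) from exc

    by_key = {(s.region_id, s.stream): s for s in streams}

    # ---- filter-posts ------------------------------------------------
    try:
        labeled = [p for p in posts if p.label is not None]
        train, test = stratified_split(
            labeled, test_fraction=config.classifier_test_fraction, seed=config.seed
        )
        clf = train_classifier(train, seed=config.seed)
        metrics = evaluate_classifier(
            clf.classify_batch([p.text for p in test]), [p.label for p in test]
        )
        kept, flog = filter_posts(posts, config.terms, clf)
        (out / "classifier_metrics.json").write_text(
            json.dumps(
                {
                    "accuracy": metrics.accuracy,
                    "precision": metrics.precision,
                    "recall": metrics.recall,
                    "tp": metrics.tp,
                    "fp": metrics.fp,
                    "fn": metrics.fn,
                    "tn": metrics.tn,
                    "n_train": len(train),
                    "n_test": len(test),
                },
                indent=1,
                sort_keys=True,
            )
            + "\n"
        )
        record(
            "filter-posts",
            input=flog.n_input,
            keyword_pass=flog.n_keyword_pass,
            relevant=flog.n_classified_relevant,
        )
    except AerosurvError as exc:
        raise fail("filter-posts", exc) from exc

    # ---- aggregate ---------------------------------------------------
    try:
        assigned, alog = assign_posts(kept, regions)
        dates = sorted({d for s in streams for d in (s.dates.min(), s.dates.max())})
        start, end = dates[0].date(), dates[-1].date()
        allergy_series, agg_log = aggregate_daily(
            assigned, list(regions["region_id"]), start, end, stream="allergy_posts"
        )
        prob_series = []
        for s in allergy_series:
            total = by_key.get((s.region_id, "total_posts"))
            if total is None:
                raise SchemaError(f"region {s.region_id}: total_posts stream missing")
            prob_series.append(post_probability(s, total))
        aio.write_series_csv(allergy_series + prob_series, out / "observed.csv")
        record(
            "aggregate",
            assigned=alog.n_assigned,
            unassigned=alog.n_unassigned,
            binned=agg_log.n_binned,
        )
    except AerosurvError as exc:
        raise fail("aggregate", exc) from exc

    # ---- qc ----------------------------------------------------------
    try:
        summaries = []
        for _, row in regions.iterrows():
            rid = str(row["region_id"])
            ed = by_key.get((rid, "ed_count"))
            alg = next(s for s in allergy_series if s.region_id == rid)
            if ed is None:
                raise SchemaError(f"region {rid}: ed_count stream missing")
            summaries.append(
                {
                    "region_id": rid,
                    "population": int(row["population"]),
                    "total_ed": float(ed.values.sum(skipna=True)),
                    "total_posts": float(alg.values.sum(skipna=True)),
                }
            )
        included, qc_report = quality_filter(pd.DataFrame(summaries), config.thresholds)
        qc_report.to_csv(out / "qc.csv", index=False)
        record("qc", regions=len(summaries), included=len(included))
        if not included:
            raise SchemaError("no region passes the quality thresholds")
    except AerosurvError as exc:
        raise fail("qc", exc) from exc

    # ---- validate ----------------------------------------------------
    try:
        def prep(stream_key: str, series_list=None):
            sel = []
            for rid in included:
                s = (
                    next((x for x in series_list if x.region_id == rid), None)
                    if series_list is not None
                    else by_key.get((rid, stream_key))
                )
                if s is None:
                    raise SchemaError(f"region {rid}: stream {stream_key} missing")
                if config.exclude_ranges:
                    s = exclude_date_range(s, config.exclude_ranges)
                sel.append(s)
            return sel

        ed_in = prep("ed_count")
        posts_in = prep("post_probability", prob_series)
        search_in = (
            prep("search_probability")
            if any(k[1] == "search_probability" for k in by_key)
            else None
        )
        reports = run_validation_battery(
            ed_in, posts_in, search_in, config.battery, included_regions=included
        )
        report_frame = battery_to_frame(reports)
        report_frame.to_csv(out / "report.csv", index=False)
        record("validate", regions=len(reports), rows=len(report_frame))
    except AerosurvError as exc:
        raise fail("validate", exc) from exc

    # ---- map-intensity -----------------------------------------------
    try:
        prob_included = [s for s in prob_series if s.region_id in included]
        result = compute_intensity(prob_included, config.windows, regions=regions)
        result.to_frame().to_csv(out / "intensity.csv", index=False)
        result.peak_dates.to_csv(out / "peaks.csv", index=False)
        weekly = result.weekly.copy()
        weekly.columns = [f"{y}-W{w:02d}" for y, w in weekly.columns]
        weekly.rename_axis("region_id").to_csv(out / "weekly.csv")
        record("map-intensity", regions=len(prob_included))
    except AerosurvError as exc:
        raise fail("map-intensity", exc) from exc

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": _versions(),
        "stages": stages,
        "thresholds": dataclasses.asdict(config.thresholds),
        "battery": dataclasses.asdict(config.battery),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return out
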