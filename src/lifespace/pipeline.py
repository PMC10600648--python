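"""End-to-end orchestration: validate -> metrics -> clean -> summarize -> model.

A run reads the three input files, writes every intermediate table plus a
results JSON into a run directory, and records a manifest (configuration,
package version, seeds, input checksums) so rerunning the same manifest
reproduces the outputs bit-identically.  No home is silently lost: every
home in the metadata ends up either analyzed or dropped-with-reason in the
accounting section of the results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, cleaning, cohort_models, lctm, metrics_core, sensor_io, summaries

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a pipeline run; defaults are the analysis constants."""

    events_path: str = ""
    metadata_path: str = ""
    reports_path: str = ""
    out_dir: str = "lifespace_run"

    alpha: float = 0.05
    outlier_sd: float = 5.0
    burn_in_days: int = 14
    longitudinal_min_days: int = 180
    covid_cutoffs: dict = field(
        default_factory=lambda: {k: str(v.date()) for k, v in cleaning.COVID_CUTOFFS.items()}
    )
    min_tooh_episode_s: int = 0

    run_trend_models: bool = True
    run_lctm: bool = False  # the trajectory grid is the expensive stage
    lctm_outcomes: tuple = ("tooh", "ilsa")
    lctm_families: str = "ABCDEFGHI"
    lctm_kmax: int = 6
    lctm_restarts: int = 20
    seed: int = 17

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _lm_to_dict(res: cohort_models.LinearModelResult) -> dict:
    out = {
        "outcome": res.outcome,
        "n_homes": res.n_homes,
        "stratified": res.stratified,
        "interaction_p": res.interaction_p,
        "dropped_terms": res.dropped_terms,
        "coefficients": res.to_frame().round(6).to_dict(orient="index"),
    }
    if res.strata:
        out["strata"] = {k: _lm_to_dict(v) for k, v in res.strata.items()}
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the results dict it also writes."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cutoffs = {k: pd.Timestamp(v) for k, v in config.covid_cutoffs.items()}

    events = sensor_io.read_events(config.events_path)
    metadata = sensor_io.read_home_metadata(config.metadata_path)
    reports = sensor_io.read_weekly_reports(config.reports_path)
    accounting: dict[str, str] = {}

    daily = metrics_core.daily_metrics_table(
        events, metadata, min_episode_seconds=config.min_tooh_episode_s
    )
    daily.to_csv(out_dir / "daily_metrics.csv", index=False)

    outages = cleaning.detect_sensor_outages(events)
    flagged = cleaning.flag_days(
        daily, reports, metadata, outages,
        burn_in_days=config.burn_in_days, covid_cutoffs=cutoffs,
    )
    flagged.to_csv(out_dir / "flagged_days.csv", index=False)

    results: dict = {"config": asdict(config), "models": {}, "trend_models": {}}

    four_week = cleaning.eligibility_window(flagged, "four_week")
    for home_id in metadata.index:
        if home_id not in set(four_week["home_id"]):
            accounting[home_id] = "dropped: under 4 weeks of eligible data"
        else:
            accounting[home_id] = "analyzed"
    summary = summaries.daily_summary(four_week)
    summary.to_csv(out_dir / "daily_summaries.csv")

    min_homes_for_models = len(cohort_models.FULL_TERMS) + 2
    for outcome in metrics_core.ALL_OUTCOMES:
        values, removed = cleaning.remove_outliers(summary[outcome], config.outlier_sd)
        if len(values) < min_homes_for_models:
            results["models"][outcome] = {
                "skipped": f"only {len(values)} homes; need {min_homes_for_models}"
            }
            continue
        res = cohort_models.fit_daily_lm(
            values.to_frame(outcome), metadata, outcome, alpha=config.alpha
        )
        entry = _lm_to_dict(res)
        entry["outliers_removed"] = list(map(str, removed))
        results["models"][outcome] = entry

    if config.run_trend_models:
        longitudinal = cleaning.eligibility_window(
            flagged, "longitudinal", longitudinal_min_days=config.longitudinal_min_days
        )
        trends = summaries.home_trend(longitudinal, min_days=config.longitudinal_min_days)
        trends.to_csv(out_dir / "home_trends.csv", index=False)
        if not trends.empty:
            for outcome in metrics_core.ALL_OUTCOMES:
                for stat in ("slope", "variability"):
                    try:
                        res = cohort_models.fit_trend_lm(
                            trends, metadata, outcome, stat, alpha=config.alpha
                        )
                    except (np.linalg.LinAlgError, KeyError) as err:
                        logger.warning("trend model %s/%s failed: %s", outcome, stat, err)
                        continue
                    results["trend_models"][f"{outcome}_{stat}"] = _lm_to_dict(res)

    if config.run_lctm:
        hi = {
            h: metrics_core.compute_home_intervals(
                grp, h, min_episode_seconds=config.min_tooh_episode_s
            )
            for h, grp in events.groupby("home_id")
        }
        hourly = summaries.hourly_summary(hi, four_week, outcomes=config.lctm_outcomes)
        hourly.to_csv(out_dir / "hourly_profiles.csv")
        results["lctm"] = {}
        for outcome in config.lctm_outcomes:
            profiles = hourly.xs(outcome, level="outcome")
            fit, ranking = lctm.select_model(
                profiles,
                k_range=range(1, config.lctm_kmax + 1),
                families=config.lctm_families,
                seed=config.seed,
                n_restarts=config.lctm_restarts,
            )
            ranking.to_csv(out_dir / f"lctm_ranking_{outcome}.csv", index=False)
            assignments = lctm.assign_classes(fit)
            membership = cohort_models.fit_class_membership(
                assignments["class"], metadata, outcome
            )
            results["lctm"][outcome] = {
                "family": fit.spec.family,
                "n_classes": fit.spec.n_classes,
                "bic": fit.bic,
                "class_sizes": fit.class_sizes.tolist(),
                "reference_class": int(membership.reference_class),
                "separation": membership.separation,
                "small_classes": [int(c) for c in membership.small_classes],
            }

    results["accounting"] = accounting
    counts = pd.Series(accounting).str.startswith("analyzed").value_counts()
    results["n_homes"] = {
        "input": int(len(metadata)),
        "analyzed": int(counts.get(True, 0)),
        "dropped": int(counts.get(False, 0)),
    }
    assert results["n_homes"]["analyzed"] + results["n_homes"]["dropped"] == len(metadata)

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "inputs": {
            name: _sha256(p)
            for name, p in (
                ("events", config.events_path),
                ("metadata", config.metadata_path),
                ("reports", config.reports_path),
            )
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out_dir / "results.json").write_text(json.dumps(results, indent=2, sort_keys=True, default=str))
    return results
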