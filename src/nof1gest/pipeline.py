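"""Pipeline orchestration: configuration, cohort I/O, staged analysis runs.

The four analysis stages run in order — preprocess, trajectory fits and
aggregates, subgroup heterogeneity, event analysis — each writing its
outputs into a run directory along with a machine-readable ``summary.json``
(byte-identical across reruns with the same inputs, config and seed) and an
INFO-level log recording every exclusion count and skipped test reason.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import events as ev
from . import heterogeneity as het
from . import preprocess as pre
from . import trajectories as traj
from .errors import ConfigurationError, InsufficientDataError, SchemaError
from .simulate import CohortConfig, FeatureConfig, generate_cohort, write_cohort

__all__ = ["PipelineConfig", "read_cohort", "run_pipeline", "STAGES"]

STAGES = ("preprocess", "fit", "heterogeneity", "events")

logger = logging.getLogger("nof1gest")

OBS_COLUMNS = ("participant_id", "feature", "day_rel_delivery", "value")
PART_COLUMNS = ("participant_id", "delivery_date")
EVENT_COLUMNS = ("participant_id", "label", "event_class", "day_rel_delivery")


@dataclass
class PipelineConfig:
    """Everything a run needs; together with the input tables it fully
    determines the outputs."""

    out_dir: str = "runs/latest"
    # Input CSVs; when None, a cohort is simulated from ``simulate``.
    participants_csv: str | None = None
    observations_csv: str | None = None
    events_csv: str | None = None
    simulate: CohortConfig | None = None
    primary_feature: str = "hrv"
    # preprocessing
    quantiles: tuple[float, float] = (0.05, 0.95)
    calibration_subset_size: int = 100
    max_missing_fraction: float = 0.6
    min_points: int = 30
    # trajectory models
    week_range: tuple[int, int] = (10, 40)
    min_weekly_points: int = 5
    concordance_tolerance_weeks: float = 0.5
    # heterogeneity
    grouping_labels: list[str] | None = None
    kde_bandwidth: float | None = None
    age_threshold: float = 30.0
    # events
    p_threshold: float = 0.05
    per_participant_samples: int = 1
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.quantiles[0] < self.quantiles[1] <= 1):
            raise ConfigurationError("quantiles must satisfy 0 <= lo < hi <= 1")
        if self.week_range[0] >= self.week_range[1]:
            raise ConfigurationError("week_range must be increasing")
        if not (0 < self.max_missing_fraction < 1):
            raise ConfigurationError("max_missing_fraction must lie in (0, 1)")
        if self.min_points < 1:
            raise ConfigurationError("min_points must be >= 1")
        if self.min_weekly_points < 3:
            raise ConfigurationError("min_weekly_points must be >= 3")
        if not (0 < self.p_threshold < 1):
            raise ConfigurationError("p_threshold must lie in (0, 1)")
        if self.simulate is not None:
            self.simulate.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        for key in ("quantiles", "week_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        if sim is not None:
            feats = sim.pop("features", None)
            if feats is not None:
                sim["features"] = tuple(
                    FeatureConfig(**{**f, "clip_bounds":
                                     tuple(f["clip_bounds"])
                                     if f.get("clip_bounds") else None})
                    for f in feats)
            for key in ("fatigue_bounds", "delivery_window",
                        "preterm_length_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            cfg.simulate = CohortConfig(**sim)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return json.loads(json.dumps(dataclasses.asdict(self), default=str))


def _require_columns(df: pd.DataFrame, columns, name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} is missing required column(s): {missing}")


def read_cohort(participants_csv: str | Path,
                observations_csv: str | Path,
                events_csv: str | Path | None = None
                ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read the documented CSV layouts into typed tables.

    Missing observation values (empty fields) become NaN. Non-numeric
    observation values raise :class:`SchemaError` listing the offending
    1-based file line numbers. An empty or absent events file yields an
    empty event table, not an error.
    """
    participants = pd.read_csv(participants_csv, dtype={"participant_id": str})
    _require_columns(participants, PART_COLUMNS, "participants table")

    observations = pd.read_csv(observations_csv,
                               dtype={"participant_id": str, "feature": str})
    _require_columns(observations, OBS_COLUMNS, "observations table")
    raw = observations["value"]
    numeric = pd.to_numeric(raw, errors="coerce")
    bad = raw.notna() & numeric.isna()
    if bad.any():
        lines = (observations.index[bad] + 2).tolist()   # +1 header, +1 1-based
        raise SchemaError(
            f"non-numeric observation values at line(s) {lines[:20]}")
    observations = observations.assign(value=numeric)
    observations["day_rel_delivery"] = observations["day_rel_delivery"].astype(int)

    if events_csv is not None and Path(events_csv).exists():
        try:
            events = pd.read_csv(events_csv, dtype={"participant_id": str})
        except pd.errors.EmptyDataError:
            events = pd.DataFrame(columns=EVENT_COLUMNS)
        if len(events):
            _require_columns(events, EVENT_COLUMNS, "events table")
        else:
            events = pd.DataFrame(columns=EVENT_COLUMNS)
    else:
        events = pd.DataFrame(columns=EVENT_COLUMNS)
    return participants, observations, events


def _json_default(o):
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: PipelineConfig, last_stage: str = "events") -> dict:
    """Execute the staged analysis and write all outputs to ``out_dir``.

    ``last_stage`` truncates the run after a prefix of ``STAGES``. Returns
    the summary dict (also written as ``summary.json``). A stage failure
    raises ``RuntimeError`` naming the stage; outputs of completed stages
    are retained in the run directory.
    """
    config.validate()
    if last_stage not in STAGES:
        raise ConfigurationError(f"last_stage must be one of {STAGES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    summary: dict = {"config": config.to_dict(), "stages": {}}
    current = "preprocess"
    try:
        if config.participants_csv is not None:
            participants, observations, events_df = read_cohort(
                config.participants_csv, config.observations_csv,
                config.events_csv)
        else:
            sim = config.simulate or CohortConfig(seed=config.seed)
            cohort = generate_cohort(sim)
            write_cohort(cohort, out / "cohort")
            participants = cohort.participants
            observations = cohort.observations
            events_df = cohort.events
        logger.info("inputs: %d participants, %d observation rows, %d events",
                    len(participants), len(observations), len(events_df))

        stop = STAGES.index(last_stage)
        stage, aligned, weekly, kept = _stage_preprocess(
            config, out, participants, observations)
        summary["stages"]["preprocess"] = stage
        if stop >= 1:
            current = "fit"
            stage, fits_frame = _stage_fit(config, out, weekly)
            summary["stages"]["fit"] = stage
        if stop >= 2:
            current = "heterogeneity"
            summary["stages"]["heterogeneity"] = _stage_heterogeneity(
                config, out, fits_frame, participants, weekly)
        if stop >= 3:
            current = "events"
            summary["stages"]["events"] = _stage_events(
                config, out, aligned, events_df, kept)
    except Exception as err:
        logger.error("stage %s failed: %s", current, err)
        raise RuntimeError(f"pipeline stage {current!r} failed: {err}") from err
    finally:
        logger.removeHandler(handler)
        handler.close()

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_json_default)
        + "\n")
    return summary


def _stage_preprocess(config, out, participants, observations):
    obs = pre.remove_duplicates(observations)
    n_dups = obs.attrs["duplicate_rows"]
    aligned = pre.align_to_gestation(obs, participants)
    kept, report = pre.filter_participants(
        aligned, participants, config.primary_feature,
        config.max_missing_fraction, config.min_points)
    logger.info("exclusions: %s", report["reason"].value_counts().to_dict())
    aligned = aligned[aligned["participant_id"].isin(kept)].reset_index(drop=True)
    bounds = pre.estimate_outlier_bounds(
        aligned, config.calibration_subset_size, config.quantiles,
        seed=config.seed)
    n_before = int(aligned["value"].notna().sum())
    aligned = pre.apply_outlier_bounds(aligned, bounds)
    n_masked = n_before - int(aligned["value"].notna().sum())
    weekly = pre.weekly_average(aligned)

    aligned.to_csv(out / "cleaned.csv", index=False)
    report.to_csv(out / "exclusions.csv", index=False)
    (out / "bounds.json").write_text(json.dumps(
        {f: dataclasses.asdict(b) for f, b in bounds.items()},
        indent=2, sort_keys=True))
    stage = {
        "n_participants_kept": len(kept),
        "n_excluded": len(report),
        "exclusion_reasons": report["reason"].value_counts().to_dict(),
        "n_duplicate_rows_removed": n_dups,
        "n_outlier_values_masked": n_masked,
        "bounds": {f: [b.lower, b.upper] for f, b in bounds.items()},
    }
    return stage, aligned, weekly, kept


def _stage_fit(config, out, weekly):
    features = sorted(weekly["feature"].unique())
    all_fits: list[traj.QuadraticFit] = []
    stage: dict = {"features": {}}
    agg_frames = []
    for feat in features:
        fits, skips = traj.fit_cohort_quadratics(
            weekly, feat, config.week_range, config.min_weekly_points)
        for _, row in skips.iterrows():
            logger.info("fit skipped %s/%s: %s", row["participant_id"],
                        feat, row["reason"])
        all_fits.extend(fits)
        agg = traj.aggregate_weekly(weekly, feat, config.week_range)
        agg.insert(0, "feature", feat)
        agg_frames.append(agg)

        feat_summary: dict = {"n_fits": len(fits), "n_skipped": len(skips)}
        vertices = [f.vertex_week for f in fits if f.has_inflection]
        if len(vertices) >= 2:
            feat_summary["median_vertex_week"] = float(np.median(vertices))
            feat_summary["vertex_cv_percent"] = traj.coefficient_of_variation(
                vertices)
        try:
            agg_fit = traj.fit_quadratic(
                agg["gestational_week"], agg["mean"],
                participant_id="<aggregate>", feature=feat,
                week_range=config.week_range,
                min_points=config.min_weekly_points)
            if agg_fit.has_inflection and fits:
                conc = traj.inflection_concordance(
                    fits, agg_fit.vertex_week,
                    config.concordance_tolerance_weeks)
                feat_summary["aggregate_vertex_week"] = agg_fit.vertex_week
                feat_summary["concordance_fraction"] = conc.fraction
                feat_summary["concordance_counts"] = [conc.n_within,
                                                      conc.n_total]
        except (ValueError, InsufficientDataError) as exc:
            logger.info("aggregate fit for %s unavailable: %s", feat, exc)
        groups = [g["mean"].to_numpy()
                  for _, g in weekly[weekly["feature"] == feat]
                  .groupby("participant_id") if len(g) >= 2]
        if len(groups) >= 2:
            try:
                feat_summary["icc_weekly"] = traj.icc_oneway(groups)
            except ValueError:
                pass
        peaks, troughs = [], []
        for pid, g in weekly[weekly["feature"] == feat].groupby("participant_id"):
            if len(g) >= 3:
                e = traj.find_extrema(g["gestational_week"], g["mean"],
                                      pid, feat)
                peaks.append(e.peak_week)
                troughs.append(e.trough_week)
        if peaks:
            feat_summary["median_peak_week"] = float(np.median(peaks))
            feat_summary["median_trough_week"] = float(np.median(troughs))
        stage["features"][feat] = feat_summary

    fits_frame = traj.fits_to_frame(all_fits)
    fits_frame.to_csv(out / "fits.csv", index=False)
    pd.concat(agg_frames, ignore_index=True).to_csv(
        out / "aggregate.csv", index=False)
    return stage, fits_frame


def _stage_heterogeneity(config, out, fits_frame, participants, weekly):
    kde_cfg = (het.KDEConfig(bandwidth=config.kde_bandwidth)
               if config.kde_bandwidth else None)
    table, densities = het.subgroup_r2_comparison(
        fits_frame, participants, labels=config.grouping_labels,
        kde_config=kde_cfg)
    table.to_csv(out / "heterogeneity.csv", index=False)
    densities.to_csv(out / "densities.csv", index=False)
    stage: dict = {
        "n_comparisons": int((table["status"] == "ok").sum()),
        "n_insufficient": int((table["status"] == "insufficient").sum()),
        "n_significant_raw": int((table["p_raw"] < 0.05).sum()),
    }
    try:
        age = het.age_predictor_test(weekly, participants,
                                     config.primary_feature,
                                     config.age_threshold, config.week_range)
        stage["age_lr_test"] = {"lr": age.lr_statistic, "df": age.df,
                                "p": age.p_value}
    except ValueError as exc:
        logger.info("age LR test unavailable: %s", exc)
    return stage


def _stage_events(config, out, aligned, events_df, kept):
    events_df = events_df[events_df["participant_id"].isin(kept)]
    merged = ev.merge_overlapping_events(events_df)
    features = sorted(aligned["feature"].unique())
    tests: list[ev.EventWindowTest] = []
    for feat in features:
        obs = aligned[aligned["feature"] == feat]
        by_pid = {pid: g for pid, g in obs.groupby("participant_id")}
        for event in merged:
            series = by_pid.get(event.participant_id)
            if series is not None:
                tests.append(ev.event_window_test(series, event))
    tests_frame = ev.tests_to_frame(tests)
    tests_frame.to_csv(out / "event_tests.csv", index=False)
    for reason, count in tests_frame["skipped_reason"].value_counts().items():
        if reason:
            logger.info("event tests skipped (%s): %d", reason, count)

    scan_frames = []
    n_flagged = 0
    for feat in features:
        scan = ev.window_scan(aligned, events_df, feat)
        n_flagged += sum(r.high_variability for r in scan)
        scan_frames.append(pd.DataFrame([{
            "feature": feat, "window_index": r.window_index,
            "start_day": r.start_day, "end_day": r.end_day,
            "n_individuals": len(r.t_by_participant),
            "sd_t": r.sd_across_individuals, "threshold": r.threshold,
            "high_variability": r.high_variability, "status": r.status,
        } for r in scan]))
    pd.concat(scan_frames, ignore_index=True).to_csv(
        out / "window_scan.csv", index=False)

    primary_tests = [t for t in tests if t.feature == config.primary_feature]
    selected = ev.sample_qualifying_events(
        primary_tests, config.p_threshold, config.per_participant_samples,
        seed=config.seed)
    (out / "selections.json").write_text(json.dumps([{
        "participant_id": t.event.participant_id,
        "event_label": t.event.label,
        "event_day": t.event.day_rel_delivery,
        "feature": t.feature, "t": t.t_statistic, "p": t.p_value,
    } for t in selected], indent=2, sort_keys=True, default=_json_default))

    done = tests_frame[tests_frame["skipped_reason"] == ""]
    return {
        "n_events_raw": int(len(events_df)),
        "n_events_merged": len(merged),
        "n_tests": int(len(done)),
        "n_tests_skipped": int(len(tests_frame) - len(done)),
        "n_significant": int((done["p"] < config.p_threshold).sum()),
        "n_windows_flagged": n_flagged,
        "n_selected_case_studies": len(selected),
    }
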