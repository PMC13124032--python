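"""Synthetic perinatal wearable cohorts with known ground truth.

Each participant carries an individual quadratic gestational trend per
feature,

    value(week) = a * (week - vertex_week)**2 + s * (week - vertex_week) + c
                  + Gaussian noise,

with the vertex week, curvature ``a``, slope ``s`` and level ``c`` drawn from
population distributions. The trend is evaluated on the integer gestational
week grid (the resolution of the weekly-smoothed analysis); the daily noise
term carries all within-week variation. Adverse/severe events shift feature means on days
within +/-7 days of the event. Missingness is missing-completely-at-random.
The generator returns the true coefficients, vertex weeks, event days and
subgroup labels so that downstream estimators can be tested for parameter
recovery.

All randomness flows from a single integer seed through per-participant
sub-streams (``numpy.random.SeedSequence.spawn``), so regenerating the same
configuration is byte-identical and prefixes of a cohort are stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "FeatureConfig",
    "CohortConfig",
    "GroundTruth",
    "Cohort",
    "default_features",
    "generate_cohort",
    "inject_event_shift",
    "write_cohort",
]

#: Event label vocabulary and the event class each label reports under.
EVENT_VOCABULARY: dict[str, str] = {
    "infection": "adverse_event",
    "fever": "biweekly_symptom",
    "low energy": "daily_severe",
}

#: Days a single event influences on either side of its date.
EVENT_HALF_WINDOW = 7


@dataclass(frozen=True)
class FeatureConfig:
    """Population-level description of one wearable/self-report feature.

    ``baseline_mean``/``baseline_sd`` give the value at the trajectory vertex
    (feature units); ``curvature_*`` the quadratic coefficient (units/week^2);
    ``slope_*`` an optional linear term (units/week, default 0 so the vertex
    sits exactly at the drawn vertex week); ``noise_sd`` the i.i.d. daily
    noise; ``event_shift`` the additive mean shift (feature units) applied on
    days within +/-7 days of an event. ``clip_bounds`` clips generated values,
    used for the ordinal 1-7 fatigue scale.
    """

    name: str
    baseline_mean: float
    baseline_sd: float = 0.0
    slope_mean: float = 0.0
    slope_sd: float = 0.0
    curvature_mean: float = 0.0
    curvature_sd: float = 0.0
    noise_sd: float = 1.0
    event_shift: float = 0.0
    clip_bounds: tuple[float, float] | None = None


def default_features() -> tuple[FeatureConfig, ...]:
    """Default feature set: nighttime HRV (ms), deep sleep and awake time
    (minutes), and self-reported fatigue (continuous 1-7).

    HRV noise is ~15% of its quadratic range over weeks 10-40
    (0.03 * (33-10)^2 ~ 16 ms range, noise SD 2.4 ms).
    """
    return (
        FeatureConfig("hrv", baseline_mean=45.0, baseline_sd=6.0,
                      curvature_mean=0.03, curvature_sd=0.006,
                      noise_sd=2.4, event_shift=-5.0),
        FeatureConfig("deep_sleep", baseline_mean=85.0, baseline_sd=15.0,
                      curvature_mean=0.08, curvature_sd=0.02,
                      noise_sd=12.0, event_shift=-15.0),
        FeatureConfig("awake", baseline_mean=45.0, baseline_sd=12.0,
                      curvature_mean=0.06, curvature_sd=0.015,
                      noise_sd=10.0, event_shift=12.0),
        FeatureConfig("fatigue", baseline_mean=2.8, baseline_sd=0.6,
                      curvature_mean=0.006, curvature_sd=0.0015,
                      noise_sd=0.8, event_shift=1.0, clip_bounds=(1.0, 7.0)),
    )


def _default_subgroups() -> dict[str, float]:
    # Complication prevalences of an included cohort of 275:
    # preterm 37, GDM 42, preeclampsia 38, gest. hypertension 66,
    # postpartum hemorrhage 39, major depression 189.
    return {
        "preterm_birth": 37 / 275,
        "gestational_diabetes": 42 / 275,
        "preeclampsia": 38 / 275,
        "gestational_hypertension": 66 / 275,
        "postpartum_hemorrhage": 39 / 275,
        "major_depression": 189 / 275,
    }


@dataclass(frozen=True)
class CohortConfig:
    """Full description of a synthetic cohort; identical config + seed
    regenerate an identical cohort."""

    n_participants: int = 200
    features: tuple[FeatureConfig, ...] = field(default_factory=default_features)
    vertex_week_mean: float = 33.0
    vertex_week_sd: float = 3.0
    missing_rate: float = 0.2
    fatigue_bounds: tuple[float, float] = (1.0, 7.0)
    event_rate: float = 3.0
    subgroup_fractions: Mapping[str, float] = field(default_factory=_default_subgroups)
    delivery_window: tuple[str, str] = ("2021-01-01", "2022-05-31")
    gestational_length_days: int = 280
    preterm_length_range: tuple[int, int] = (210, 258)
    start_week: int = 10
    seed: int = 0

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming the offending field."""
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if not (0.0 <= self.missing_rate < 0.6):
            raise ConfigurationError("missing_rate must lie in [0, 0.6)")
        if self.event_rate < 0:
            raise ConfigurationError("event_rate must be >= 0")
        if self.vertex_week_sd < 0:
            raise ConfigurationError("vertex_week_sd must be >= 0")
        if not self.features:
            raise ConfigurationError("features must be non-empty")
        for f in self.features:
            for fld in ("baseline_sd", "slope_sd", "curvature_sd", "noise_sd"):
                if getattr(f, fld) < 0:
                    raise ConfigurationError(
                        f"features[{f.name!r}].{fld} must be >= 0")
        for label, frac in self.subgroup_fractions.items():
            if not (0.0 <= frac <= 1.0):
                raise ConfigurationError(
                    f"subgroup_fractions[{label!r}] must lie in [0, 1]")
        if not (self.fatigue_bounds[0] < self.fatigue_bounds[1]):
            raise ConfigurationError("fatigue_bounds must be increasing")
        lo, hi = self.preterm_length_range
        if not (140 <= lo <= hi <= self.gestational_length_days):
            raise ConfigurationError(
                "preterm_length_range must satisfy 140 <= lo <= hi <= term length")
        if not (0 < self.start_week * 7 < lo):
            raise ConfigurationError(
                "start_week must fall before the shortest gestation")


@dataclass
class GroundTruth:
    """True generating parameters, one record set per participant.

    ``coefficients`` holds one row per (participant, feature) with the
    expanded quadratic ``a*w^2 + b*w + c`` and its vertex ``-b/(2a)``;
    ``events`` one row per injected event day; ``subgroups`` the labels
    assigned to each participant; ``event_shifts`` the per-feature mean shift
    applied inside each event's +/-7-day window.
    """

    coefficients: pd.DataFrame
    events: pd.DataFrame
    subgroups: pd.DataFrame
    event_shifts: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "coefficients": self.coefficients.to_dict(orient="records"),
            "events": self.events.to_dict(orient="records"),
            "subgroups": self.subgroups.to_dict(orient="records"),
            "event_shifts": self.event_shifts,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


@dataclass
class Cohort:
    """A generated cohort: the three study tables plus ground truth."""

    participants: pd.DataFrame
    observations: pd.DataFrame
    events: pd.DataFrame
    ground_truth: GroundTruth


def _expand_coefficients(a: float, s: float, c0: float, vertex: float
                         ) -> tuple[float, float, float, float]:
    """Expand a*(w-v)^2 + s*(w-v) + c0 into a*w^2 + b*w + c and its vertex."""
    b = s - 2.0 * a * vertex
    c = a * vertex ** 2 - s * vertex + c0
    true_vertex = -b / (2.0 * a) if a != 0.0 else float("nan")
    return a, b, c, true_vertex


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a reproducible synthetic cohort.

    Returns a :class:`Cohort` with a participant table (one row per
    enrollee), long-format daily observations (rows kept for missing days
    with NaN values, mirroring an export where missing = empty field), an
    event table, and the :class:`GroundTruth`.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_participants)

    window_start = np.datetime64(config.delivery_window[0])
    window_end = np.datetime64(config.delivery_window[1])
    window_days = int((window_end - window_start) / np.timedelta64(1, "D"))
    if window_days < 0:
        raise ConfigurationError("delivery_window must be increasing")

    labels_sorted = sorted(config.subgroup_fractions)
    vocab = sorted(EVENT_VOCABULARY)

    part_rows: list[dict] = []
    obs_frames: list[pd.DataFrame] = []
    event_rows: list[dict] = []
    coef_rows: list[dict] = []
    truth_event_rows: list[dict] = []
    subgroup_rows: list[dict] = []

    width = max(4, len(str(config.n_participants)))
    for i in range(config.n_participants):
        rng = np.random.default_rng(children[i])
        pid = f"P{i + 1:0{width}d}"

        labels = [lab for lab in labels_sorted
                  if rng.random() < config.subgroup_fractions[lab]]
        preterm = "preterm_birth" in labels
        if preterm:
            lo, hi = config.preterm_length_range
            gest_len = int(rng.integers(lo, hi + 1))
        else:
            gest_len = config.gestational_length_days
        delivery = window_start + np.timedelta64(int(rng.integers(0, window_days + 1)), "D")
        due = delivery + np.timedelta64(config.gestational_length_days - gest_len, "D")
        age = round(float(np.clip(rng.normal(32.0, 4.5), 18.0, 45.0)), 1)
        bmi = round(float(np.clip(rng.normal(26.5, 5.0), 16.0, 50.0)), 1)
        vertex = float(rng.normal(config.vertex_week_mean, config.vertex_week_sd))

        gest_day = np.arange(config.start_week * 7, gest_len + 1)
        day_rel = gest_day - gest_len        # negative prenatal, 0 = delivery
        # trend evaluated on the integer-week grid the weekly analysis uses;
        # within-week variation is carried by the daily noise term
        week = np.floor(gest_day / 7.0)
        n_days = gest_day.size

        # Homogeneous per-day event process at expected event_rate per person.
        p_day = min(1.0, config.event_rate / n_days)
        event_days = day_rel[rng.random(n_days) < p_day]
        event_labels = [vocab[int(k)] for k in rng.integers(0, len(vocab), event_days.size)]

        for feat in config.features:
            c0 = float(rng.normal(feat.baseline_mean, feat.baseline_sd))
            a = float(rng.normal(feat.curvature_mean, feat.curvature_sd))
            s = float(rng.normal(feat.slope_mean, feat.slope_sd))
            values = (a * (week - vertex) ** 2 + s * (week - vertex) + c0
                      + rng.normal(0.0, feat.noise_sd, n_days))
            for ev_day in event_days:
                mask = np.abs(day_rel - ev_day) <= EVENT_HALF_WINDOW
                values[mask] += feat.event_shift
            clip = feat.clip_bounds
            if clip is None and feat.name == "fatigue":
                clip = config.fatigue_bounds
            if clip is not None:
                values = np.clip(values, clip[0], clip[1])
            if config.missing_rate > 0:
                values = np.where(rng.random(n_days) < config.missing_rate,
                                  np.nan, values)
            obs_frames.append(pd.DataFrame({
                "participant_id": pid,
                "feature": feat.name,
                "day_rel_delivery": day_rel,
                "value": values,
            }))
            ea, eb, ec, true_vertex = _expand_coefficients(a, s, c0, vertex)
            coef_rows.append({
                "participant_id": pid, "feature": feat.name,
                "a": ea, "b": eb, "c": ec, "vertex_week": true_vertex,
            })

        part_rows.append({
            "participant_id": pid,
            "delivery_date": str(delivery),
            "due_date": str(due),
            "age": age,
            "bmi": bmi,
            "complications": ";".join(labels),
        })
        for ev_day, lab in zip(event_days, event_labels):
            event_rows.append({
                "participant_id": pid,
                "label": lab,
                "event_class": EVENT_VOCABULARY[lab],
                "day_rel_delivery": int(ev_day),
            })
            truth_event_rows.append({
                "participant_id": pid,
                "day_rel_delivery": int(ev_day),
                "label": lab,
            })
        subgroup_rows.append({"participant_id": pid,
                              "labels": ";".join(labels),
                              "vertex_week": vertex,
                              "gestational_length_days": gest_len})

    participants = pd.DataFrame(part_rows)
    observations = pd.concat(obs_frames, ignore_index=True)
    event_cols = ["participant_id", "label", "event_class", "day_rel_delivery"]
    events = pd.DataFrame(event_rows, columns=event_cols)
    truth = GroundTruth(
        coefficients=pd.DataFrame(coef_rows),
        events=pd.DataFrame(truth_event_rows,
                            columns=["participant_id", "day_rel_delivery", "label"]),
        subgroups=pd.DataFrame(subgroup_rows),
        event_shifts={f.name: f.event_shift for f in config.features},
    )
    return Cohort(participants, observations, events, truth)


def inject_event_shift(series: pd.DataFrame, event_day: int, shift: float
                       ) -> pd.DataFrame:
    """Additively shift a single feature series on days within +/-7 days of
    ``event_day``; all other days are unchanged.

    ``series`` is a long-format frame for one (participant, feature) with
    ``day_rel_delivery`` and ``value`` columns. Raises ``ValueError`` when
    ``event_day`` falls outside the observed span.
    """
    days = series["day_rel_delivery"].to_numpy()
    if not (days.min() <= event_day <= days.max()):
        raise ValueError(
            f"event_day {event_day} outside observed span "
            f"[{days.min()}, {days.max()}]")
    out = series.copy()
    mask = np.abs(days - event_day) <= EVENT_HALF_WINDOW
    out.loc[mask, "value"] = out.loc[mask, "value"] + shift
    return out


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write participants.csv, observations.csv, events.csv and
    ground_truth.json; missing observation values become empty fields."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "participants": outdir / "participants.csv",
        "observations": outdir / "observations.csv",
        "events": outdir / "events.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    cohort.participants.to_csv(paths["participants"], index=False)
    cohort.observations.to_csv(paths["observations"], index=False)
    cohort.events.to_csv(paths["events"], index=False)
    cohort.ground_truth.to_json(paths["ground_truth"])
    return paths
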