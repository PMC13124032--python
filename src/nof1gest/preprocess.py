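"""Gestational alignment, inclusion filters, outlier masking, weekly smoothing.

Conventions:

* ``gestational_day = L + day_rel_delivery`` where ``L`` is the participant's
  gestational length in days, ``L = (delivery - due) + 280`` clipped to
  [140, 320] (280 when the due date is unknown); ``gestational_week =
  floor(gestational_day / 7)``.
* Inclusion filters run on the prenatal span (``day_rel_delivery <= 0``) of
  the feature under analysis; the missingness denominator is the day span
  from the participant's first to last non-missing observation, inclusive.
* Outlier bounds are per-feature 0.05/0.95 quantiles (linear-interpolation
  estimator) pooled over a seeded random subset of participants and applied
  uniformly to everyone; only values strictly outside the bounds are masked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OutlierBounds",
    "align_to_gestation",
    "filter_participants",
    "remove_duplicates",
    "estimate_outlier_bounds",
    "apply_outlier_bounds",
    "weekly_average",
]

REASON_MISSING_DELIVERY = "missing delivery information"
REASON_TOO_MISSING = "more than 60% missing data"
REASON_TOO_FEW = "fewer than 30 data points"

TERM_GESTATION_DAYS = 280
GESTATION_BOUNDS_DAYS = (140, 320)


@dataclass(frozen=True)
class OutlierBounds:
    """Per-feature quantile bounds calibrated on a participant subset."""

    feature: str
    lower: float
    upper: float
    calibration_subset_size: int

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")


def gestational_length_days(delivery_date, due_date) -> float:
    """Gestational length in days from delivery and (optional) due date."""
    if pd.isna(delivery_date):
        return float("nan")
    if pd.isna(due_date):
        return float(TERM_GESTATION_DAYS)
    length = TERM_GESTATION_DAYS + (pd.Timestamp(delivery_date)
                                    - pd.Timestamp(due_date)).days
    lo, hi = GESTATION_BOUNDS_DAYS
    return float(min(max(length, lo), hi))


def align_to_gestation(observations: pd.DataFrame,
                       participants: pd.DataFrame) -> pd.DataFrame:
    """Attach gestational day/week and a postpartum flag to each observation.

    Observations must reference known participants (unknown ids raise a
    ``ValueError`` listing them). Participants lacking a delivery date get
    NaN gestational fields and are caught later by ``filter_participants``.
    Observations after delivery (day_rel_delivery > 0) are retained but
    flagged ``postpartum``.
    """
    known = set(participants["participant_id"])
    present = set(observations["participant_id"].unique())
    unknown = sorted(present - known)
    if unknown:
        raise ValueError(f"observations reference unknown participants: {unknown}")

    part = participants.copy()
    part["delivery_date"] = pd.to_datetime(part["delivery_date"], errors="coerce")
    part["due_date"] = pd.to_datetime(part.get("due_date"), errors="coerce")
    part["gestational_length"] = [
        gestational_length_days(d, u)
        for d, u in zip(part["delivery_date"], part["due_date"])
    ]
    aligned = observations.merge(
        part[["participant_id", "gestational_length"]],
        on="participant_id", how="left", validate="many_to_one")
    aligned["gestational_day"] = (aligned["gestational_length"]
                                  + aligned["day_rel_delivery"])
    aligned["gestational_week"] = np.floor(aligned["gestational_day"] / 7.0)
    aligned["postpartum"] = aligned["day_rel_delivery"] > 0
    return aligned


def filter_participants(aligned: pd.DataFrame,
                        participants: pd.DataFrame,
                        feature: str,
                        max_missing_fraction: float = 0.6,
                        min_points: int = 30
                        ) -> tuple[list[str], pd.DataFrame]:
    """Apply the cohort inclusion rules on the prenatal span of ``feature``.

    Excludes participants with a missing delivery date, more than
    ``max_missing_fraction`` missing days over their observed span, or fewer
    than ``min_points`` non-missing points; returns the kept ids (sorted) and
    an exclusion report with one reason per excluded participant. The report
    is independent of input row order.
    """
    part = participants.copy()
    part["delivery_date"] = pd.to_datetime(part["delivery_date"], errors="coerce")
    prenatal = aligned[(aligned["feature"] == feature)
                       & (aligned["day_rel_delivery"] <= 0)]
    by_pid = {pid: grp for pid, grp in prenatal.groupby("participant_id")}

    kept: list[str] = []
    report_rows: list[dict] = []
    for _, row in part.iterrows():
        pid = row["participant_id"]
        if pd.isna(row["delivery_date"]):
            report_rows.append({"participant_id": pid,
                                "reason": REASON_MISSING_DELIVERY})
            continue
        grp = by_pid.get(pid)
        observed = (grp.dropna(subset=["value"])
                    if grp is not None else None)
        n = 0 if observed is None else len(observed)
        if n == 0:
            report_rows.append({"participant_id": pid, "reason": REASON_TOO_FEW})
            continue
        days = observed["day_rel_delivery"]
        span = int(days.max() - days.min()) + 1
        missing_fraction = 1.0 - n / span
        if missing_fraction > max_missing_fraction:
            report_rows.append({"participant_id": pid,
                                "reason": REASON_TOO_MISSING})
        elif n < min_points:
            report_rows.append({"participant_id": pid, "reason": REASON_TOO_FEW})
        else:
            kept.append(pid)
    report = (pd.DataFrame(report_rows, columns=["participant_id", "reason"])
              .sort_values("participant_id", kind="stable")
              .reset_index(drop=True))
    return sorted(kept), report


def remove_duplicates(observations: pd.DataFrame) -> pd.DataFrame:
    """Keep the first occurrence per (participant, feature, day).

    Later rows for the same key are dropped; collisions are recorded in the
    returned frame's ``attrs['duplicate_rows']``.
    """
    key = ["participant_id", "feature", "day_rel_delivery"]
    dup_mask = observations.duplicated(subset=key, keep="first")
    out = observations.loc[~dup_mask].reset_index(drop=True)
    out.attrs["duplicate_rows"] = int(dup_mask.sum())
    return out


def estimate_outlier_bounds(observations: pd.DataFrame,
                            subset_size: int = 100,
                            quantiles: tuple[float, float] = (0.05, 0.95),
                            seed: int | None = None
                            ) -> dict[str, OutlierBounds]:
    """Per-feature quantile bounds from a seeded random participant subset.

    Participants are drawn uniformly without replacement; when fewer than
    ``subset_size`` are available all are used and a warning is issued.
    Quantiles use linear interpolation between order statistics. A feature
    with no pooled non-missing data raises ``ValueError``.
    """
    pids = np.array(sorted(observations["participant_id"].unique()))
    if subset_size < len(pids):
        rng = np.random.default_rng(seed)
        subset = rng.choice(pids, size=subset_size, replace=False)
    else:
        if subset_size > len(pids):
            warnings.warn(
                f"subset_size {subset_size} exceeds cohort size {len(pids)}; "
                "using all participants", stacklevel=2)
        subset = pids
    pool = observations[observations["participant_id"].isin(subset)]
    bounds: dict[str, OutlierBounds] = {}
    for feat in sorted(observations["feature"].unique()):
        vals = pool.loc[pool["feature"] == feat, "value"].dropna().to_numpy()
        if vals.size == 0:
            raise ValueError(f"no calibration data for feature {feat!r}")
        lo, hi = np.quantile(vals, quantiles, method="linear")
        bounds[feat] = OutlierBounds(feat, float(lo), float(hi), len(subset))
    return bounds


def apply_outlier_bounds(observations: pd.DataFrame,
                         bounds: dict[str, OutlierBounds]) -> pd.DataFrame:
    """Mask values strictly outside their feature's bounds (set to NaN).

    Values equal to a bound are retained. Applied uniformly to every
    participant, including those outside the calibration subset. Idempotent.
    """
    missing = sorted(set(observations["feature"].unique()) - set(bounds))
    if missing:
        raise KeyError(f"no outlier bounds for features: {missing}")
    out = observations.copy()
    for feat, b in bounds.items():
        sel = out["feature"] == feat
        vals = out.loc[sel, "value"]
        out.loc[sel, "value"] = vals.where(
            vals.isna() | ((vals >= b.lower) & (vals <= b.upper)))
    return out


def weekly_average(aligned: pd.DataFrame) -> pd.DataFrame:
    """Smooth daily observations into gestational-week means.

    Returns one row per (participant, feature, gestational_week) having at
    least one non-missing observation, with the mean over that week's
    non-missing values and their count ``n``.
    """
    obs = aligned.dropna(subset=["value", "gestational_week"])
    weekly = (obs.groupby(["participant_id", "feature", "gestational_week"],
                          as_index=False)
              .agg(mean=("value", "mean"), n=("value", "size")))
    weekly["gestational_week"] = weekly["gestational_week"].astype(int)
    return weekly
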