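"""Peri-event change detection and the interindividual window scan.

For every adverse/severe event, the feature's peri-event window (7 days
before through 7 days after the event) is compared with a baseline period
(30 to 7 days before) by an unpaired Welch t test, computed only when both
windows hold at least 7 non-missing points. Events whose peri windows
overlap are merged transitively into composite events. A scan over
consecutive 14-day windows tiling gestational days [-270, 0) averages each
individual's t statistics per window and flags a window as high-variability
when some pair of individuals' average t statistics differs by strictly
more than twice the across-individual SD.

Sign convention: t > 0 means the feature mean was higher in the peri-event
window than at baseline (peri minus baseline in the numerator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EventRecord",
    "WelchTResult",
    "EventWindowTest",
    "WindowScanResult",
    "welch_t",
    "event_window_test",
    "merge_overlapping_events",
    "tile_windows",
    "variability_flag",
    "window_scan",
    "sample_qualifying_events",
    "matched_symptom_pairs",
    "tests_to_frame",
]

PERI_HALF_WINDOW = 7        # days before/after the event
BASELINE_WINDOW = (30, 7)   # days before the event, [start, end) half-open
MIN_WINDOW_POINTS = 7
EVENT_CLASSES = ("daily_severe", "biweekly_symptom", "adverse_event")

SKIP_BASELINE = "insufficient baseline"
SKIP_PERI = "insufficient peri-event"


@dataclass(frozen=True)
class EventRecord:
    participant_id: str
    label: str
    event_class: str
    day_rel_delivery: int
    n_members: int = 1      # >1 for composite (merged) events


@dataclass(frozen=True)
class WelchTResult:
    t: float
    df: float
    p: float


@dataclass
class EventWindowTest:
    """Baseline-vs-peri-event Welch t result for one event and feature.

    ``skipped_reason`` is set (and the statistics are NaN) when either
    window held fewer than 7 points.
    """

    event: EventRecord
    feature: str
    baseline_n: int
    peri_n: int
    baseline_mean: float = float("nan")
    peri_mean: float = float("nan")
    t_statistic: float = float("nan")
    welch_df: float = float("nan")
    p_value: float = float("nan")
    skipped_reason: str | None = None

    @property
    def skipped(self) -> bool:
        return self.skipped_reason is not None


@dataclass
class WindowScanResult:
    """One 14-day scan window with per-individual average t statistics."""

    window_index: int
    start_day: int
    end_day: int                    # span is [start_day, end_day)
    t_by_participant: dict[str, float]
    sd_across_individuals: float
    threshold: float                # 2 * sd
    high_variability: bool
    status: str                     # "ok" or "not assessable"


def welch_t(a, b) -> WelchTResult:
    """Unpaired Welch t test (unequal variances), two-sided.

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b) with
    Welch-Satterthwaite degrees of freedom. Degenerate zero-variance cases:
    equal means give t = 0 (p = 1); unequal means give a signed infinite t
    (p = 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each sample needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    se2 = va / na + vb / nb
    if se2 == 0.0:
        if diff == 0.0:
            return WelchTResult(0.0, float(na + nb - 2), 1.0)
        return WelchTResult(math.copysign(math.inf, diff),
                            float(na + nb - 2), 0.0)
    t = diff / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return WelchTResult(float(t), float(df), p)


def event_window_test(series: pd.DataFrame, event: EventRecord,
                      min_points: int = MIN_WINDOW_POINTS,
                      truncate_day: int | None = 0) -> EventWindowTest:
    """Welch t test of the peri-event window against baseline for one event.

    ``series`` holds one participant's daily values for one feature
    (columns ``day_rel_delivery``, ``value``, optionally ``feature``).
    Baseline: days [event-30, event-7); peri: [event-7, event+7], truncated
    at ``truncate_day`` (delivery) so postpartum days never enter. The test
    is skipped — never raised — when either window holds fewer than
    ``min_points`` non-missing values.
    """
    feature = (str(series["feature"].iloc[0])
               if "feature" in series.columns and len(series) else "")
    d = event.day_rel_delivery
    days = series["day_rel_delivery"].to_numpy()
    vals = series["value"].to_numpy(dtype=float)
    finite = np.isfinite(vals)
    base_mask = finite & (days >= d - BASELINE_WINDOW[0]) & (days < d - BASELINE_WINDOW[1])
    peri_hi = d + PERI_HALF_WINDOW
    if truncate_day is not None:
        peri_hi = min(peri_hi, truncate_day)
    peri_mask = finite & (days >= d - PERI_HALF_WINDOW) & (days <= peri_hi)
    base = vals[base_mask]
    peri = vals[peri_mask]
    test = EventWindowTest(event, feature, int(base.size), int(peri.size))
    if base.size < min_points:
        test.skipped_reason = SKIP_BASELINE
        return test
    if peri.size < min_points:
        test.skipped_reason = SKIP_PERI
        return test
    res = welch_t(peri, base)   # peri minus baseline: t > 0 = increase
    test.baseline_mean = float(base.mean())
    test.peri_mean = float(peri.mean())
    test.t_statistic, test.welch_df, test.p_value = res.t, res.df, res.p
    return test


def _round_toward_zero(x: float) -> int:
    return int(math.trunc(x))


def merge_overlapping_events(events: pd.DataFrame) -> list[EventRecord]:
    """Merge events whose +/-7-day peri windows overlap into composites.

    Operates per participant; events are sorted by day internally, so the
    result is independent of input order, and merging is transitive (a chain
    of pairwise-overlapping windows becomes one composite). The composite
    day is the mean of member days rounded toward delivery (toward 0);
    composite labels join the distinct member labels with ``+``. Idempotent:
    composites of adjacent clusters are always more than 14 days apart.
    """
    merged: list[EventRecord] = []
    for pid in sorted(events["participant_id"].unique()):
        sub = events[events["participant_id"] == pid].sort_values(
            "day_rel_delivery", kind="stable")
        cluster: list[pd.Series] = []
        for _, row in sub.iterrows():
            if cluster and (row["day_rel_delivery"]
                            - cluster[-1]["day_rel_delivery"]
                            > 2 * PERI_HALF_WINDOW):
                merged.append(_finalize_cluster(pid, cluster))
                cluster = []
            cluster.append(row)
        if cluster:
            merged.append(_finalize_cluster(pid, cluster))
    return merged


def _finalize_cluster(pid: str, cluster: list[pd.Series]) -> EventRecord:
    days = [int(r["day_rel_delivery"]) for r in cluster]
    labels = sorted({str(r["label"]) for r in cluster})
    classes = {str(r["event_class"]) for r in cluster}
    return EventRecord(
        participant_id=pid,
        label="+".join(labels),
        event_class=classes.pop() if len(classes) == 1 else "composite",
        day_rel_delivery=_round_toward_zero(float(np.mean(days))),
        n_members=len(cluster),
    )


def tile_windows(span: tuple[int, int] = (-270, 0),
                 width: int = 14) -> list[tuple[int, int]]:
    """Consecutive half-open windows [start, end) tiling ``span`` with no
    gaps or overlaps; the last window is truncated when the span is not a
    multiple of ``width``."""
    lo, hi = span
    if lo >= hi:
        raise ValueError("span must be increasing")
    edges = list(range(lo, hi, width)) + [hi]
    return [(edges[i], min(edges[i] + width, hi)) for i in range(len(edges) - 1)]


def variability_flag(t_values) -> tuple[float, float, bool]:
    """High-variability rule for one window: (sd, threshold, flag).

    sd is the sample SD (ddof=1) of the per-individual average t statistics;
    the flag is True iff some pair differs by strictly more than 2*sd, which
    for a scalar list reduces to max - min > 2*sd.
    """
    t = np.asarray(t_values, dtype=float)
    if t.size < 2:
        raise ValueError("need >= 2 individuals")
    sd = float(t.std(ddof=1))
    threshold = 2.0 * sd
    flag = bool(t.max() - t.min() > threshold)
    return sd, threshold, flag


def window_scan(observations: pd.DataFrame, events: pd.DataFrame,
                feature: str,
                span: tuple[int, int] = (-270, 0), width: int = 14,
                min_points: int = MIN_WINDOW_POINTS
                ) -> list[WindowScanResult]:
    """Scan 14-day windows over gestational days [-270, 0).

    Events are merged per participant first. In each window, every
    individual with at least one merged event there contributes the mean t
    over that individual's qualifying (non-skipped) peri-event tests for
    ``feature``; the window's across-individual SD sets the 2*SD
    high-variability threshold. Windows with fewer than two contributing
    individuals are marked ``not assessable``.
    """
    merged = merge_overlapping_events(events)
    obs = observations[observations["feature"] == feature]
    series_by_pid = {pid: grp for pid, grp in obs.groupby("participant_id")}
    tests: dict[tuple[str, int], EventWindowTest] = {}
    for ev in merged:
        series = series_by_pid.get(ev.participant_id)
        if series is None:
            continue
        tests[(ev.participant_id, ev.day_rel_delivery)] = event_window_test(
            series, ev, min_points=min_points)

    results: list[WindowScanResult] = []
    for idx, (start, end) in enumerate(tile_windows(span, width)):
        per_person: dict[str, list[float]] = {}
        for ev in merged:
            if not (start <= ev.day_rel_delivery < end):
                continue
            test = tests.get((ev.participant_id, ev.day_rel_delivery))
            if test is None or test.skipped or not np.isfinite(test.t_statistic):
                continue
            per_person.setdefault(ev.participant_id, []).append(test.t_statistic)
        t_by_pid = {pid: float(np.mean(ts)) for pid, ts in sorted(per_person.items())}
        if len(t_by_pid) < 2:
            results.append(WindowScanResult(idx, start, end, t_by_pid,
                                            float("nan"), float("nan"),
                                            False, "not assessable"))
        else:
            sd, threshold, flag = variability_flag(list(t_by_pid.values()))
            results.append(WindowScanResult(idx, start, end, t_by_pid,
                                            sd, threshold, flag, "ok"))
    return results


def sample_qualifying_events(tests: list[EventWindowTest],
                             p_threshold: float = 0.05,
                             per_participant: int = 1,
                             seed: int | None = None
                             ) -> list[EventWindowTest]:
    """Uniformly sample qualifying events, without replacement, per person.

    Qualifying: non-skipped tests with p < ``p_threshold``. From each
    participant having at least one, ``per_participant`` events (or all, if
    fewer) are drawn with a seeded generator; deterministic for a fixed
    seed. Participants are visited in sorted id order.
    """
    rng = np.random.default_rng(seed)
    by_pid: dict[str, list[EventWindowTest]] = {}
    for t in tests:
        if not t.skipped and np.isfinite(t.p_value) and t.p_value < p_threshold:
            by_pid.setdefault(t.event.participant_id, []).append(t)
    selected: list[EventWindowTest] = []
    for pid in sorted(by_pid):
        cand = by_pid[pid]
        k = min(per_participant, len(cand))
        idx = rng.choice(len(cand), size=k, replace=False)
        selected.extend(cand[i] for i in sorted(idx))
    return selected


def matched_symptom_pairs(events: pd.DataFrame,
                          tests: list[EventWindowTest] | None = None,
                          span: tuple[int, int] = (-270, 0),
                          width: int = 14) -> pd.DataFrame:
    """All unordered participant pairs sharing an event label in the same
    14-day scan window, annotated with both participants' t statistics when
    ``tests`` are supplied (NaN otherwise)."""
    merged = merge_overlapping_events(events)
    windows = tile_windows(span, width)
    t_lookup: dict[tuple[str, int], float] = {}
    for t in tests or []:
        t_lookup[(t.event.participant_id, t.event.day_rel_delivery)] = (
            t.t_statistic if not t.skipped else float("nan"))

    groups: dict[tuple[str, int], list[EventRecord]] = {}
    for ev in merged:
        for idx, (start, end) in enumerate(windows):
            if start <= ev.day_rel_delivery < end:
                groups.setdefault((ev.label, idx), []).append(ev)
                break
    rows: list[dict] = []
    for (label, idx), evs in sorted(groups.items()):
        evs = sorted(evs, key=lambda e: e.participant_id)
        for i in range(len(evs)):
            for j in range(i + 1, len(evs)):
                if evs[i].participant_id == evs[j].participant_id:
                    continue
                rows.append({
                    "label": label, "window_index": idx,
                    "participant_a": evs[i].participant_id,
                    "participant_b": evs[j].participant_id,
                    "day_a": evs[i].day_rel_delivery,
                    "day_b": evs[j].day_rel_delivery,
                    "t_a": t_lookup.get((evs[i].participant_id,
                                         evs[i].day_rel_delivery), float("nan")),
                    "t_b": t_lookup.get((evs[j].participant_id,
                                         evs[j].day_rel_delivery), float("nan")),
                })
    return pd.DataFrame(rows, columns=["label", "window_index",
                                       "participant_a", "participant_b",
                                       "day_a", "day_b", "t_a", "t_b"])


def tests_to_frame(tests: list[EventWindowTest]) -> pd.DataFrame:
    """Tabulate event tests for CSV export (t is peri minus baseline)."""
    return pd.DataFrame([{
        "participant_id": t.event.participant_id,
        "event_label": t.event.label,
        "event_day": t.event.day_rel_delivery,
        "feature": t.feature,
        "n_base": t.baseline_n, "n_peri": t.peri_n,
        "baseline_mean": t.baseline_mean, "peri_mean": t.peri_mean,
        "t_peri_minus_base": t.t_statistic, "welch_df": t.welch_df,
        "p": t.p_value, "skipped_reason": t.skipped_reason or "",
    } for t in tests], columns=["participant_id", "event_label", "event_day",
                                "feature", "n_base", "n_peri",
                                "baseline_mean", "peri_mean",
                                "t_peri_minus_base", "welch_df", "p",
                                "skipped_reason"])
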