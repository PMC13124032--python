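"""Per-individual trajectory models and cohort-level trend summaries.

The central object is the per-participant quadratic fit over gestational
weeks 10-40, whose vertex (-b/2a, the fitted minimum when a > 0) is read as
that individual's inflection week. Cohort summaries cover weekly aggregate
trends with 95% CIs, one-way random-effects ICC, coefficient of variation,
per-individual extrema and linear slopes, and the concordance of individual
inflections with an aggregate inflection week.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError

__all__ = [
    "QuadraticFit",
    "LinearFit",
    "ExtremaResult",
    "ConcordanceResult",
    "r_squared",
    "fit_quadratic",
    "fit_cohort_quadratics",
    "fit_linear_slope",
    "find_extrema",
    "aggregate_weekly",
    "icc_oneway",
    "coefficient_of_variation",
    "inflection_concordance",
    "fits_to_frame",
]

DEFAULT_WEEK_RANGE = (10, 40)
#: |a| below this is treated as "no curvature" and the vertex is undefined.
CURVATURE_TOL = 1e-8

FLAG_NO_CURVATURE = "no curvature"
FLAG_NO_INFLECTION = "no inflection in window"
FLAG_CONSTANT = "constant series"


@dataclass
class QuadraticFit:
    """Least-squares quadratic ``a*w^2 + b*w + c`` over gestational weeks.

    ``vertex_week`` is NaN when |a| < tolerance; an in-range fit with a
    vertex outside ``week_range`` keeps its numeric vertex but carries the
    ``no inflection in window`` flag.
    """

    participant_id: str
    feature: str
    a: float
    b: float
    c: float
    vertex_week: float
    r_squared: float
    n_weeks: int
    week_range: tuple[int, int]
    flags: tuple[str, ...] = ()

    @property
    def has_inflection(self) -> bool:
        return (np.isfinite(self.vertex_week)
                and FLAG_NO_INFLECTION not in self.flags)

    def predict(self, weeks) -> np.ndarray:
        w = np.asarray(weeks, dtype=float)
        return self.a * w ** 2 + self.b * w + self.c


@dataclass
class LinearFit:
    participant_id: str
    feature: str
    slope: float
    intercept: float
    r_squared: float
    n_weeks: int


@dataclass
class ExtremaResult:
    """Weekly-mean peak and trough; ties resolve to the earliest week."""

    participant_id: str
    feature: str
    peak_week: int
    trough_week: int
    peak_value: float
    trough_value: float


@dataclass
class ConcordanceResult:
    fraction: float
    n_within: int
    n_total: int


def r_squared(y_observed, y_fitted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot; may be negative.

    Raises ``ValueError`` when ``y_observed`` is constant (zero total sum of
    squares).
    """
    y = np.asarray(y_observed, dtype=float)
    f = np.asarray(y_fitted, dtype=float)
    if y.shape != f.shape or y.size < 2:
        raise ValueError("y_observed and y_fitted must be equal length >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("y_observed is constant; R^2 undefined")
    ss_res = float(np.sum((y - f) ** 2))
    return 1.0 - ss_res / ss_tot


def _select_window(weeks, values, week_range):
    w = np.asarray(weeks, dtype=float)
    y = np.asarray(values, dtype=float)
    keep = (w >= week_range[0]) & (w <= week_range[1]) & np.isfinite(y)
    return w[keep], y[keep]


def fit_quadratic(weeks, values,
                  participant_id: str = "", feature: str = "",
                  week_range: tuple[int, int] = DEFAULT_WEEK_RANGE,
                  min_points: int = 5,
                  curvature_tol: float = CURVATURE_TOL) -> QuadraticFit:
    """Least-squares quadratic over the weekly means inside ``week_range``.

    Needs at least ``min_points`` weekly points (three free parameters plus
    two residual degrees of freedom); fewer raises
    :class:`InsufficientDataError` so cohort drivers can record the skip.
    """
    w, y = _select_window(weeks, values, week_range)
    if w.size < min_points:
        raise InsufficientDataError(
            f"fewer than {min_points} weekly points",
            f"{participant_id}/{feature}: {w.size} weekly points in "
            f"{week_range}, need {min_points}")
    if np.unique(w).size < 3:
        raise ValueError("singular design: fewer than 3 distinct weeks")
    a, b, c = np.polyfit(w, y, 2)
    fitted = a * w ** 2 + b * w + c
    flags: list[str] = []
    try:
        r2 = r_squared(y, fitted)
    except ValueError:
        r2 = float("nan")
        flags.append(FLAG_CONSTANT)
    if abs(a) < curvature_tol:
        vertex = float("nan")
        flags.append(FLAG_NO_CURVATURE)
    else:
        vertex = float(-b / (2.0 * a))
        if not (week_range[0] <= vertex <= week_range[1]):
            flags.append(FLAG_NO_INFLECTION)
    return QuadraticFit(participant_id, feature, float(a), float(b), float(c),
                        vertex, r2, int(w.size), tuple(week_range),
                        tuple(flags))


def fit_cohort_quadratics(weekly: pd.DataFrame, feature: str,
                          week_range: tuple[int, int] = DEFAULT_WEEK_RANGE,
                          min_points: int = 5
                          ) -> tuple[list[QuadraticFit], pd.DataFrame]:
    """Fit every participant's weekly series for ``feature``.

    Returns the fits and a skip report (participant_id, reason) for series
    with too few weekly points.
    """
    fits: list[QuadraticFit] = []
    skips: list[dict] = []
    sub = weekly[weekly["feature"] == feature]
    for pid in sorted(sub["participant_id"].unique()):
        grp = sub[sub["participant_id"] == pid]
        try:
            fits.append(fit_quadratic(grp["gestational_week"], grp["mean"],
                                      participant_id=pid, feature=feature,
                                      week_range=week_range,
                                      min_points=min_points))
        except InsufficientDataError as err:
            skips.append({"participant_id": pid, "reason": err.reason})
    return fits, pd.DataFrame(skips, columns=["participant_id", "reason"])


def fit_linear_slope(weeks, values,
                     participant_id: str = "", feature: str = "",
                     week_range: tuple[int, int] = DEFAULT_WEEK_RANGE,
                     min_points: int = 3) -> LinearFit:
    """Ordinary least-squares slope of weekly means over gestational week."""
    w, y = _select_window(weeks, values, week_range)
    if w.size < min_points:
        raise InsufficientDataError(
            f"fewer than {min_points} weekly points",
            f"{participant_id}/{feature}: {w.size} points, need {min_points}")
    slope, intercept = np.polyfit(w, y, 1)
    fitted = slope * w + intercept
    try:
        r2 = r_squared(y, fitted)
    except ValueError:
        r2 = float("nan")
    return LinearFit(participant_id, feature, float(slope), float(intercept),
                     r2, int(w.size))


def find_extrema(weeks, values, participant_id: str = "",
                 feature: str = "") -> ExtremaResult:
    """Peak and trough of the weekly means; ties go to the earliest week."""
    w = np.asarray(weeks)
    y = np.asarray(values, dtype=float)
    if w.size < 3:
        raise InsufficientDataError("fewer than 3 weekly points")
    order = np.argsort(w, kind="stable")
    w, y = w[order], y[order]
    i_max = int(np.argmax(y))       # first occurrence = earliest week
    i_min = int(np.argmin(y))
    return ExtremaResult(participant_id, feature,
                         int(w[i_max]), int(w[i_min]),
                         float(y[i_max]), float(y[i_min]))


def aggregate_weekly(weekly: pd.DataFrame, feature: str,
                     week_range: tuple[int, int] | None = DEFAULT_WEEK_RANGE,
                     min_participants: int = 2) -> pd.DataFrame:
    """Cohort trend: per-week mean of participants' weekly means with a
    95% CI half-width 1.96 * SD / sqrt(n); weeks with fewer than
    ``min_participants`` contributors are dropped."""
    sub = weekly[weekly["feature"] == feature]
    if week_range is not None:
        sub = sub[(sub["gestational_week"] >= week_range[0])
                  & (sub["gestational_week"] <= week_range[1])]
    agg = (sub.groupby("gestational_week")["mean"]
           .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="size")
           .reset_index())
    agg = agg[agg["n"] >= min_participants].reset_index(drop=True)
    agg["ci_half_width"] = 1.96 * agg["sd"] / np.sqrt(agg["n"])
    return agg[["gestational_week", "mean", "ci_half_width", "n"]]


def icc_oneway(groups) -> float:
    """One-way random-effects ICC(1) from the ANOVA decomposition.

    ``groups`` is a sequence of per-participant value arrays (possibly
    unequal sizes). ICC = (MSB - MSW) / (MSB + (k_bar - 1) * MSW) with
    ``k_bar`` the mean group size; range [-1/(k_bar-1), 1].
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a[np.isfinite(a)] for a in arrays]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    sizes = np.array([a.size for a in arrays], dtype=float)
    n_total = sizes.sum()
    g = len(arrays)
    grand = sum(a.sum() for a in arrays) / n_total
    means = np.array([a.mean() for a in arrays])
    ss_between = float(np.sum(sizes * (means - grand) ** 2))
    ss_within = float(sum(np.sum((a - m) ** 2) for a, m in zip(arrays, means)))
    if ss_between + ss_within == 0.0:
        raise ValueError("zero total variance; ICC undefined")
    msb = ss_between / (g - 1)
    msw = ss_within / (n_total - g)
    k_bar = n_total / g
    return (msb - msw) / (msb + (k_bar - 1.0) * msw)


def coefficient_of_variation(values) -> float:
    """Sample CV as a percentage: 100 * SD / mean (SD with ddof=1)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need >= 2 values")
    mean = v.mean()
    if mean == 0.0:
        raise ValueError("zero mean; CV undefined")
    return 100.0 * v.std(ddof=1) / mean


def inflection_concordance(fits, aggregate_week: float,
                           tolerance_weeks: float = 0.5) -> ConcordanceResult:
    """Fraction of individuals whose inflection lies within
    ``tolerance_weeks`` of the aggregate inflection week.

    ``fits`` may be :class:`QuadraticFit` objects or raw vertex weeks (NaN =
    undefined). Individuals without a usable inflection stay in the
    denominator — the statistic asks how many people actually share the
    aggregate inflection.
    """
    vertices = []
    for f in fits:
        if hasattr(f, "vertex_week"):
            vertices.append(f.vertex_week if f.has_inflection else np.nan)
        else:
            vertices.append(float(f))
    v = np.asarray(vertices, dtype=float)
    if v.size == 0:
        raise ValueError("empty fit collection")
    within = np.abs(v - aggregate_week) <= tolerance_weeks
    n_within = int(np.nansum(within[np.isfinite(v)]))
    return ConcordanceResult(n_within / v.size, n_within, int(v.size))


def fits_to_frame(fits: list[QuadraticFit]) -> pd.DataFrame:
    """Tabulate quadratic fits for CSV export / subgroup comparison."""
    return pd.DataFrame([{
        "participant_id": f.participant_id, "feature": f.feature,
        "a": f.a, "b": f.b, "c": f.c, "vertex_week": f.vertex_week,
        "r_squared": f.r_squared, "n_weeks": f.n_weeks,
        "flags": ";".join(f.flags),
    } for f in fits], columns=["participant_id", "feature", "a", "b", "c",
                               "vertex_week", "r_squared", "n_weeks", "flags"])
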