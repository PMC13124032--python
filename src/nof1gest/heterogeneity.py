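"""Subgroup heterogeneity: KDE curves, KS tests, likelihood-ratio tests.

Distributions of individual-level model fit (R^2) are compared between a
complication/demographic subgroup and its complement with a two-sample
Kolmogorov-Smirnov test; the age predictor is assessed with a
likelihood-ratio test between nested Gaussian linear models of the cohort
weekly means (quadratic in gestational week, with and without a binary
age-group intercept, df = 1).

P-values are reported raw; a Holm-adjusted column is additionally emitted
for transparency (clearly labeled, not part of the replication surface).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "KDEConfig",
    "KSResult",
    "LRTestResult",
    "kde_density",
    "ks_two_sample",
    "lr_test",
    "gaussian_linear_loglik",
    "age_predictor_test",
    "subgroup_r2_comparison",
]

ALPHA = 0.05
#: switch from exact to asymptotic KS p-values above this n1*n2
KS_EXACT_LIMIT = 10_000


@dataclass(frozen=True)
class KDEConfig:
    """Gaussian-kernel density estimate configuration.

    ``bandwidth`` is in data units (None = Silverman's rule); the evaluation
    grid has ``grid_size`` points over ``grid_range`` (default: data range
    padded by ``pad_bandwidths`` bandwidths on each side, wide enough that
    the trapezoid integral of the curve is ~1).
    """

    bandwidth: float | None = None
    grid_size: int = 512
    grid_range: tuple[float, float] | None = None
    pad_bandwidths: float = 4.0

    def __post_init__(self):
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")


@dataclass(frozen=True)
class KSResult:
    statistic: float
    p_value: float
    n1: int
    n2: int

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class LRTestResult:
    ll_full: float
    ll_reduced: float
    lr_statistic: float
    df: int
    p_value: float


def kde_density(values, config: KDEConfig | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE evaluated on a grid; returns ``(grid, density)``.

    Needs at least two distinct values (a degenerate sample has zero
    Silverman bandwidth and raises ``ValueError``).
    """
    config = config or KDEConfig()
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2 or np.unique(v).size < 2:
        raise ValueError("kde_density needs >= 2 distinct values")
    sd = v.std(ddof=1)
    if config.bandwidth is None:
        kde = stats.gaussian_kde(v, bw_method="silverman")
    else:
        kde = stats.gaussian_kde(v, bw_method=config.bandwidth / sd)
    h = kde.factor * sd
    if config.grid_range is not None:
        lo, hi = config.grid_range
    else:
        lo = v.min() - config.pad_bandwidths * h
        hi = v.max() + config.pad_bandwidths * h
    grid = np.linspace(lo, hi, config.grid_size)
    return grid, kde(grid)


def ks_two_sample(a, b) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test: D = sup |ECDF_a - ECDF_b|.

    Exact p-value for small samples (n1*n2 <= 10^4), asymptotic otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need >= 2 values")
    method = "exact" if a.size * b.size <= KS_EXACT_LIMIT else "asymp"
    with warnings.catch_warnings():
        # scipy falls back to the asymptotic p-value when ties preclude the
        # exact computation; that fallback is the intended behaviour here
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ks_2samp(a, b, method=method)
    return KSResult(float(res.statistic), float(res.pvalue),
                    int(a.size), int(b.size))


def lr_test(ll_full: float, ll_reduced: float, df: int,
            tol: float = 1e-7) -> LRTestResult:
    """Likelihood-ratio test LR = -2*(ll_reduced - ll_full), p from the
    upper tail of chi-square with ``df`` degrees of freedom.

    ``ll_full`` below ``ll_reduced`` by more than ``tol`` violates nesting
    and raises ``ValueError``.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if ll_full < ll_reduced - tol:
        raise ValueError(
            f"nesting violated: ll_full={ll_full} < ll_reduced={ll_reduced}")
    lr = max(0.0, -2.0 * (ll_reduced - ll_full))
    p = float(stats.chi2.sf(lr, df))
    return LRTestResult(float(ll_full), float(ll_reduced), lr, int(df), p)


def gaussian_linear_loglik(X: np.ndarray, y: np.ndarray) -> float:
    """Maximized Gaussian log-likelihood of an OLS fit (ML variance)."""
    n = y.size
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / n
    if sigma2 <= 0:
        raise ValueError("zero residual variance; likelihood unbounded")
    return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)


def age_predictor_test(weekly: pd.DataFrame, participants: pd.DataFrame,
                       feature: str, age_threshold: float = 30.0,
                       week_range: tuple[int, int] = (10, 40)
                       ) -> LRTestResult:
    """Does a binary age split improve the cohort trajectory model?

    Full model: weekly mean ~ 1 + week + week^2 + 1[age >= threshold];
    reduced model drops the age term. Gaussian ML likelihoods, df = 1.
    Both age strata must be non-empty.
    """
    sub = weekly[(weekly["feature"] == feature)
                 & (weekly["gestational_week"] >= week_range[0])
                 & (weekly["gestational_week"] <= week_range[1])]
    merged = sub.merge(participants[["participant_id", "age"]],
                       on="participant_id", how="inner")
    if merged.empty:
        raise ValueError("no weekly data after merging ages")
    older = (merged["age"] >= age_threshold).to_numpy(dtype=float)
    if older.all() or not older.any():
        raise ValueError(
            f"empty age stratum at threshold {age_threshold}")
    w = merged["gestational_week"].to_numpy(dtype=float)
    y = merged["mean"].to_numpy(dtype=float)
    ones = np.ones_like(w)
    X_reduced = np.column_stack([ones, w, w ** 2])
    X_full = np.column_stack([ones, w, w ** 2, older])
    ll_full = gaussian_linear_loglik(X_full, y)
    ll_reduced = gaussian_linear_loglik(X_reduced, y)
    return lr_test(ll_full, ll_reduced, df=1)


def _participant_labels(participants: pd.DataFrame) -> pd.Series:
    comps = participants.set_index("participant_id")["complications"]
    return comps.fillna("").map(
        lambda s: frozenset(x for x in str(s).split(";") if x))


def subgroup_r2_comparison(fits: pd.DataFrame, participants: pd.DataFrame,
                           labels: list[str] | None = None,
                           kde_config: KDEConfig | None = None,
                           min_group: int = 2
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare R^2 distributions of each subgroup against its complement.

    ``fits`` is the frame from :func:`~nof1gest.trajectories.fits_to_frame`.
    For every (label, feature): KS test of the group's R^2 values versus all
    other participants'. Groups (or complements) smaller than ``min_group``
    are marked ``insufficient``. Returns the comparison table (with raw and
    Holm-adjusted p-values) and per-group KDE curves in long format.
    """
    label_sets = _participant_labels(participants)
    if labels is None:
        labels = sorted(set().union(*label_sets) if len(label_sets) else set())
    features = sorted(fits["feature"].unique())
    rows: list[dict] = []
    density_rows: list[pd.DataFrame] = []
    for label in labels:
        in_group = label_sets.index[label_sets.map(lambda s: label in s)]
        for feat in features:
            sub = fits[fits["feature"] == feat].dropna(subset=["r_squared"])
            grp = sub[sub["participant_id"].isin(in_group)]["r_squared"]
            comp = sub[~sub["participant_id"].isin(in_group)]["r_squared"]
            row = {"feature": feat, "group": label,
                   "n_group": int(len(grp)), "n_complement": int(len(comp))}
            if len(grp) < min_group or len(comp) < min_group:
                row.update(ks_D=np.nan, p_raw=np.nan, status="insufficient")
            else:
                ks = ks_two_sample(grp, comp)
                row.update(ks_D=ks.statistic, p_raw=ks.p_value, status="ok")
                try:
                    grid, dens = kde_density(grp, kde_config)
                    density_rows.append(pd.DataFrame({
                        "feature": feat, "group": label,
                        "grid_x": grid, "density": dens}))
                except ValueError:
                    pass    # degenerate group distribution: no curve
            rows.append(row)
    table = pd.DataFrame(rows, columns=["feature", "group", "n_group",
                                        "n_complement", "ks_D", "p_raw",
                                        "status"])
    # Holm column is supplementary (raw p-values are the primary readout).
    table["p_holm"] = np.nan
    ok = table["status"] == "ok"
    if ok.any():
        table.loc[ok, "p_holm"] = multipletests(
            table.loc[ok, "p_raw"], method="holm")[1]
    densities = (pd.concat(density_rows, ignore_index=True) if density_rows
                 else pd.DataFrame(columns=["feature", "group",
                                            "grid_x", "density"]))
    return table, densities
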