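# Methods

This note documents the statistical procedures implemented in `nof1gest`,
the conventions chosen where several were defensible, and what the
synthetic-data experiments do and do not establish.

## Gestational alignment and preprocessing

Observations arrive as daily values indexed by `day_rel_delivery` (signed
days, 0 = delivery). Gestational length is `L = (delivery − due) + 280`
days, clipped to [140, 320]; when the due date is unknown `L = 280`. Then
`gestational_day = L + day_rel_delivery` and
`gestational_week = floor(gestational_day / 7)`, so a sample 70 days before
a term delivery falls in week 30 and delivery day is week 40. Postpartum
observations (day > 0) are retained but flagged and excluded from all
trajectory windows.

Inclusion filters run on the prenatal span of the feature under analysis.
A participant is excluded for (in order of precedence) missing delivery
information, more than 60% missing days, or fewer than 30 non-missing
points. The missingness denominator is the day span from the participant's
first to last non-missing observation, inclusive — the only denominator
computable from the data alone. Both thresholds are strict inequalities, so
exactly 60% missing or exactly 30 points is kept.

Duplicate (participant, feature, day) rows keep the first occurrence in
input order; collisions are counted. Outlier bounds are the 0.05/0.95
quantiles (linear interpolation between order statistics, the common
"type 7" estimator) of values pooled from a seeded uniform random subset of
100 participants, applied uniformly to the whole cohort per feature; only
values strictly outside the bounds are masked to NaN, so masking is
idempotent and never alters retained values. Bounds are global per feature
rather than per gestational window. Weekly smoothing averages each week's
non-missing values.

## Individual trajectories

Each participant's weekly means over gestational weeks 10–40 are fitted
with a least-squares quadratic. At least 5 weekly points are required
(three parameters plus two residual degrees of freedom); fewer points skip
the fit with a recorded reason. Curvature below |a| < 1e−8 (feature
units/week²) is treated as "no curvature" and the vertex is undefined; a
vertex falling outside weeks 10–40 is kept numerically but flagged "no
inflection in window" and treated as not having an inflection. R² is
1 − SS_res/SS_tot and may be negative; it is undefined (error) for a
constant observed series.

Inflection concordance counts individuals whose vertex lies within a
tolerance (default ±0.5 weeks, i.e. the same integer week) of a reference
aggregate inflection week; individuals without a usable inflection stay in
the denominator, since the question is how many people share the aggregate
feature. Extrema of weekly means break ties toward the earliest week.
Aggregate weekly trends use the normal 95% multiplier (1.96·SD/√n across
participants' weekly means); per-week n is large in the intended use, so a
t quantile would change little. ICC is the one-way random-effects ICC(1)
from the ANOVA decomposition with the mean group size k̄ for unbalanced
groups. The coefficient of variation is the sample SD over the mean, in
percent.

## Subgroup heterogeneity

Distributions of per-individual R² are compared between each subgroup and
its complement with the two-sample Kolmogorov–Smirnov test (exact p-value
when n₁·n₂ ≤ 10⁴, asymptotic otherwise; scipy falls back to asymptotic in
the presence of ties). Density curves use a Gaussian KDE with Silverman's
bandwidth (scalar override in data units available). P-values are reported
raw, matching the per-group readout of the comparison; a Holm-adjusted
column is additionally emitted and clearly labelled as supplementary.

The age predictor is assessed with a likelihood-ratio test between nested
Gaussian linear models of the pooled weekly means: mean ~ 1 + week + week²
(+ 1[age ≥ 30]), maximized Gaussian log-likelihoods, LR =
−2(ll_reduced − ll_full), χ² with df = 1. This is the simplest nested pair
for the question "does an age split improve the cohort trajectory model".
**Caveat**: the model treats all weekly observations as independent. When
between-person baseline variance is substantial — which is exactly the
regime the package is designed to expose — the pooled test is
anticonservative, because chance imbalance between age strata in person
baselines is amplified by the many within-person observations. Its type-I
error is calibrated under i.i.d. residuals (verified by simulation in the
acceptance suite) and should be interpreted cautiously otherwise; a mixed
model would be the remedy but is outside the implemented scope.

## Event analysis

Windows are defined on `day_rel_delivery`. For an event at day *d*:
baseline is days [d−30, d−7), half-open so day d−7 is not double-counted
("one month" read as 30 days); the peri-event window is [d−7, d+7], closed,
truncated at day 0 so postpartum days never enter. A Welch *t* test
(unequal variances, Welch–Satterthwaite df, two-sided) compares peri minus
baseline — positive *t* means the feature rose around the event. Tests
require ≥7 non-missing points in both windows; otherwise they are skipped
with a recorded reason, never raised. Degenerate zero-variance windows take
*t* = 0 when the means agree and a signed infinite *t* otherwise.

Events whose ±7-day windows overlap (day gap ≤ 14) merge transitively into
a composite at the mean member day rounded toward delivery; composites of
adjacent clusters are always >14 days apart, so merging is idempotent, and
internal sorting makes it input-order invariant.

The interindividual scan tiles days [−270, 0) with consecutive 14-day
windows — 19 full windows plus a final [−4, 0) window, since 270 is not a
multiple of 14. Per window, each individual with ≥1 merged event there
contributes the mean *t* over their qualifying tests (per feature; features
are never pooled). The high-variability threshold is twice the sample SD
(ddof = 1) of those per-individual averages; the flag is raised when some
pair differs by strictly more than the threshold, which reduces to
max − min > 2·SD. Windows with fewer than two contributors are "not
assessable". Case-study events are drawn uniformly without replacement
(seeded) from each participant's significant (p < .05) tests.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes: per
participant, per feature,

value(week) = a·(week − v)² + s·(week − v) + c + N(0, σ²),

with vertex week v ~ N(33, 3), curvature, optional slope (default 0) and
level drawn from population distributions; the trend is evaluated on the
integer-week grid that the weekly analysis uses, with all within-week
variation carried by the daily noise term, so noiseless cohorts are
recovered exactly by the weekly estimator. Default HRV noise (SD 2.4 ms) is
15% of the quadratic range over weeks 10–40. Missingness is
missing-completely-at-random (default 20%, below the 60% exclusion
threshold). Fatigue is clipped to [1, 7]. Events follow a homogeneous
per-day Bernoulli process (default expectation 3 per participant) with
labels from a small fixed vocabulary, shifting each feature's mean by a
configured amount within ±7 days. Complication labels are independent
Bernoulli draws with prevalences matching a 275-person perinatal cohort
(e.g. preterm birth 13%, major depression 69%); a preterm label shortens
gestation to 210–258 days. Delivery dates are uniform over a configurable
calendar window. All randomness flows from one seed through
per-participant sub-streams, so identical configs regenerate byte-identical
cohorts.

What the generator deliberately omits: autocorrelated or circadian noise,
informative missingness, event-time clustering, ordinal measurement of
fatigue (it is continuous then clipped), and any coupling between subgroup
labels and trajectories. Passing tests therefore demonstrate correctness of
the estimators under the assumed generative structure — parameter recovery,
calibration, mechanics — not robustness to real-world violations such as
serial correlation (which would make peri-event tests anticonservative) or
missingness related to symptom burden.

## Problem sizes and numerical choices

The test and acceptance experiments use desk-scale problem sizes chosen for
tight statistical bands at interactive runtimes: 200-participant cohorts
for recovery checks (vertex error, ICC ±0.05 of a configured 0.6,
concordance vs the closed-form normal mass), 1000 replicates for null
calibration of the event and age tests, and 500 replicates for the
1.5-SD-shift power check. The ICC recovery experiment evaluates weeks
10–39: at term, gestational week 40 contains a single day, so its weekly
mean carries seven times the within-person variance of a full week and
would bias the configured variance ratio.

Tolerances: quadratic/linear fits use `numpy.polyfit` least squares;
curvature guard 1e−8; LR nesting violations beyond 1e−7 raise; KDE curves
integrate to 1 within 1e−3 on a ±4-bandwidth grid. Ties in extrema go to
the earliest week; duplicate observations keep the first row seen.
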