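# Methods

## The estimand and the window design

The package estimates *pulse effects*: immediate, transient shifts in the
mean of a weekly (or daily) series at a calendar-anchored event, as opposed
to durable level or slope changes. For an event year, the **event window**
is the period containing the anchor date (May 31 for the awareness-day
application; Jan 1 for the New Year benchmark) plus `event_halfwidth_weeks`
periods on each side — 3 weeks by default, chosen to capture presaging and
lingering activity. The **reference windows** are the
`reference_halfwidth_weeks` (12) periods immediately before and after the
event window. The effect is

    effect = mean(event) / mean(reference) − 1,

a ratio so that nations with different baselines are comparable. Weeks
inside windows are treated as exchangeable draws; serial correlation is not
modeled. That simplification is checked empirically by the placebo scan
(re-estimating at anchor dates shifted in whole weeks), which is the
design's substitute for untreated control units: a global event has none.

Missing observations are explicit (NaN) and are dropped from window means,
never zero-filled; an observed zero is data. Reference windows truncated by
the panel edge are used but flagged, and pooling excludes estimates with
fewer than `min_reference_per_side` (8) reference weeks on either side —
silent exclusion and silent truncation are the two ways a pooled result
can drift without any individual number being wrong, so both are logged.

Weekly panels are keyed by week-start date; weeks start on Sunday by
default (the convention of Trends-style exports, whose historical exports
do not document it — the convention is configurable through the panel
dates themselves, since windows are located on whatever grid a panel uses).

## Scales

- **News**: cessation-story counts over total-story counts, reported per
  100,000 stories. A zero total with a positive numerator is an error; a
  zero total with a zero numerator is missing, not zero.
- **Queries**: relative search volume (RSV), the series max-normalized to
  100 and, as exported, rounded to integers. Rounding is half-up. The
  estimator is exactly invariant under positive rescaling of its input
  (the ratio cancels any scale), so RSV normalization does not distort
  effects; integer quantization perturbs them by < 0.02 at baselines ≥ 30
  (asserted in the test suite).

## Confidence intervals

The interval method for a ratio of a 3-point mean to a 24-point mean is
genuinely open; three are implemented, selectable via `CISettings`:

- **`delta` (default)**: delta-method interval for the ratio of means with
  a Welch–Satterthwaite-df Student-t critical value. Under a flat baseline
  with 10% multiplicative noise its null exclusion rate is ≈ 0.073 over
  6,048 simulated panels (nominal 0.05; the excess comes from the ~2.5
  effective df and the skewness of small lognormal means). Log-scale delta
  and Fieller intervals were evaluated on the same panels (0.071 both) and
  bought nothing, so the simplest form is kept.
- **`bootstrap`**: percentile bootstrap resampling event- and
  reference-window observations independently (10,000 reps by default),
  with Hesterberg's expanded-percentile small-sample adjustment: endpoint
  levels widened to Φ(−t·√(V₁/V₀)) with t at the Welch df, V₁/V₀ the
  unbiased/plug-in variance ratio. Null exclusion ≈ 0.094: with n = 3 the
  bootstrap distribution of the event mean has bounded support (10 distinct
  resamples), which no level adjustment fully repairs.
- **`percentile`**: the raw percentile bootstrap, for comparison. Null
  exclusion ≈ 0.19 — do not use it at these window sizes; it is retained
  as the baseline the adjustment is measured against.

Quantile intervals from few distinct resamples can exclude the point
estimate; intervals are clipped to contain it. Zero within-window variance
(noiseless data) yields a degenerate [effect, effect] interval.

## Pooling

Nation-year estimates are combined per metric within a grouping (overall,
by nation, by year). The default is the **unweighted mean** with pooled
variance Σvᵢ/k² (vᵢ recovered from each CI half-width at its level), CI
normal. Fixed-effect inverse-variance weighting is implemented and
selectable, but it is *not* the default on purpose: with variance estimates
carrying ~2.5 df, weights are strongly negatively correlated with the
estimate (a ratio's variance scales with (1+effect)²) and 1/s² grossly
overstates precision, which in simulation biased pooled lifts down by
0.013–0.023 and cut pooled 95% CI coverage to ≈ 57%; the unweighted mean
has bias ≤ 0.006 with full coverage. When every component shares the same
window design, equal weights are also the efficient choice. With k = 1 the
input estimate is returned unchanged; a zero-variance component under
inverse-variance weighting receives a 1e−12 floor and flags the result.

## The synthetic generator

The generator is a stand-in for news/query archives that are not
reproducibly retrievable, not a model fitted to them. Per nation and week:

- **news**: cessation counts with mean `news_total_weekly · news_base_rate ·
  season(t) · (1 + g_news·ramp(t)) · (1 + g_ny·ny(t))`; Poisson when noise
  is on, exactly the mean when `noise_cv = 0` (the mode exact-recovery
  tests use). Total counts are the constant `news_total_weekly`: the
  denominator is ~5 orders of magnitude larger than the numerator, so its
  sampling noise is negligible. The awareness-day shape `ramp` rises
  linearly over the 4 preceding weeks (0.2, 0.4, 0.6, 0.8), peaks at 1 in
  the event week, and drops to 0.3 the week after — a month-long buildup
  with a few-days decay, seen at weekly resolution.
- **queries**: latent propensity `b · season(t) · (1 + g_ny·ny(t)) ·
  (1 + g_query·event(t)) · anomaly(t)^κ · ε`, then max-100 normalization
  with integer quantization. `event` is rectangular over the 3-week event
  window (interest persists through the week after the event); `ny` is
  rectangular over the 3 weeks around Jan 1 (both streams); `anomaly` is
  the *expected* news pulse factor, so injected lifts stay closed-form
  while realized news still co-moves with queries near the event; ε is
  log-normal with CV `noise_cv`, mean 1. κ (`query_news_coupling`) is the
  elasticity of queries with respect to news.
- **seasonality**: one annual cosine, amplitude `seasonal_amplitude`,
  peaking at New Year (cessation interest is highest around the New Year).
- **missing nation-years**: three nations lack 2006–2007 by default;
  leading/trailing missing years shorten the panel, interior ones are NaN.
- **randomness**: per-nation, per-stream substreams keyed by a CRC of the
  label, so adding a nation or stream never perturbs another's draws;
  identical seed + config is bit-identical.

Default calibration (the study conditions): `wntd_news_pulse = 0.71`,
`wntd_pulse = 0.10` with `κ = log₂1.5 ≈ 0.585` — a news doubling maps to a
+50% query lift, and the total event-window query lift lands near +0.39 —
`newyear_pulse = 0.10`, `news_base_rate = 1.75e−4` of
`news_total_weekly = 100,000` (≈ 17.5 baseline stories per 100,000, ≈ 30
at the event peak), `baseline_query_propensity = 50`,
`seasonal_amplitude = 0.10`, `noise_cv = 0.10`, quantization on. Pulse
lifts accept scalars, per-nation, or per-(nation, year) maps.

`ground_truth()` tabulates, per nation-year-metric, the direct pulse
parameter (`lift`), the expected event-window mean lift (`event_lift`,
which dilutes the news peak over the ramp and folds coupling into
queries), and `design_effect` — the population value of the two-mean
estimator under a flat baseline, accounting for the ramp weeks that fall
inside the reference windows. With coupling and news pulse off,
`design_effect` equals `lift` exactly, and the estimator recovers it to
machine precision on noiseless worlds.

What the generator does **not** emulate: day-of-week effects (it emits
weekly panels only, though window location and estimation handle daily
panels), autocorrelated noise beyond the pulse/seasonal structure,
cross-nation correlation, drifting baselines, or the sampling noise of
Trends' query-share estimates. Passing tests therefore certify the
estimator and pipeline under these stated conditions, not the behavior of
real archives.

## A deterministic limitation: seasonal curvature

The ±12-week reference design absorbs locally *linear* drift. An annual
sinusoid is not locally linear over the ±15-week span the design covers:
writing A·cosθ for the seasonal term at the anchor, the event and
reference means attenuate it by factors c_ev ≈ 0.995 and c_ref ≈ 0.571,
so a pulse-free series shows a spurious effect of
(1 + c_ev·A·cosθ)/(1 + c_ref·A·cosθ) − 1 ≈ 0.42·A·cosθ. At the default
amplitude (A = 0.10) and a late-May anchor (cosθ ≈ −0.85) this is −0.038 —
about 0.6 standard errors of a single nation-year estimate — which pushes
the null CI-exclusion rate to ≈ 0.11–0.14 even for a well-calibrated
interval. The test suite pins this bias to its closed form and reports the
calibration consequence honestly rather than hiding the seasonality. In
practice it cautions against reading small pulse effects (≲ 0.05) off this
design when the series has material smooth seasonality; estimates of the
size the application targets (0.3–0.7) are shifted by only a few points,
scaling with (1 + effect).

## Problem sizes

Simulation-backed checks use: 6,048 panels for CI calibration; 201
replicate worlds (67 per injected lift in {0.10, 0.40, 0.84}) for pooled
recovery, which lands at |bias| ≤ 0.006, MAE ≤ 0.017 and full CI coverage;
200 placebo estimates at offsets ≥ 15 weeks; 20 seeded end-to-end pipeline
runs for the qualitative findings (news lifts exceed query lifts in most
nation-years, event-restricted r² exceeds full-series r², pooled query
lift exceeds a 0.10 New-Year lift). Recovery and placebo worlds run with
seasonality off so the measured error isolates the estimator from the
curvature bias quantified above, which is tested separately. Bootstrap
calibration runs use 2,000 replicates per interval (the exclusion rate is
insensitive beyond that); interactive defaults keep 10,000.

## Association and benchmarking choices

- The lagged regression puts lags 0, 1, 2 of the news rate into **one**
  multiple OLS of queries (complete-case after lag-shifting; a constant
  regressor at any lag is a rank error naming the lag); per-lag simple
  regressions are also reported since "the r² at lags 0–2" can be read
  either way. The event-restricted r² refits on the union over years of
  ±13 weeks (~3 months) around the anchor week.
- Effect ratios (query lift / news lift) are defined only for positive
  news lifts; undefined nation-years are excluded and counted. The summary
  is median + IQR.
- New Year effects support two baselines: the local ±12-week reference, or
  the *awareness day's* reference windows of the same calendar year, which
  puts both events over one denominator (the comparison the application
  calls for). The common-baseline variant deliberately includes the
  seasonal difference between January and the awareness-day season — that
  difference is part of what "bigger than New Year" means on a common
  scale.
- The tax-equivalence regression takes tax increases (percentage points,
  all effective Jan 1) as the **response** and New-Year-period effects as
  the predictor, so the prediction at a target effect is directly a tax
  percentage with a mean-prediction CI; years without an increase enter at
  0 (the New Year recurs; the tax is what varies). The reverse orientation
  (invert the fitted line, delta-method CI) is available behind a flag.
  Because which stream should anchor the comparison is itself open, the
  pipeline computes the equivalence per metric and reports both. Every tax
  change rode on top of whatever the New Year was already doing; that
  caveat is attached to the result object and always printed in the
  report, not adjusted for.

## Pipeline

`run_full_evaluation` chains simulate (or load) → estimate → pool →
associate → benchmark → report. Every per-estimate random seed derives
deterministically from the run seed and the (nation, metric, year) labels,
so reruns are byte-identical and stage outputs can be regenerated in
isolation; every number in `report.md` is read back from the stage
CSV/JSON files rather than recomputed. Exclusions (un-locatable windows,
e.g. missing years) and reference truncations are logged and tabulated in
the report. Plots (series with event shading, a forest plot) are a
convenience behind `make_plots` and require matplotlib.
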