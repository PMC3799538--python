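# infopulse

Pulse-effect interrupted time-series evaluation of calendar-anchored health
events — awareness days, New Year's Day, tax changes — on digital
surveillance streams: news coverage rates and Internet search queries.

Annual surveys cannot see what a single awareness day does; its footprint
lives at daily-to-weekly resolution. `infopulse` is built for the
infoveillance setting where two streams are cheap to monitor per nation:
weekly counts of news stories on a topic (expressed per 100,000 of all
stories) and relative search volume (RSV: a query share rescaled so its
maximum week is 100, the scale Trends-style exports use). The motivating
application is World No Tobacco Day (May 31) and smoking-cessation
news/queries across seven Latin American nations, 2006–2011, but every
piece is generic over the anchor date and topic.

## The statistic

Because a global awareness day leaves no untreated control nations, each
nation is its own counterfactual in time. For a series $y_t$ and an event
year, let $E$ be the 3-week event window (the week containing the anchor,
plus one week either side) and $R$ the 12 weeks on each side of $E$. The
pulse effect is the dimensionless ratio

$$\hat\delta = \frac{\bar y_E}{\bar y_R} - 1,
\qquad H_0\colon\; \frac{\bar y_E - \bar y_R}{\bar y_R} = 0 ,$$

comparable across nations with different baselines (0.40 = a 40% lift).
Default confidence intervals are Welch-t delta-method intervals for the
ratio of means (bootstrap variants are selectable; with only three
event-window observations the percentile bootstrap is anticonservative —
see `docs/methods.md`). Nation-year estimates are pooled (overall, by
nation, by year) with the pooled CI built from the component CIs. Around
the core estimator sit:

- a **synthetic-data generator** emulating the two streams with seasonality,
  a New Year pulse, an awareness-day pulse (news builds up over the prior
  month; query interest persists a week after), news→query coupling, noise,
  Trends-style integer renormalization, and missing nation-years — with
  exact ground truth for every injected effect;
- **lagged regression** of queries on news (lags 0–2 weeks), with $r^2$ over
  the full series and restricted to ±13 weeks around the event;
- **effect ratios** (query lift / news lift) summarizing diminishing returns
  of coverage on interest;
- **policy benchmarks**: the same pulse design at Jan 1, and a cross-year
  regression of cigarette excise-tax increases on New-Year-period effects,
  evaluated at the pooled awareness-day effect to express it as an
  equivalent tax increase;
- **placebo scans** re-estimating the pulse at shifted anchor dates as an
  empirical null.

## Worked example

```python
from infopulse import (PulseWindowSpec, SyntheticConfig, estimate_pulse_effect,
                       pool_effects, simulate_world)

config = SyntheticConfig(seed=7)          # 7 nations, 2006-2011 study conditions
world = simulate_world(config)
spec = PulseWindowSpec.wntd()             # May 31 anchor, 3-week event, +/-12-week reference

estimates = [estimate_pulse_effect(world.query_rsv[n], spec, y)
             for n in config.nations for y in config.available_years(n)]
overall = pool_effects(estimates, "overall")[0]
print(f"pooled query effect: {100 * overall.effect:.0f}% "
      f"(95% CI {100 * overall.ci_low:.0f} to {100 * overall.ci_high:.0f})")
```

prints

```
pooled query effect: 34% (95% CI 26 to 43)
```

— across 36 nation-years, search interest in the event window sits about a
third above the flanking-weeks baseline, and the interval excludes zero.
The scripts in `examples/` walk through each capability (panel transforms,
simulation, estimation and pooling, association, policy benchmarking, the
full pipeline); `examples/06_full_pipeline.py` runs everything into a
report bundle:

```
pooled news_rate: 35.1% (22.5 to 47.7), k=36
pooled query_rsv: 30.4% (23.5 to 37.3), k=36
query/news ratio median: 0.88
tax equivalence (query_rsv): 3.6%
```

The same pipeline is exposed as a thin CLI:

```bash
infopulse run-all --seed 11 --outdir runs/demo     # simulate -> ... -> report.md
infopulse simulate --seed 11 --outdir panels/      # stage-by-stage variants:
infopulse estimate --panels panels/ --out effects.csv
infopulse pool --effects effects.csv --group nation --out pooled.csv
```

Exit codes: 0 ok, 1 configuration error, 2 data error. Reruns with the
same seed and config are byte-identical.

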