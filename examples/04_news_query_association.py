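"""Quantify how news coverage relates to search interest.

Two views: (1) OLS of queries on news at lags 0-2 weeks, with r² over the
whole series and restricted to ±13 weeks around the awareness day; (2) the
ratio of each nation-year's query effect to its news effect — ratios below
1 mean coverage lifts outrun interest lifts (diminishing returns).
"""

from infopulse import (
    Metric,
    PulseWindowSpec,
    SyntheticConfig,
    effect_ratio,
    estimate_pulse_effect,
    lagged_regression,
    simulate_world,
    summarize_effect_ratios,
)
from infopulse.timeseries import align_panels

config = SyntheticConfig(seed=3)
world = simulate_world(config)
spec = PulseWindowSpec.wntd()

print("nation       r2_full  r2_event   (event-restricted window fits better when")
print("                                  the news->query link is event-local)")
for nation in config.nations[:4]:
    news, queries = align_panels([world.news_rate(nation), world.query_rsv[nation]])
    res = lagged_regression(news, queries)
    print(f"{nation:<12} {res.r2_full:7.3f} {res.r2_wntd:9.3f}")

ratios = []
for nation in config.nations:
    for year in config.available_years(nation):
        news_est = estimate_pulse_effect(world.news_rate(nation), spec, year)
        query_est = estimate_pulse_effect(world.query_rsv[nation], spec, year)
        if news_est.effect > 0:
            ratios.append(effect_ratio(news_est, query_est))

summary = summarize_effect_ratios(ratios)
print(f"\nquery/news effect ratio: median {summary['median']:.2f} "
      f"(IQR {summary['q1']:.2f}-{summary['q3']:.2f}, n={summary['n']}) — "
      "a median near 0.5 would mean a doubling of news coverage goes with "
      "roughly a 50% rise in queries.")
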