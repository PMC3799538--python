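"""Generate a synthetic seven-nation study with known injected effects.

The generator emulates weekly cessation-news counts and max-normalized
query series for 2006-2011 with seasonality, a New Year pulse, an
awareness-day pulse at May 31 (news building up over the prior month), and
news->query coupling; three nations lack 2006-2007 coverage.
"""

import numpy as np

from infopulse import SyntheticConfig, simulate_world

config = SyntheticConfig(seed=42)
world = simulate_world(config)

mexico = world.query_rsv["Mexico"]
print(f"Mexico query panel: {len(mexico)} weeks, "
      f"{mexico.dates[0].date()} .. {mexico.dates[-1].date()}, "
      f"max RSV {np.nanmax(mexico.values):.0f}")
chile = world.query_rsv["Chile"]
print(f"Chile panel starts {chile.dates[0].date()} (2006-2007 unavailable)")

rate = world.news_rate("Mexico")
print(f"Mexico news rate: mean {np.nanmean(rate.values):.1f} per 100,000 stories")

truth = world.ground_truth()
print("\nInjected ground truth (first rows):")
print(truth.head(4).to_string(index=False))
print("\n'lift' is the direct pulse parameter; 'design_effect' is the value the")
print("two-mean window estimator should recover under a flat baseline.")
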