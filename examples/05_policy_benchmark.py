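"""Benchmark the awareness-day lift against New Year's Day and tax increases.

New Year effects use the same pulse design anchored at Jan 1 (here against
the awareness day's reference baseline, so both lifts share a denominator).
Regressing tax increases on New-Year-period effects across years and
evaluating the line at the pooled awareness-day effect reads off the tax
increase with an equivalent short-run lift in cessation interest.
"""

from infopulse import (
    PulseWindowSpec,
    SyntheticConfig,
    default_tax_events,
    estimate_pulse_effect,
    new_year_effect,
    pool_effects,
    simulate_world,
    tax_equivalence,
)

config = SyntheticConfig(seed=12)
world = simulate_world(config)
spec = PulseWindowSpec.wntd()
panel = world.query_rsv["Mexico"]

ny_effects = {}
for year in config.years():
    ny_effects[year] = new_year_effect(panel, year, baseline="wntd_reference")
print("Mexico New-Year query effects (vs the awareness-day baseline):")
for year, est in ny_effects.items():
    print(f"  {year}: {100 * est.effect:6.1f}%")

estimates = [estimate_pulse_effect(world.query_rsv[n], spec, y)
             for n in config.nations for y in config.available_years(n)]
target = pool_effects(estimates, "overall")[0]
print(f"\npooled awareness-day query effect: {100 * target.effect:.1f}%")

eq = tax_equivalence(ny_effects, default_tax_events(), target)
print(f"equivalent cigarette excise-tax increase: {eq.equivalent_tax_pct:.1f}% "
      f"(95% CI {eq.ci_low:.1f} to {eq.ci_high:.1f}, {eq.n_years} years)")
print(f"\n{eq.note}")
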