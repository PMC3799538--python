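"""Pulse-effect estimator, CI behavior, pooling arithmetic and placebo scans."""

import dataclasses
import datetime

import numpy as np
import pytest
from scipy import stats

from infopulse.estimation import (
    CISettings,
    EffectEstimate,
    estimate_pulse_effect,
    placebo_scan,
    pool_effects,
)
from infopulse.exceptions import ConfigError, UndefinedEffectError
from infopulse.synthetic import SyntheticConfig, simulate_query_series, simulate_world
from infopulse.timeseries import Metric, PulseWindowSpec, locate_event_window, normalize_rsv

from conftest import weekly_panel

WNTD = PulseWindowSpec.wntd()


def panel_with_windows(event_values, ref_value=50.0, ref_values=None):
    """52-week 2008 panel with prescribed event-window and reference values."""
    panel = weekly_panel(np.full(52, ref_value))
    win = locate_event_window(panel, WNTD, 2008)
    values = panel.values.copy()
    if ref_values is not None:
        values[win.reference] = ref_values
    values[win.event] = event_values
    return panel.with_values(values)


def make_estimate(effect, var, nation="Mexico", year=2008, metric="query_rsv",
                  n_before=12, n_after=12, level=0.95):
    half = stats.norm.ppf(0.5 + level / 2) * np.sqrt(var)
    return EffectEstimate(
        nation=nation, year=year, metric=metric, effect=effect,
        ci_low=effect - half, ci_high=effect + half, mean_event=0.0, mean_reference=1.0,
        n_event=3, n_reference=n_before + n_after, n_reference_before=n_before,
        n_reference_after=n_after, truncated_reference=False, ci_level=level,
    )


# -- point estimate ----------------------------------------------------------


def test_effect_is_event_over_reference_minus_one():
    est = estimate_pulse_effect(panel_with_windows([85.0, 85.0, 85.0]), WNTD, 2008)
    assert est.effect == pytest.approx(0.70, abs=1e-12)
    assert est.mean_event == pytest.approx(85.0)
    assert est.mean_reference == pytest.approx(50.0)
    assert est.n_event == 3 and est.n_reference == 24


def test_flat_series_effect_zero_ci_contains_zero():
    for method in ("delta", "bootstrap", "percentile"):
        est = estimate_pulse_effect(
            weekly_panel(np.full(52, 50.0)), WNTD, 2008,
            CISettings(method=method, reps=500, seed=0),
        )
        assert est.effect == pytest.approx(0.0, abs=1e-12)
        assert est.ci_low <= 0.0 <= est.ci_high


def test_alternating_reference_same_means_gives_zero():
    ref = np.tile([40.0, 60.0], 12)  # mean 50
    est = estimate_pulse_effect(
        panel_with_windows([55.0, 50.0, 45.0], ref_values=ref), WNTD, 2008
    )
    # independent two-mean oracle
    assert est.effect == pytest.approx(np.mean([55, 50, 45]) / np.mean(ref) - 1, abs=1e-12)
    assert est.effect == pytest.approx(0.0, abs=1e-12)


def test_brute_force_two_mean_oracle_on_random_panels():
    rng = np.random.default_rng(11)
    for _ in range(25):
        n = int(rng.integers(31, 61))
        start_shift = int(rng.integers(0, 5))
        vals = rng.uniform(1.0, 100.0, n)
        panel = weekly_panel(vals, start=datetime.date(2008, 1, 6)
                             + datetime.timedelta(weeks=start_shift))
        try:
            est = estimate_pulse_effect(panel, WNTD, 2008)
        except UndefinedEffectError:
            continue
        # oracle: membership by explicit date arithmetic, means by plain sums
        anchor = datetime.date(2008, 5, 31)
        ws = anchor - datetime.timedelta(days=(anchor.weekday() + 1) % 7)
        starts = [d.date() for d in panel.dates]
        center = starts.index(ws)
        ev = [vals[i] for i in (center - 1, center, center + 1)]
        rf = [vals[i] for i in range(max(0, center - 13), center - 1)]
        rf += [vals[i] for i in range(center + 2, min(n, center + 14))]
        oracle = (sum(ev) / len(ev)) / (sum(rf) / len(rf)) - 1
        assert est.effect == pytest.approx(oracle, abs=1e-12)


def test_zero_reference_mean_raises():
    with pytest.raises(UndefinedEffectError):
        estimate_pulse_effect(panel_with_windows([5.0, 5.0, 5.0], ref_value=0.0), WNTD, 2008)


def test_missing_values_are_dropped_not_zeroed():
    panel = panel_with_windows([80.0, np.nan, 90.0])
    est = estimate_pulse_effect(panel, WNTD, 2008)
    assert est.mean_event == pytest.approx(85.0)
    assert est.n_event == 2


# -- CI properties -----------------------------------------------------------


@pytest.mark.parametrize("method", ["delta", "bootstrap", "percentile"])
def test_scale_invariance_of_effect_and_ci(method):
    rng = np.random.default_rng(3)
    vals = rng.uniform(20.0, 80.0, 52)
    ci = CISettings(method=method, reps=1000, seed=99)
    a = estimate_pulse_effect(weekly_panel(vals, metric=Metric.NEWS_RATE), WNTD, 2008, ci)
    # powers of two rescale exactly in binary floating point: bitwise equality
    b = estimate_pulse_effect(weekly_panel(vals * 8.0, metric=Metric.NEWS_RATE), WNTD, 2008, ci)
    assert b.effect == a.effect
    assert b.ci_low == a.ci_low and b.ci_high == a.ci_high
    # arbitrary positive constants agree to rounding error
    c = estimate_pulse_effect(weekly_panel(vals * 7.3, metric=Metric.NEWS_RATE), WNTD, 2008, ci)
    assert c.effect == pytest.approx(a.effect, rel=1e-12)
    assert c.ci_low == pytest.approx(a.ci_low, rel=1e-9, abs=1e-12)
    assert c.ci_high == pytest.approx(a.ci_high, rel=1e-9, abs=1e-12)


def test_ci_orders_and_contains_point_estimate():
    rng = np.random.default_rng(4)
    for method in ("delta", "bootstrap", "percentile"):
        vals = 50.0 + rng.normal(0, 5, 52)
        est = estimate_pulse_effect(weekly_panel(vals), WNTD, 2008,
                                    CISettings(method=method, reps=500, seed=1))
        assert est.ci_low <= est.effect <= est.ci_high


def test_default_ci_is_calibrated_when_reference_design_holds():
    """Null exclusion of the default interval sits near its nominal 5% on a
    flat-baseline world (no pulse, no seasonal curvature), within the 3-8%
    binomial band around nominal over ~6000 panels."""
    excl = n = 0
    base = SyntheticConfig(wntd_pulse=0.0, wntd_news_pulse=0.0, query_news_coupling=0.0,
                           seasonal_amplitude=0.0, noise_cv=0.1)
    for ws in range(168):
        cfg = dataclasses.replace(base, seed=20_000 + ws)
        panels = simulate_query_series(cfg)
        for nation in cfg.nations:
            for year in cfg.available_years(nation):
                est = estimate_pulse_effect(panels[nation], WNTD, year)
                n += 1
                excl += est.ci_low > 0 or est.ci_high < 0
    assert n >= 6000
    assert 0.03 <= excl / n <= 0.08, f"null exclusion {excl / n:.3f} over {n} panels"


def test_seasonal_curvature_bias_matches_closed_form():
    """An annual sinusoid is not locally linear over the +/-15-week reference
    span: the two-mean design carries a deterministic bias whose closed form
    is (1 + c_ev*A*cos(theta)) / (1 + c_ref*A*cos(theta)) - 1, with c_ev and
    c_ref the cosine attenuation of event and reference averaging."""
    cfg = SyntheticConfig(nations=("Mexico",), wntd_pulse=0.0, wntd_news_pulse=0.0,
                          newyear_pulse=0.0, query_news_coupling=0.0, noise_cv=0.0,
                          quantize=False, seasonal_amplitude=0.10,
                          missing_nation_years=frozenset())
    est = estimate_pulse_effect(simulate_query_series(cfg)["Mexico"], WNTD, 2008)
    omega = 2 * np.pi * 7 / 365.25
    c_ev = np.mean([np.cos(omega * k) for k in (-1, 0, 1)])
    c_ref = np.mean([np.cos(omega * k) for k in range(-13, 14) if abs(k) >= 2])
    theta = 2 * np.pi * (datetime.date(2008, 5, 25) - datetime.date(2008, 1, 1)).days / 365.25
    a_cos = cfg.seasonal_amplitude * np.cos(theta)
    closed_form = (1 + c_ev * a_cos) / (1 + c_ref * a_cos) - 1
    assert est.effect == pytest.approx(closed_form, abs=0.003)
    assert est.effect < -0.03  # the bias is material at amplitude 0.10


def test_quantization_shifts_estimate_less_than_002_at_baseline_30():
    rng = np.random.default_rng(12)
    for _ in range(10):
        raw = weekly_panel(rng.uniform(30.0, 95.0, 52), metric=Metric.NEWS_CESSATION_COUNT)
        exact = estimate_pulse_effect(normalize_rsv(raw), WNTD, 2008).effect
        quant = estimate_pulse_effect(normalize_rsv(raw, quantize=True), WNTD, 2008).effect
        assert abs(exact - quant) < 0.02


# -- pooling -----------------------------------------------------------------


@pytest.mark.parametrize("method", ["mean", "inverse_variance"])
def test_two_identical_estimates_halve_the_variance(method):
    e = make_estimate(0.4, 0.01)
    pooled = pool_effects([e, dataclasses.replace(e, year=2009)], "overall", method=method)[0]
    assert pooled.effect == pytest.approx(0.4)
    half = (pooled.ci_high - pooled.ci_low) / 2
    assert (half / stats.norm.ppf(0.975)) ** 2 == pytest.approx(0.005, rel=1e-9)
    assert pooled.k == 2


def test_single_estimate_pools_to_itself():
    e = make_estimate(0.37, 0.02)
    pooled = pool_effects([e], "overall")[0]
    assert (pooled.effect, pooled.ci_low, pooled.ci_high) == (e.effect, e.ci_low, e.ci_high)
    assert pooled.k == 1


def test_inverse_variance_weighting_closed_form():
    ests = [make_estimate(0.2, 0.01), make_estimate(0.6, 0.04, year=2009)]
    pooled = pool_effects(ests, "overall", method="inverse_variance")[0]
    assert pooled.effect == pytest.approx((0.2 / 0.01 + 0.6 / 0.04) / (1 / 0.01 + 1 / 0.04))
    assert pooled.effect == pytest.approx(0.28)


def test_pooled_ci_never_wider_than_widest_component():
    rng = np.random.default_rng(8)
    ests = [make_estimate(float(rng.normal(0.4, 0.1)), float(rng.uniform(0.005, 0.05)),
                          year=2006 + i) for i in range(6)]
    widths = [e.ci_high - e.ci_low for e in ests]
    for method in ("mean", "inverse_variance"):
        pooled = pool_effects(ests, "overall", method=method)[0]
        assert pooled.ci_high - pooled.ci_low <= max(widths) + 1e-12


def test_grouping_by_nation_and_year():
    ests = [make_estimate(0.2, 0.01, nation="Mexico", year=2008),
            make_estimate(0.4, 0.01, nation="Mexico", year=2009),
            make_estimate(0.6, 0.01, nation="Peru", year=2008)]
    by_nation = {p.key: p for p in pool_effects(ests, "by_nation")}
    assert by_nation["Mexico"].k == 2 and by_nation["Peru"].k == 1
    assert by_nation["Mexico"].effect == pytest.approx(0.3)
    by_year = {p.key: p for p in pool_effects(ests, "by_year")}
    assert by_year["2008"].k == 2
    with pytest.raises(ConfigError):
        pool_effects(ests, "by_planet")


def test_short_reference_estimates_are_excluded_from_pooling():
    good = make_estimate(0.2, 0.01)
    short = make_estimate(0.9, 0.01, year=2009, n_before=5)
    pooled = pool_effects([good, short], "overall")[0]
    assert pooled.k == 1 and pooled.n_excluded == 1
    assert pooled.effect == pytest.approx(0.2)
    both = pool_effects([good, short], "overall", min_reference_per_side=5)[0]
    assert both.k == 2


def test_zero_variance_component_is_floored_and_flagged():
    exact = make_estimate(0.3, 0.0)
    noisy = make_estimate(0.5, 0.01, year=2009)
    pooled = pool_effects([exact, noisy], "overall", method="inverse_variance")[0]
    assert pooled.variance_floored
    assert 0.3 <= pooled.effect <= 0.5


def test_empty_pooling_raises():
    with pytest.raises(UndefinedEffectError):
        pool_effects([], "overall")


# -- placebo scan ------------------------------------------------------------


def test_placebo_offset_zero_equals_standard_estimate():
    rng = np.random.default_rng(5)
    panel = weekly_panel(rng.uniform(20, 80, 52))
    ci = CISettings(seed=7)
    [shifted] = placebo_scan(panel, WNTD, 2008, offsets=[0], ci=ci)
    direct = estimate_pulse_effect(panel, WNTD, 2008, ci=ci)
    assert shifted.effect == direct.effect
    assert (shifted.ci_low, shifted.ci_high) == (direct.ci_low, direct.ci_high)


def test_placebo_on_flat_series_is_zero_at_any_offset():
    panel = weekly_panel(np.full(80, 40.0), start=datetime.date(2007, 11, 4))
    for est in placebo_scan(panel, WNTD, 2008, offsets=[-6, -2, 3, 8]):
        assert est.effect == pytest.approx(0.0, abs=1e-12)


def test_placebo_far_from_an_injected_pulse_is_null():
    cfg = SyntheticConfig(nations=("Mexico",), wntd_pulse=0.4, wntd_news_pulse=0.0,
                          query_news_coupling=0.0, seasonal_amplitude=0.0,
                          newyear_pulse=0.0, noise_cv=0.1, seed=77,
                          missing_nation_years=frozenset())
    panel = simulate_query_series(cfg)["Mexico"]
    noise_se = 0.1 * np.sqrt(1 / 3 + 1 / 24)
    for est in placebo_scan(panel, WNTD, 2008, offsets=[-20, 20]):
        assert abs(est.effect) < 3 * noise_se
    on_target = estimate_pulse_effect(panel, WNTD, 2008)
    assert on_target.effect > 0.2
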