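"""Panel containers, rate/RSV transforms, window geometry and CSV round trips."""

import datetime

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from infopulse.exceptions import (
    AlignmentError,
    DegenerateSeriesError,
    PanelFormatError,
    PanelValidationError,
    UndefinedRateError,
    WindowError,
)
from infopulse.timeseries import (
    Metric,
    PulseWindowSpec,
    Resolution,
    TimeSeriesPanel,
    compute_news_rate,
    locate_event_window,
    normalize_rsv,
    read_panel_csv,
    week_start,
    write_panel_csv,
)

from conftest import daily_panel, weekly_panel


# -- panel invariants --------------------------------------------------------


def test_panel_rejects_structural_violations():
    good = pd.date_range("2008-01-06", periods=3, freq="7D")
    with pytest.raises(PanelValidationError):
        TimeSeriesPanel("Mexico", Metric.QUERY_RSV, Resolution.WEEKLY,
                        good[[0, 2, 1]], np.ones(3))
    uneven = pd.DatetimeIndex(["2008-01-06", "2008-01-13", "2008-01-21"])
    with pytest.raises(PanelValidationError):
        TimeSeriesPanel("Mexico", Metric.QUERY_RSV, Resolution.WEEKLY, uneven, np.ones(3))
    with pytest.raises(PanelValidationError):
        weekly_panel([1.0, -0.5, 2.0])
    with pytest.raises(PanelValidationError):
        weekly_panel([50.0, 101.0, 20.0])  # RSV bounded by 100
    # same values are fine under a count metric
    weekly_panel([50.0, 101.0, 20.0], metric=Metric.NEWS_CESSATION_COUNT)


def test_panel_allows_missing_and_weekly_weekday_is_shared():
    p = weekly_panel([1.0, np.nan, 3.0])
    assert np.isnan(p.values[1])
    assert p.week_start_weekday == 6  # Sunday


# -- news rate ---------------------------------------------------------------


@pytest.mark.parametrize(
    "cessation, total, expected",
    [(147.0, 100_000.0, 147.0), (0.0, 5000.0, 0.0), (3.0, 40_000.0, 7.5)],
)
def test_news_rate_per_100k(cessation, total, expected):
    cess = weekly_panel([cessation], metric=Metric.NEWS_CESSATION_COUNT)
    tot = weekly_panel([total], metric=Metric.NEWS_TOTAL_COUNT)
    rate = compute_news_rate(cess, tot)
    assert rate.metric is Metric.NEWS_RATE
    assert rate.values[0] == pytest.approx(expected, abs=1e-12)


def test_news_rate_missing_and_error_handling():
    cess = weekly_panel([2.0, np.nan, 0.0], metric=Metric.NEWS_CESSATION_COUNT)
    tot = weekly_panel([1000.0, 1000.0, 0.0], metric=Metric.NEWS_TOTAL_COUNT)
    rate = compute_news_rate(cess, tot)
    assert np.isnan(rate.values[1])  # missing numerator
    assert np.isnan(rate.values[2])  # zero total, zero cessation -> missing
    bad_tot = weekly_panel([0.0, 1000.0, 10.0], metric=Metric.NEWS_TOTAL_COUNT)
    with pytest.raises(UndefinedRateError):
        compute_news_rate(cess, bad_tot)
    shifted = weekly_panel([2.0, 1.0, 0.0], start=datetime.date(2008, 1, 13),
                           metric=Metric.NEWS_TOTAL_COUNT)
    with pytest.raises(AlignmentError):
        compute_news_rate(cess, shifted)


def test_news_rate_linear_in_numerator_and_scale_free_in_paired_rescaling():
    rng = np.random.default_rng(7)
    cess_vals = rng.integers(0, 50, 30).astype(float)
    tot_vals = rng.integers(1000, 5000, 30).astype(float)
    cess = weekly_panel(cess_vals, metric=Metric.NEWS_CESSATION_COUNT)
    tot = weekly_panel(tot_vals, metric=Metric.NEWS_TOTAL_COUNT)
    base = compute_news_rate(cess, tot).values
    doubled = compute_news_rate(cess.with_values(2 * cess_vals), tot).values
    np.testing.assert_allclose(doubled, 2 * base, rtol=1e-12)
    both = compute_news_rate(
        cess.with_values(3 * cess_vals), tot.with_values(3 * tot_vals)
    ).values
    np.testing.assert_allclose(both, base, rtol=1e-12)


# -- RSV normalization -------------------------------------------------------


@pytest.mark.parametrize(
    "raw, quantize, expected",
    [
        ([2, 4, 1], False, [50.0, 100.0, 25.0]),
        ([7, 7, 7], False, [100.0, 100.0, 100.0]),
        ([1, 3], True, [33.0, 100.0]),  # half-up integer rounding
    ],
)
def test_normalize_rsv_examples(raw, quantize, expected):
    out = normalize_rsv(
        weekly_panel(raw, metric=Metric.NEWS_CESSATION_COUNT), quantize=quantize
    )
    assert out.metric is Metric.QUERY_RSV
    np.testing.assert_allclose(out.values, expected)


def test_normalize_rsv_degenerate_series_raises():
    with pytest.raises(DegenerateSeriesError):
        normalize_rsv(weekly_panel([0.0, 0.0], metric=Metric.NEWS_CESSATION_COUNT))


@settings(derandomize=True, max_examples=50)
@given(
    raw=st.lists(st.floats(0, 1e6, allow_nan=False), min_size=2, max_size=30).filter(
        lambda xs: max(xs) > 0
    ),
    scale=st.floats(1e-3, 1e3, allow_nan=False),
)
def test_normalize_rsv_idempotent_and_scale_invariant(raw, scale):
    panel = weekly_panel(raw, metric=Metric.NEWS_CESSATION_COUNT)
    once = normalize_rsv(panel)
    twice = normalize_rsv(once)
    np.testing.assert_allclose(twice.values, once.values, rtol=1e-12, atol=1e-12)
    scaled = normalize_rsv(panel.with_values(np.asarray(raw) * scale))
    np.testing.assert_allclose(scaled.values, once.values, rtol=1e-9, atol=1e-9)
    assert np.nanmax(once.values) == pytest.approx(100.0)


# -- window geometry ---------------------------------------------------------


def test_wntd_window_weekly_2008(year_2008_panel):
    spec = PulseWindowSpec.wntd()
    win = locate_event_window(year_2008_panel, spec, 2008)
    event_dates = year_2008_panel.dates[win.event]
    # the week containing 2008-05-31 starts Sunday 2008-05-25
    assert pd.Timestamp("2008-05-25") in event_dates
    assert len(win.event) == 3
    assert len(win.reference) == 2 * spec.reference_halfwidth_weeks
    assert not win.truncated
    assert set(win.event).isdisjoint(win.reference)


def test_reference_truncation_is_flagged():
    # panel starts 10 weeks before the event window: 10 + 3 + 12 weeks
    start = week_start(datetime.date(2008, 5, 31)) - datetime.timedelta(weeks=11)
    panel = weekly_panel(np.full(25, 5.0), start=start)
    win = locate_event_window(panel, PulseWindowSpec.wntd(), 2008)
    assert len(win.reference_before) == 10
    assert win.truncated_before and not win.truncated_after
    assert len(win.reference_after) == 12


def test_daily_event_window_spans_15_days():
    start = datetime.date(2008, 1, 1)
    panel = daily_panel(np.full(366, 5.0), start=start)
    spec = PulseWindowSpec.wntd(daily_event_halfwidth_days=7)
    win = locate_event_window(panel, spec, 2008)
    assert len(win.event) == 15
    center = panel.dates[win.event][7]
    assert center == pd.Timestamp("2008-05-31")


def test_anchor_outside_span_raises(year_2008_panel):
    with pytest.raises(WindowError):
        locate_event_window(year_2008_panel, PulseWindowSpec.wntd(), 2010)


@pytest.mark.parametrize("ehw,rhw", [(0, 4), (1, 12), (2, 8)])
def test_windows_disjoint_and_complete(ehw, rhw):
    panel = weekly_panel(np.full(80, 5.0), start=datetime.date(2007, 11, 4))
    spec = PulseWindowSpec.wntd(event_halfwidth_weeks=ehw, reference_halfwidth_weeks=rhw)
    win = locate_event_window(panel, spec, 2008)
    assert len(win.event) == 2 * ehw + 1
    assert len(win.reference) == 2 * rhw
    assert set(win.event).isdisjoint(win.reference)


# -- CSV I/O -----------------------------------------------------------------


def test_panel_csv_round_trip(tmp_path):
    panel = weekly_panel([10.0, np.nan, 100.0, 32.5])
    path = tmp_path / "panel.csv"
    write_panel_csv(panel, path)
    back = read_panel_csv(path)
    assert back.nation == panel.nation
    assert back.metric is panel.metric
    assert back.resolution is panel.resolution
    assert back.dates.equals(panel.dates)
    np.testing.assert_array_equal(np.isnan(back.values), np.isnan(panel.values))
    np.testing.assert_allclose(back.values[~np.isnan(back.values)],
                               panel.values[~np.isnan(panel.values)])


@pytest.mark.parametrize(
    "rows, message_part",
    [
        (["2008-01-13,5", "2008-01-06,6"], "out of order"),
        (["not-a-date,5"], "malformed date"),
        (["2008-01-06,-3"], "negative"),
        (["2008-01-06,101"], "query_rsv"),
    ],
)
def test_panel_csv_parse_errors_name_the_problem(tmp_path, rows, message_part):
    path = tmp_path / "bad.csv"
    path.write_text(
        "\n".join(
            ["# nation=Mexico", "# metric=query_rsv", "# resolution=weekly", "date,value", *rows]
        )
    )
    with pytest.raises(PanelFormatError, match=message_part):
        read_panel_csv(path)
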