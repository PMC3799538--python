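"""Core time-series containers, calendar arithmetic, transforms and CSV I/O.

The common currency of the package is the :class:`TimeSeriesPanel`: one
nation, one metric, one evenly spaced daily or weekly date grid.  Weekly
panels are keyed by week-start dates; the default convention is that weeks
start on Sunday, matching Google-Trends-style exports.  Missing observations
are carried as NaN and are never silently zero-filled — an observed zero and
a missing week mean different things.

Two transforms defined here underpin the whole analysis:

* :func:`compute_news_rate` — cessation-story counts over total-story counts,
  reported per 100,000 stories.
* :func:`normalize_rsv` — relative search volume: a series rescaled so its
  maximum period equals 100 (the scale Google Insights/Trends exports use),
  optionally quantized to integers as those exports are.

Window geometry for the pulse-effect design (the event window around an
anchor date such as May 31, and the flanking reference windows) also lives
here, in :class:`PulseWindowSpec` and :func:`locate_event_window`.
"""

from __future__ import annotations

import dataclasses
import datetime
import enum
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    DegenerateSeriesError,
    PanelFormatError,
    PanelValidationError,
    UndefinedRateError,
    WindowError,
)

#: Stories denominator for news rates ("per 100,000 stories").
RATE_PER_STORIES = 100_000

#: Python ``date.weekday()`` code for Sunday (Monday == 0).
SUNDAY = 6


class Metric(str, enum.Enum):
    """What a panel's values measure."""

    QUERY_RSV = "query_rsv"
    NEWS_RATE = "news_rate"
    NEWS_CESSATION_COUNT = "news_cessation_count"
    NEWS_TOTAL_COUNT = "news_total_count"


class Resolution(str, enum.Enum):
    DAILY = "daily"
    WEEKLY = "weekly"

    @property
    def step_days(self) -> int:
        return 7 if self is Resolution.WEEKLY else 1


def week_start(day: datetime.date, week_start_weekday: int = SUNDAY) -> datetime.date:
    """Return the start date of the week containing ``day``.

    ``week_start_weekday`` uses Python's Monday=0 convention; the default is
    Sunday, the Google-Trends export convention.
    """
    return day - datetime.timedelta(days=(day.weekday() - week_start_weekday) % 7)


@dataclasses.dataclass(frozen=True)
class TimeSeriesPanel:
    """One nation × one metric × one evenly spaced date grid.

    Parameters
    ----------
    nation : str
        Nation label.
    metric : Metric
        What the values measure.
    resolution : Resolution
        Daily or weekly; weekly panels are keyed by week-start dates.
    dates : pandas.DatetimeIndex
        Strictly increasing, evenly spaced at the resolution's step.
    values : numpy.ndarray
        Non-negative floats; NaN marks a missing observation.  RSV panels
        are additionally bounded above by 100.
    """

    nation: str
    metric: Metric
    resolution: Resolution
    dates: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "metric", Metric(self.metric))
        object.__setattr__(self, "resolution", Resolution(self.resolution))
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "values", values)
        if len(dates) == 0:
            raise PanelValidationError("panel must contain at least one period")
        if len(dates) != len(values):
            raise PanelValidationError(
                f"dates ({len(dates)}) and values ({len(values)}) differ in length"
            )
        step = np.timedelta64(self.resolution.step_days, "D")
        diffs = np.diff(dates.values)
        if len(diffs) and not np.all(diffs == step):
            bad = int(np.flatnonzero(diffs != step)[0])
            raise PanelValidationError(
                f"dates must be strictly increasing and evenly spaced at "
                f"{self.resolution.value} resolution; violation after row {bad} "
                f"({dates[bad].date()} -> {dates[bad + 1].date()})"
            )
        finite = values[~np.isnan(values)]
        if np.any(finite < 0):
            raise PanelValidationError(f"negative value in panel {self.nation}/{self.metric.value}")
        if self.metric is Metric.QUERY_RSV and np.any(finite > 100 + 1e-9):
            raise PanelValidationError(
                f"query_rsv value above 100 in panel {self.nation}"
            )

    # -- convenience accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def week_start_weekday(self) -> int:
        """Weekday (Monday=0) shared by all dates of a weekly panel."""
        return int(self.dates[0].weekday())

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.dates, name=self.metric.value)

    def with_values(self, values: np.ndarray, metric: Metric | None = None) -> "TimeSeriesPanel":
        return TimeSeriesPanel(
            nation=self.nation,
            metric=self.metric if metric is None else metric,
            resolution=self.resolution,
            dates=self.dates,
            values=np.asarray(values, dtype=float),
        )

    def index_of(self, day: datetime.date) -> int:
        """Position of the period containing ``day``; raises WindowError outside the span."""
        ts = pd.Timestamp(day)
        if self.resolution is Resolution.WEEKLY:
            ts = pd.Timestamp(week_start(ts.date(), self.week_start_weekday))
        pos = self.dates.searchsorted(ts)
        if pos >= len(self.dates) or self.dates[pos] != ts:
            raise WindowError(
                f"date {day} (period start {ts.date()}) outside panel span "
                f"{self.dates[0].date()}..{self.dates[-1].date()} for {self.nation}"
            )
        return int(pos)


# -- window geometry ---------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class PulseWindowSpec:
    """Anchor rule plus event/reference window geometry for a pulse design.

    The event window is the period containing the anchor date plus
    ``event_halfwidth_weeks`` periods on each side (3 weeks total by default:
    week before, week of, week after).  The reference windows are
    ``reference_halfwidth_weeks`` periods immediately before the event window
    and the same number immediately after (12 each side by default).
    """

    anchor_month: int
    anchor_day: int
    event_halfwidth_weeks: int = 1
    reference_halfwidth_weeks: int = 12
    daily_event_halfwidth_days: int = 7

    def __post_init__(self) -> None:
        if self.event_halfwidth_weeks < 0:
            raise PanelValidationError("event_halfwidth_weeks must be >= 0")
        if self.reference_halfwidth_weeks < 1:
            raise PanelValidationError("reference_halfwidth_weeks must be >= 1")
        if self.daily_event_halfwidth_days < 0:
            raise PanelValidationError("daily_event_halfwidth_days must be >= 0")
        datetime.date(2000, self.anchor_month, self.anchor_day)  # validates month/day

    @classmethod
    def wntd(cls, **kw) -> "PulseWindowSpec":
        """World No Tobacco Day: May 31."""
        return cls(anchor_month=5, anchor_day=31, **kw)

    @classmethod
    def new_year(cls, **kw) -> "PulseWindowSpec":
        """New Year's Day: January 1."""
        return cls(anchor_month=1, anchor_day=1, **kw)

    def anchor_date(self, year: int) -> datetime.date:
        return datetime.date(year, self.anchor_month, self.anchor_day)


@dataclasses.dataclass(frozen=True)
class WindowIndices:
    """Integer positions of event and reference periods within a panel."""

    event: np.ndarray
    reference_before: np.ndarray
    reference_after: np.ndarray
    truncated_before: bool
    truncated_after: bool

    @property
    def reference(self) -> np.ndarray:
        return np.concatenate([self.reference_before, self.reference_after])

    @property
    def truncated(self) -> bool:
        return self.truncated_before or self.truncated_after


def locate_event_window(
    panel: TimeSeriesPanel,
    spec: PulseWindowSpec,
    year: int,
    anchor_override: datetime.date | None = None,
) -> WindowIndices:
    """Locate the event and reference windows for ``year`` in ``panel``.

    The event window must be fully covered by the panel; reference windows
    truncated at panel edges are returned truncated with the corresponding
    flag set (the caller decides whether a truncated design is acceptable).
    ``anchor_override`` replaces the spec's calendar anchor with an explicit
    date — used by placebo scans.
    """
    anchor = anchor_override if anchor_override is not None else spec.anchor_date(year)
    center = panel.index_of(anchor)
    n = len(panel)
    if panel.resolution is Resolution.WEEKLY:
        ehw = spec.event_halfwidth_weeks
        rhw = spec.reference_halfwidth_weeks
    else:
        ehw = spec.daily_event_halfwidth_days
        rhw = spec.reference_halfwidth_weeks * 7
    lo, hi = center - ehw, center + ehw
    if lo < 0 or hi >= n:
        raise WindowError(
            f"event window around {anchor} extends beyond panel span for {panel.nation}"
        )
    event = np.arange(lo, hi + 1)
    before = np.arange(max(0, lo - rhw), lo)
    after = np.arange(hi + 1, min(n, hi + 1 + rhw))
    return WindowIndices(
        event=event,
        reference_before=before,
        reference_after=after,
        truncated_before=len(before) < rhw,
        truncated_after=len(after) < rhw,
    )


# -- transforms --------------------------------------------------------------


def compute_news_rate(
    cessation_counts: TimeSeriesPanel, total_counts: TimeSeriesPanel
) -> TimeSeriesPanel:
    """Cessation stories per 100,000 total stories.

    Both panels must share nation, resolution and an identical date grid.
    The rate is missing wherever either input is missing, and wherever both
    counts are zero (no stories at all that period); a zero total with a
    positive cessation count is a contradiction and raises.
    """
    if cessation_counts.nation != total_counts.nation:
        raise AlignmentError(
            f"nation mismatch: {cessation_counts.nation} vs {total_counts.nation}"
        )
    if cessation_counts.resolution is not total_counts.resolution:
        raise AlignmentError("resolution mismatch between count panels")
    if not cessation_counts.dates.equals(total_counts.dates):
        raise AlignmentError(
            f"date grids differ between cessation and total counts for "
            f"{cessation_counts.nation}"
        )
    cess = cessation_counts.values
    tot = total_counts.values
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = cess / tot * RATE_PER_STORIES
    zero_tot = tot == 0
    if np.any(zero_tot & (cess > 0)):
        week = cessation_counts.dates[np.flatnonzero(zero_tot & (cess > 0))[0]].date()
        raise UndefinedRateError(
            f"zero total stories with positive cessation count at {week} "
            f"for {cessation_counts.nation}"
        )
    rate[zero_tot] = np.nan
    return cessation_counts.with_values(rate, metric=Metric.NEWS_RATE)


def normalize_rsv(raw: TimeSeriesPanel, quantize: bool = False) -> TimeSeriesPanel:
    """Rescale a non-negative series to relative search volume (max period = 100).

    With ``quantize`` the result is rounded half-up to integers, emulating
    Trends-style exports; the maximum period always maps to exactly 100.
    """
    values = raw.values
    finite = values[~np.isnan(values)]
    if len(finite) == 0 or np.nanmax(values) <= 0:
        raise DegenerateSeriesError(
            f"all-zero or all-missing series cannot be normalized ({raw.nation})"
        )
    rsv = values / np.nanmax(values) * 100.0
    if quantize:
        rsv = np.floor(rsv + 0.5)  # round half-up
    return raw.with_values(rsv, metric=Metric.QUERY_RSV)


# -- CSV I/O -----------------------------------------------------------------
#
# Panel CSV format: three comment header lines carrying the metadata, then
# ordinary date,value rows with ISO-8601 dates and an empty value field for
# missing observations:
#
#   # nation=Mexico
#   # metric=query_rsv
#   # resolution=weekly
#   date,value
#   2008-01-06,47
#   2008-01-13,


def write_panel_csv(panel: TimeSeriesPanel, path: str | Path) -> None:
    path = Path(path)
    lines = [
        f"# nation={panel.nation}",
        f"# metric={panel.metric.value}",
        f"# resolution={panel.resolution.value}",
        "date,value",
    ]
    for ts, v in zip(panel.dates, panel.values):
        val = "" if np.isnan(v) else f"{v:.10g}"
        lines.append(f"{ts.date().isoformat()},{val}")
    path.write_text("\n".join(lines) + "\n")


def read_panel_csv(path: str | Path) -> TimeSeriesPanel:
    path = Path(path)
    text = path.read_text().splitlines()
    meta: dict[str, str] = {}
    body_start = 0
    for i, line in enumerate(text):
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition("=")
            meta[key.strip()] = val.strip()
        else:
            body_start = i
            break
    for key in ("nation", "metric", "resolution"):
        if key not in meta:
            raise PanelFormatError(f"{path}: missing '{key}' header line")
    if body_start >= len(text) or text[body_start].strip() != "date,value":
        raise PanelFormatError(f"{path}: expected 'date,value' column header")
    dates: list[pd.Timestamp] = []
    values: list[float] = []
    for row_no, line in enumerate(text[body_start + 1 :], start=body_start + 2):
        if not line.strip():
            continue
        date_s, _, val_s = line.partition(",")
        try:
            ts = pd.Timestamp(datetime.date.fromisoformat(date_s.strip()))
        except ValueError as exc:
            raise PanelFormatError(f"{path}:{row_no}: malformed date {date_s!r}") from exc
        if dates and ts <= dates[-1]:
            raise PanelFormatError(f"{path}:{row_no}: dates out of order at {date_s}")
        if val_s.strip() == "":
            v = np.nan
        else:
            try:
                v = float(val_s)
            except ValueError as exc:
                raise PanelFormatError(f"{path}:{row_no}: malformed value {val_s!r}") from exc
            if v < 0:
                raise PanelFormatError(f"{path}:{row_no}: negative value {v}")
        dates.append(ts)
        values.append(v)
    try:
        return TimeSeriesPanel(
            nation=meta["nation"],
            metric=Metric(meta["metric"]),
            resolution=Resolution(meta["resolution"]),
            dates=pd.DatetimeIndex(dates),
            values=np.array(values, dtype=float),
        )
    except (ValueError, PanelValidationError) as exc:
        raise PanelFormatError(f"{path}: {exc}") from exc


def align_panels(panels: Iterable[TimeSeriesPanel]) -> list[TimeSeriesPanel]:
    """Restrict panels to their common date range (inner join on the grid)."""
    panels = list(panels)
    if not panels:
        return []
    common = panels[0].dates
    for p in panels[1:]:
        common = common.intersection(p.dates)
    if len(common) == 0:
        raise AlignmentError("panels share no dates")
    out = []
    for p in panels:
        mask = p.dates.isin(common)
        out.append(
            TimeSeriesPanel(
                nation=p.nation,
                metric=p.metric,
                resolution=p.resolution,
                dates=p.dates[mask],
                values=p.values[mask],
            )
        )
    return out
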