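"""News→query association: lagged regression and the effect-size ratio.

Does a lift in cessation news coverage translate into a lift in cessation
search queries?  Two complementary views:

* :func:`lagged_regression` — ordinary least squares of the query series on
  the news series at lags of 0, 1 and 2 weeks (jointly), reporting multiple
  r² over the full series and restricted to ±13 weeks (~3 months) around
  each year's awareness-day week.  Per-lag simple regressions are also
  reported since "the r² at lags 0–2" can be read either way.
* :func:`effect_ratio` — the ratio of a nation-year's query pulse effect to
  its news pulse effect; ratios below 1 mean news lifts outrun query lifts
  ("diminishing returns" of coverage on interest).
"""

from __future__ import annotations

import dataclasses
import datetime
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .estimation import EffectEstimate
from .exceptions import AlignmentError, DataError, RankDeficiencyError
from .timeseries import Metric, PulseWindowSpec, TimeSeriesPanel, week_start

MIN_COMPLETE_CASES = 10


@dataclasses.dataclass(frozen=True)
class LagRegressionResult:
    """Joint lagged OLS of queries on news, full-series and event-restricted."""

    nation: str
    lags: tuple[int, ...]
    coefficients: dict[int, float]
    intercept: float
    r2_full: float
    r2_wntd: float
    n_full: int
    n_wntd: int
    simple_r2: dict[int, float]


def _lag_design(
    news: TimeSeriesPanel, queries: TimeSeriesPanel, lags: Sequence[int]
) -> pd.DataFrame:
    if news.nation != queries.nation:
        raise AlignmentError(f"nation mismatch: {news.nation} vs {queries.nation}")
    if news.resolution is not queries.resolution:
        raise AlignmentError("resolution mismatch between news and query panels")
    y = queries.as_series()
    frame = {"query": y}
    x = news.as_series()
    for lag in lags:
        frame[f"news_lag{lag}"] = x.shift(lag)  # news at t - lag
    df = pd.DataFrame(frame).dropna()
    return df


def _restriction_mask(
    index: pd.DatetimeIndex, spec: PulseWindowSpec, halfwidth_weeks: int
) -> np.ndarray:
    """Union over years of ±halfwidth weeks around each year's anchor week."""
    mask = np.zeros(len(index), dtype=bool)
    wsd = int(index[0].weekday())
    for year in range(int(index[0].year), int(index[-1].year) + 1):
        anchor = pd.Timestamp(week_start(spec.anchor_date(year), wsd))
        delta = (index - anchor).days / 7.0
        mask |= np.abs(delta) <= halfwidth_weeks
    return mask


def lagged_regression(
    news: TimeSeriesPanel,
    queries: TimeSeriesPanel,
    lags: Sequence[int] = (0, 1, 2),
    spec: PulseWindowSpec | None = None,
    restrict_halfwidth_weeks: int = 13,
) -> LagRegressionResult:
    """OLS of queries on news lagged by ``lags`` weeks, jointly.

    Lag-induced edge periods and missing weeks are dropped (complete-case).
    ``r2_wntd`` refits the same model on periods within
    ``restrict_halfwidth_weeks`` weeks of the anchor week, unioned across
    years.  Raises if fewer than 10 complete cases remain or any lagged
    regressor is constant.
    """
    spec = spec or PulseWindowSpec.wntd()
    df = _lag_design(news, queries, lags)
    if len(df) < MIN_COMPLETE_CASES:
        raise DataError(
            f"only {len(df)} complete cases after lagging for {news.nation}; need "
            f">= {MIN_COMPLETE_CASES}"
        )
    for lag in lags:
        if np.isclose(df[f"news_lag{lag}"].std(), 0.0):
            raise RankDeficiencyError(f"news regressor constant at lag {lag} for {news.nation}")
    X = sm.add_constant(df[[f"news_lag{lag}" for lag in lags]])
    fit = sm.OLS(df["query"], X).fit()
    mask = _restriction_mask(pd.DatetimeIndex(df.index), spec, restrict_halfwidth_weeks)
    sub = df[mask]
    if len(sub) < len(lags) + 2:
        raise DataError(f"too few periods around the event window for {news.nation}")
    fit_sub = sm.OLS(sub["query"], sm.add_constant(sub[[f"news_lag{lag}" for lag in lags]])).fit()
    simple = {}
    for lag in lags:
        xs = sm.add_constant(df[[f"news_lag{lag}"]])
        simple[lag] = float(sm.OLS(df["query"], xs).fit().rsquared)
    return LagRegressionResult(
        nation=news.nation,
        lags=tuple(int(l) for l in lags),
        coefficients={int(l): float(fit.params[f"news_lag{l}"]) for l in lags},
        intercept=float(fit.params["const"]),
        r2_full=float(fit.rsquared),
        r2_wntd=float(fit_sub.rsquared),
        n_full=int(len(df)),
        n_wntd=int(len(sub)),
        simple_r2=simple,
    )


@dataclasses.dataclass(frozen=True)
class EffectRatio:
    """Query pulse effect over news pulse effect for one nation-year."""

    nation: str
    year: int
    news_effect: float
    query_effect: float
    ratio: float


def effect_ratio(news_effect: EffectEstimate, query_effect: EffectEstimate) -> EffectRatio:
    """Ratio of query to news pulse effects; undefined when news effect <= 0."""
    if (news_effect.nation, news_effect.year) != (query_effect.nation, query_effect.year):
        raise AlignmentError(
            f"effect estimates are for different nation-years: "
            f"{news_effect.nation}/{news_effect.year} vs {query_effect.nation}/{query_effect.year}"
        )
    if news_effect.metric != Metric.NEWS_RATE.value:
        raise DataError(f"news_effect has metric {news_effect.metric}")
    if query_effect.metric != Metric.QUERY_RSV.value:
        raise DataError(f"query_effect has metric {query_effect.metric}")
    if news_effect.effect <= 0:
        raise DataError(
            f"effect ratio undefined: news effect {news_effect.effect:.3f} <= 0 "
            f"for {news_effect.nation} {news_effect.year}"
        )
    return EffectRatio(
        nation=news_effect.nation,
        year=news_effect.year,
        news_effect=news_effect.effect,
        query_effect=query_effect.effect,
        ratio=query_effect.effect / news_effect.effect,
    )


def summarize_effect_ratios(ratios: Iterable[EffectRatio]) -> dict[str, float]:
    """Median and interquartile range of the query/news effect ratios."""
    vals = np.array([r.ratio for r in ratios], dtype=float)
    if len(vals) == 0:
        raise DataError("no defined effect ratios to summarize")
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3), "n": int(len(vals))}
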