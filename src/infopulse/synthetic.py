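"""Synthetic multi-nation news and search-query panels with known ground truth.

The generator emulates the statistical structure of the archives the analysis
is designed for — weekly cessation-news story counts (relative to total story
counts) and max-100-normalized relative search volume (RSV) per nation — so
that every downstream stage can be tested against injected effects.  It is a
stand-in for those archives, not a model fitted to them; distributional
choices (Poisson counts, log-normal query noise, sinusoidal seasonality) are
conventional minimal choices, documented in the methods note.

Structure of the data-generating process, per nation and week ``t``:

* news story mean:  ``N_total × p_base × season(t) × (1 + g_news·ramp(t)) × (1 + g_ny·ny(t))``
  where ``ramp`` rises linearly over the 4 weeks before the awareness-day
  week, peaks at 1 in the event week, and drops to a small tail the week
  after (news builds up for about a month and decays within days).
* query propensity: ``b × season(t) × (1 + g_ny·ny(t)) × (1 + g_query·event(t)) × anomaly(t)^κ × ε``
  where ``event`` is rectangular over the 3-week event window (week before,
  of, after — search interest persists for the week after the event),
  ``anomaly`` is the expected news pulse factor, ``κ`` the news→query
  coupling elasticity, and ``ε`` multiplicative log-normal noise.
  Query series are then max-100 normalized (and integer-quantized by
  default, as Trends-style exports are).

Pulse lifts can be scalars, per-nation maps, or per-(nation, year) maps;
:func:`ground_truth` tabulates the exact injected lifts for recovery tests.
"""

from __future__ import annotations

import dataclasses
import datetime
import zlib
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .timeseries import (
    Metric,
    Resolution,
    TimeSeriesPanel,
    compute_news_rate,
    normalize_rsv,
    week_start,
)

#: The seven study nations.
NATIONS = ("Mexico", "Colombia", "Argentina", "Peru", "Venezuela", "Chile", "Ecuador")

#: Nation-years without archive coverage in the emulated source.
DEFAULT_MISSING = frozenset(
    (nation, year) for nation in ("Ecuador", "Chile", "Colombia") for year in (2006, 2007)
)

#: News pulse shape by week offset from the awareness-day week: linear
#: buildup over the 4 preceding weeks, plateau in the event week, and a
#: small tail the week after (a 2–3 day decay seen at weekly resolution).
NEWS_PULSE_SHAPE: dict[int, float] = {-4: 0.2, -3: 0.4, -2: 0.6, -1: 0.8, 0: 1.0, 1: 0.3}

#: Query pulse shape: rectangular over the 3-week event window.
QUERY_PULSE_SHAPE: dict[int, float] = {-1: 1.0, 0: 1.0, 1: 1.0}

#: New Year pulse shape (both streams): rectangular over the 3 weeks around Jan 1.
NEWYEAR_PULSE_SHAPE: dict[int, float] = {-1: 1.0, 0: 1.0, 1: 1.0}

DAYS_PER_YEAR = 365.25

LiftSpec = float | Mapping[str, float] | Mapping[tuple[str, int], float]


def resolve_lift(spec: LiftSpec, nation: str, year: int) -> float:
    """Resolve a scalar / per-nation / per-(nation, year) lift specification."""
    if isinstance(spec, Mapping):
        if (nation, year) in spec:
            return float(spec[(nation, year)])
        if nation in spec:
            return float(spec[nation])
        return 0.0
    return float(spec)


def _max_lift(spec: LiftSpec) -> float:
    if isinstance(spec, Mapping):
        return max((float(v) for v in spec.values()), default=0.0)
    return float(spec)


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of the data-generating process.

    Defaults are calibrated to the magnitudes the analysis targets: a news
    pulse of +71% and a total query lift near +40% (direct +10% pulse
    amplified by news→query coupling κ = log2(1.5), i.e. a news doubling
    maps to a +50% query lift), a +10% New Year pulse on both streams,
    baseline news coverage near 17.5 cessation stories per 100,000, mild
    annual seasonality peaking at New Year, and 10% multiplicative query
    noise.  Three nations lack 2006–2007 coverage.
    """

    nations: tuple[str, ...] = NATIONS
    start_year: int = 2006
    end_year: int = 2011
    baseline_query_propensity: float | Mapping[str, float] = 50.0
    seasonal_amplitude: float = 0.10
    newyear_pulse: LiftSpec = 0.10
    wntd_pulse: LiftSpec = 0.10
    wntd_news_pulse: LiftSpec = 0.71
    news_total_weekly: int = 100_000
    news_base_rate: float = 1.75e-4
    noise_cv: float = 0.10
    query_news_coupling: float = float(np.log2(1.5))
    missing_nation_years: frozenset[tuple[str, int]] = DEFAULT_MISSING
    quantize: bool = True
    pad_weeks: int = 16
    anchor_month: int = 5
    anchor_day: int = 31
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "nations", tuple(self.nations))
        object.__setattr__(
            self, "missing_nation_years", frozenset(tuple(x) for x in self.missing_nation_years)
        )
        if self.start_year > self.end_year:
            raise ConfigError("start_year must not exceed end_year")
        if not (0 <= self.seasonal_amplitude < 1):
            raise ConfigError("seasonal_amplitude must lie in [0, 1)")
        for name, spec in (
            ("newyear_pulse", self.newyear_pulse),
            ("wntd_pulse", self.wntd_pulse),
            ("wntd_news_pulse", self.wntd_news_pulse),
        ):
            vals = spec.values() if isinstance(spec, Mapping) else [spec]
            if any(float(v) < 0 for v in vals):
                raise ConfigError(f"{name} lifts must be >= 0")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if self.query_news_coupling < 0:
            raise ConfigError("query_news_coupling must be >= 0")
        if self.news_total_weekly <= 0:
            raise ConfigError("news_total_weekly must be positive")
        baselines = (
            self.baseline_query_propensity.values()
            if isinstance(self.baseline_query_propensity, Mapping)
            else [self.baseline_query_propensity]
        )
        if any(float(b) <= 0 for b in baselines):
            raise ConfigError("baseline_query_propensity must be positive")
        peak_prob = (
            self.news_base_rate
            * (1 + self.seasonal_amplitude)
            * (1 + _max_lift(self.wntd_news_pulse))
            * (1 + _max_lift(self.newyear_pulse))
        )
        if not (0 < self.news_base_rate) or peak_prob > 1:
            raise ConfigError(
                f"news_base_rate with pulses yields story probability {peak_prob:.3g} > 1"
            )
        if self.pad_weeks < 14:
            # 12 reference weeks + event halfwidth + one spare
            raise ConfigError("pad_weeks must be >= 14 to cover reference windows")

    # -- per-nation helpers ---------------------------------------------------

    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)

    def available_years(self, nation: str) -> list[int]:
        return [y for y in self.years() if (nation, y) not in self.missing_nation_years]

    def baseline_for(self, nation: str) -> float:
        if isinstance(self.baseline_query_propensity, Mapping):
            return float(self.baseline_query_propensity[nation])
        return float(self.baseline_query_propensity)

    def week_grid(self, nation: str) -> pd.DatetimeIndex:
        years = self.available_years(nation)
        if not years:
            raise ConfigError(f"nation {nation} has no available years")
        first = week_start(datetime.date(min(years), 1, 1)) - datetime.timedelta(
            weeks=self.pad_weeks
        )
        last = week_start(datetime.date(max(years), 12, 31)) + datetime.timedelta(
            weeks=self.pad_weeks
        )
        return pd.date_range(first, last, freq="7D")


def _rng_for(config: SyntheticConfig, nation: str, stream: str) -> np.random.Generator:
    """Deterministic per-nation, per-stream substream: adding a nation or
    stream never perturbs the draws of another."""
    key = zlib.crc32(f"{nation}|{stream}".encode())
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), key]))


def _seasonal(config: SyntheticConfig, dates: pd.DatetimeIndex) -> np.ndarray:
    """Annual sinusoid with peak at New Year, amplitude ``seasonal_amplitude``."""
    jan1 = pd.to_datetime({"year": dates.year, "month": 1, "day": 1})
    frac = (dates - pd.DatetimeIndex(jan1)).days / DAYS_PER_YEAR
    return 1.0 + config.seasonal_amplitude * np.cos(2 * np.pi * frac.to_numpy())


def _pulse_factor(
    config: SyntheticConfig,
    nation: str,
    dates: pd.DatetimeIndex,
    shape: dict[int, float],
    lift_spec: LiftSpec,
    anchor_month: int,
    anchor_day: int,
    years: list[int],
) -> np.ndarray:
    """Multiplicative factor array ``1 + lift × shape`` around each year's anchor week."""
    factor = np.ones(len(dates))
    for year in years:
        lift = resolve_lift(lift_spec, nation, year)
        if lift == 0:
            continue
        anchor_week = pd.Timestamp(week_start(datetime.date(year, anchor_month, anchor_day)))
        pos = dates.searchsorted(anchor_week)
        if pos >= len(dates) or dates[pos] != anchor_week:
            continue
        for off, frac in shape.items():
            idx = pos + off
            if 0 <= idx < len(dates):
                factor[idx] *= 1.0 + lift * frac
    return factor


def _mask_missing_years(
    config: SyntheticConfig, nation: str, dates: pd.DatetimeIndex, values: np.ndarray
) -> np.ndarray:
    """NaN out weeks belonging to interior missing nation-years (leading and
    trailing missing years are already absent from the grid)."""
    missing = {y for (nat, y) in config.missing_nation_years if nat == nation}
    years = config.available_years(nation)
    interior = {y for y in missing if min(years) < y < max(years)}
    if interior:
        values = values.copy()
        values[np.isin(dates.year, list(interior))] = np.nan
    return values


def _expected_news_factor(
    config: SyntheticConfig, nation: str, dates: pd.DatetimeIndex
) -> np.ndarray:
    """Expected news pulse factor (awareness-day ramp × New Year pulse)."""
    years = config.available_years(nation)
    ny_years = list(range(min(years), max(years) + 2))
    wntd = _pulse_factor(
        config, nation, dates, NEWS_PULSE_SHAPE, config.wntd_news_pulse,
        config.anchor_month, config.anchor_day, years,
    )
    ny = _pulse_factor(
        config, nation, dates, NEWYEAR_PULSE_SHAPE, config.newyear_pulse, 1, 1, ny_years
    )
    return wntd * ny


def simulate_news_counts(
    config: SyntheticConfig,
) -> dict[str, tuple[TimeSeriesPanel, TimeSeriesPanel]]:
    """Weekly cessation-story and total-story count panels per nation.

    Cessation counts are Poisson around the structured mean when
    ``noise_cv > 0`` and equal to the mean exactly when ``noise_cv == 0``
    (the deterministic mode used by exact-recovery tests).  Total counts are
    a constant ``news_total_weekly``: the denominator is orders of magnitude
    larger than the numerator, so its sampling noise is negligible.
    """
    out: dict[str, tuple[TimeSeriesPanel, TimeSeriesPanel]] = {}
    for nation in config.nations:
        dates = config.week_grid(nation)
        mean = (
            config.news_total_weekly
            * config.news_base_rate
            * _seasonal(config, dates)
            * _expected_news_factor(config, nation, dates)
        )
        if config.noise_cv > 0:
            rng = _rng_for(config, nation, "news")
            counts = rng.poisson(mean).astype(float)
        else:
            counts = mean.astype(float)
        counts = _mask_missing_years(config, nation, dates, counts)
        totals = np.full(len(dates), float(config.news_total_weekly))
        totals = _mask_missing_years(config, nation, dates, totals)
        cess = TimeSeriesPanel(nation, Metric.NEWS_CESSATION_COUNT, Resolution.WEEKLY, dates, counts)
        tot = TimeSeriesPanel(nation, Metric.NEWS_TOTAL_COUNT, Resolution.WEEKLY, dates, totals)
        out[nation] = (cess, tot)
    return out


def simulate_query_series(config: SyntheticConfig) -> dict[str, TimeSeriesPanel]:
    """Weekly RSV query panels per nation.

    The latent propensity couples to the *expected* news anomaly raised to
    the coupling elasticity (so injected lifts stay closed-form), takes
    multiplicative log-normal noise with CV ``noise_cv``, and is then
    max-100 normalized (quantized to integers when ``config.quantize``).
    """
    out: dict[str, TimeSeriesPanel] = {}
    for nation in config.nations:
        dates = config.week_grid(nation)
        years = config.available_years(nation)
        ny_years = list(range(min(years), max(years) + 2))
        latent = (
            config.baseline_for(nation)
            * _seasonal(config, dates)
            * _pulse_factor(
                config, nation, dates, NEWYEAR_PULSE_SHAPE, config.newyear_pulse, 1, 1, ny_years
            )
            * _pulse_factor(
                config, nation, dates, QUERY_PULSE_SHAPE, config.wntd_pulse,
                config.anchor_month, config.anchor_day, years,
            )
        )
        if config.query_news_coupling > 0:
            anomaly = _expected_news_factor(config, nation, dates)
            latent = latent * anomaly**config.query_news_coupling
        if config.noise_cv > 0:
            rng = _rng_for(config, nation, "query")
            sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))
            latent = latent * rng.lognormal(-(sigma**2) / 2.0, sigma, len(dates))
        latent = _mask_missing_years(config, nation, dates, latent)
        # raw latent values exceed 100, so build under a count metric; the
        # normalization assigns the query_rsv metric and its 0-100 bound.
        raw = TimeSeriesPanel(nation, Metric.NEWS_CESSATION_COUNT, Resolution.WEEKLY, dates, latent)
        out[nation] = normalize_rsv(raw, quantize=config.quantize)
    return out


def ground_truth(config: SyntheticConfig) -> pd.DataFrame:
    """Exact injected lifts per nation-year-metric.

    Columns:

    ``lift``
        The direct pulse parameter (``wntd_pulse`` / ``wntd_news_pulse``).
    ``event_lift``
        The expected event-window mean lift the pulse design measures — for
        news this dilutes the peak over the ramp shape; for queries it folds
        in the coupling amplification from the news anomaly.
    ``design_effect``
        The population value of the two-mean ratio estimator under a flat
        baseline: event-window mean over reference-window mean minus 1,
        accounting for the news-ramp weeks that fall inside the ±12-week
        reference windows.  With coupling and news pulse off this equals
        ``lift`` exactly.
    """
    ref_offsets = [k for k in range(-13, 14) if abs(k) >= 2]
    rows = []
    for nation in config.nations:
        for year in config.available_years(nation):
            g_news = resolve_lift(config.wntd_news_pulse, nation, year)
            g_query = resolve_lift(config.wntd_pulse, nation, year)
            kappa = config.query_news_coupling
            news_factor = {k: 1.0 + g_news * NEWS_PULSE_SHAPE.get(k, 0.0) for k in range(-13, 14)}
            news_event = [news_factor[k] for k in (-1, 0, 1)]
            news_ref = [news_factor[k] for k in ref_offsets]
            query_event = [(1.0 + g_query) * a**kappa for a in news_event]
            query_ref = [a**kappa for a in news_ref]
            rows.append(
                dict(nation=nation, year=year, metric=Metric.NEWS_RATE.value,
                     lift=g_news, event_lift=float(np.mean(news_event)) - 1.0,
                     design_effect=float(np.mean(news_event) / np.mean(news_ref)) - 1.0)
            )
            rows.append(
                dict(nation=nation, year=year, metric=Metric.QUERY_RSV.value,
                     lift=g_query, event_lift=float(np.mean(query_event)) - 1.0,
                     design_effect=float(np.mean(query_event) / np.mean(query_ref)) - 1.0)
            )
    return pd.DataFrame(
        rows, columns=["nation", "year", "metric", "lift", "event_lift", "design_effect"]
    )


@dataclasses.dataclass(frozen=True)
class SyntheticWorld:
    """All panels from one generator run, plus the config that made them."""

    config: SyntheticConfig
    news_cessation: dict[str, TimeSeriesPanel]
    news_total: dict[str, TimeSeriesPanel]
    query_rsv: dict[str, TimeSeriesPanel]

    def news_rate(self, nation: str) -> TimeSeriesPanel:
        return compute_news_rate(self.news_cessation[nation], self.news_total[nation])

    def ground_truth(self) -> pd.DataFrame:
        return ground_truth(self.config)


def simulate_world(config: SyntheticConfig) -> SyntheticWorld:
    """Run the full generator: news counts and query RSV for every nation."""
    news = simulate_news_counts(config)
    queries = simulate_query_series(config)
    return SyntheticWorld(
        config=config,
        news_cessation={n: c for n, (c, _) in news.items()},
        news_total={n: t for n, (_, t) in news.items()},
        query_rsv=queries,
    )
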