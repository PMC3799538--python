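"""Policy benchmarking: New Year's Day pulses and cigarette-tax equivalence.

An awareness-day lift means little in isolation; this module expresses it
against two yardsticks:

* :func:`new_year_effect` — the same pulse design anchored at January 1,
  either with its own local ±12-week reference, or with the awareness day's
  reference window of the same year as the denominator so the two event
  lifts are measured against a common baseline.
* :func:`tax_equivalence` — cigarette excise-tax increases (which in the
  study setting all took effect on New Year's Day) regressed on the
  New-Year-period pulse effects across years; evaluating the fitted line at
  a target pulse effect reads off the tax increase with an equivalent
  short-run lift in cessation interest.  The equivalence is associational
  and confounded by the New Year itself: every tax hike rode on top of
  whatever New Year's resolutions were already doing, a caveat carried on
  the result object and surfaced in the pipeline report.
"""

from __future__ import annotations

import dataclasses
import datetime
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .estimation import CISettings, EffectEstimate, PooledEffect, ratio_effect_estimate
from .exceptions import ConfigError, DataError, RankDeficiencyError
from .timeseries import PulseWindowSpec, TimeSeriesPanel, locate_event_window

TAX_CONFOUNDING_NOTE = (
    "Tax-equivalence caveat: every tax increase took effect on New Year's Day, "
    "so its estimated lift includes any New Year's effect; the equivalence is "
    "associational and may overstate the tax increase needed to match the "
    "awareness-day lift."
)

#: Mexico's cigarette excise-tax increases (percentage points) effective Jan 1.
MEXICO_TAX_INCREASES = {2007: 4.7, 2008: 1.3, 2009: 1.2, 2011: 7.8}


@dataclasses.dataclass(frozen=True)
class TaxEvent:
    """One excise-tax increase taking effect on Jan 1 of ``year``."""

    nation: str
    year: int
    tax_increase_pct: float

    def __post_init__(self) -> None:
        if self.tax_increase_pct < 0:
            raise ConfigError("tax_increase_pct must be >= 0")


def default_tax_events(nation: str = "Mexico") -> list[TaxEvent]:
    return [TaxEvent(nation, y, pct) for y, pct in sorted(MEXICO_TAX_INCREASES.items())]


def read_tax_csv(path: str | Path) -> list[TaxEvent]:
    df = pd.read_csv(path)
    required = {"nation", "year", "tax_increase_pct"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: tax CSV must have columns {sorted(required)}")
    return [
        TaxEvent(str(r.nation), int(r.year), float(r.tax_increase_pct))
        for r in df.itertuples()
    ]


def write_tax_csv(events: Sequence[TaxEvent], path: str | Path) -> None:
    pd.DataFrame(
        [dataclasses.asdict(e) for e in events],
        columns=["nation", "year", "tax_increase_pct"],
    ).to_csv(path, index=False)


def new_year_effect(
    panel: TimeSeriesPanel,
    year: int,
    spec: PulseWindowSpec | None = None,
    baseline: str = "local_reference",
    wntd_spec: PulseWindowSpec | None = None,
    ci: CISettings | None = None,
) -> EffectEstimate:
    """Pulse effect around Jan 1 of ``year``.

    ``baseline="local_reference"`` uses the standard ±12-week reference
    around the New Year window; ``baseline="wntd_reference"`` divides by the
    mean of the *awareness day's* reference window of the same calendar
    year, putting New Year and awareness-day lifts on one common baseline.
    """
    spec = spec or PulseWindowSpec.new_year()
    ci = ci or CISettings()
    win = locate_event_window(panel, spec, year)
    ev = panel.values[win.event]
    ev = ev[~np.isnan(ev)]
    if len(ev) == 0:
        raise DataError(f"New Year event window all missing for {panel.nation} {year}")
    if baseline == "local_reference":
        rf = panel.values[win.reference]
        n_before, n_after = len(win.reference_before), len(win.reference_after)
        truncated = win.truncated
    elif baseline == "wntd_reference":
        wspec = wntd_spec or PulseWindowSpec.wntd(
            event_halfwidth_weeks=spec.event_halfwidth_weeks,
            reference_halfwidth_weeks=spec.reference_halfwidth_weeks,
        )
        wwin = locate_event_window(panel, wspec, year)
        rf = panel.values[wwin.reference]
        n_before, n_after = len(wwin.reference_before), len(wwin.reference_after)
        truncated = wwin.truncated
    else:
        raise ConfigError(f"unknown baseline {baseline!r}")
    rf = rf[~np.isnan(rf)]
    if len(rf) == 0:
        raise DataError(f"reference window all missing for {panel.nation} {year}")
    return ratio_effect_estimate(
        ev,
        rf,
        nation=panel.nation,
        year=year,
        metric=panel.metric.value,
        ci=ci,
        n_before=n_before,
        n_after=n_after,
        truncated=truncated,
    )


@dataclasses.dataclass(frozen=True)
class TaxEquivalence:
    """Tax increase whose New-Year-period lift matches a target pulse effect."""

    equivalent_tax_pct: float
    ci_low: float
    ci_high: float
    n_years: int
    intercept: float
    slope: float
    target_effect: float
    note: str = TAX_CONFOUNDING_NOTE


def tax_equivalence(
    new_year_effects: Mapping[int, EffectEstimate],
    tax_events: Sequence[TaxEvent],
    target_effect: float | PooledEffect,
    level: float = 0.95,
    orientation: str = "tax_on_effect",
) -> TaxEquivalence:
    """Cross-year regression of tax increases on New-Year pulse effects.

    Years without a tax increase enter with tax = 0 (the New Year happens
    every year; the tax is the treatment that varies).  With
    ``orientation="tax_on_effect"`` (default) the tax is the response, so
    the prediction at ``target_effect`` is directly a tax percentage and
    its CI is the mean-prediction interval.  The reverse orientation fits
    effect on tax and inverts the line, with a delta-method CI.
    """
    if orientation not in ("tax_on_effect", "effect_on_tax"):
        raise ConfigError(f"unknown orientation {orientation!r}")
    target = target_effect.effect if isinstance(target_effect, PooledEffect) else float(target_effect)
    taxes_by_year = {e.year: e.tax_increase_pct for e in tax_events}
    years = sorted(new_year_effects)
    if len(years) < 3:
        raise DataError(f"need >= 3 years with a New-Year effect; got {len(years)}")
    effects = np.array([new_year_effects[y].effect for y in years])
    taxes = np.array([taxes_by_year.get(y, 0.0) for y in years])
    if np.isclose(effects.std(), 0.0):
        raise RankDeficiencyError("New-Year effects have zero variance across years")
    if orientation == "tax_on_effect":
        X = sm.add_constant(pd.DataFrame({"effect": effects}))
        fit = sm.OLS(taxes, X).fit()
        pred = fit.get_prediction(pd.DataFrame({"const": [1.0], "effect": [target]}))
        lo, hi = (float(v) for v in pred.conf_int(alpha=1 - level)[0])
        return TaxEquivalence(
            equivalent_tax_pct=float(pred.predicted_mean[0]),
            ci_low=lo,
            ci_high=hi,
            n_years=len(years),
            intercept=float(fit.params.iloc[0]),
            slope=float(fit.params.iloc[1]),
            target_effect=target,
        )
    # effect on tax, inverted: tax* = (target - a) / b
    if np.isclose(taxes.std(), 0.0):
        raise RankDeficiencyError("tax increases have zero variance across years")
    X = sm.add_constant(pd.DataFrame({"tax": taxes}))
    fit = sm.OLS(effects, X).fit()
    a, b = float(fit.params.iloc[0]), float(fit.params.iloc[1])
    est = (target - a) / b
    # delta method on g(a, b) = (target - a) / b
    grad = np.array([-1.0 / b, -(target - a) / b**2])
    var = float(grad @ fit.cov_params().to_numpy() @ grad)
    from scipy import stats

    tcrit = stats.t.ppf(0.5 + level / 2, df=max(int(fit.df_resid), 1))
    half = tcrit * np.sqrt(max(var, 0.0))
    return TaxEquivalence(
        equivalent_tax_pct=float(est),
        ci_low=float(est - half),
        ci_high=float(est + half),
        n_years=len(years),
        intercept=a,
        slope=b,
        target_effect=target,
    )
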