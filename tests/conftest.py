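import datetime

import numpy as np
import pandas as pd
import pytest

from infopulse.timeseries import Metric, Resolution, TimeSeriesPanel

# 2008-01-06 is a Sunday: weekly fixtures follow the Sunday week-start convention.
SUNDAY_START = datetime.date(2008, 1, 6)


def weekly_panel(
    values,
    start: datetime.date = SUNDAY_START,
    nation: str = "Mexico",
    metric: Metric = Metric.QUERY_RSV,
) -> TimeSeriesPanel:
    values = np.asarray(values, dtype=float)
    dates = pd.date_range(start, periods=len(values), freq="7D")
    return TimeSeriesPanel(nation, metric, Resolution.WEEKLY, dates, values)


def daily_panel(values, start: datetime.date, nation="Mexico", metric=Metric.QUERY_RSV):
    values = np.asarray(values, dtype=float)
    dates = pd.date_range(start, periods=len(values), freq="D")
    return TimeSeriesPanel(nation, metric, Resolution.DAILY, dates, values)


@pytest.fixture
def year_2008_panel():
    """52 constant weeks covering all of 2008 (week starts 2008-01-06 .. 2008-12-28)."""
    return weekly_panel(np.full(52, 50.0))
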