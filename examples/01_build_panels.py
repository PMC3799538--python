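"""Build news-rate and RSV panels from raw counts and write them to CSV.

The two transforms shown here define the scales the whole analysis runs on:
cessation stories per 100,000 total stories, and relative search volume
(series max-normalized to 100, integer-quantized like a Trends export).
"""

import datetime
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from infopulse import (
    Metric,
    Resolution,
    TimeSeriesPanel,
    compute_news_rate,
    normalize_rsv,
    read_panel_csv,
    write_panel_csv,
)

weeks = pd.date_range(datetime.date(2008, 1, 6), periods=8, freq="7D")  # Sunday starts
cessation = TimeSeriesPanel("Mexico", Metric.NEWS_CESSATION_COUNT, Resolution.WEEKLY,
                            weeks, np.array([12, 15, 9, 40, 33, 14, 11, 13.0]))
total = TimeSeriesPanel("Mexico", Metric.NEWS_TOTAL_COUNT, Resolution.WEEKLY,
                        weeks, np.full(8, 80_000.0))

rate = compute_news_rate(cessation, total)
print("news rate (per 100,000 stories):", np.round(rate.values, 1))
# e.g. 12/80000 * 1e5 = 15.0 -- the peak weeks stand out on a comparable scale

searches = TimeSeriesPanel("Mexico", Metric.NEWS_CESSATION_COUNT, Resolution.WEEKLY,
                           weeks, np.array([0.8, 0.9, 0.7, 2.0, 1.6, 0.9, 0.8, 0.85]))
rsv = normalize_rsv(searches, quantize=True)
print("relative search volume (max week = 100):", rsv.values)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "Mexico_query_rsv.csv"
    write_panel_csv(rsv, path)
    print("\nCSV round trip preserves the panel:",
          np.array_equal(read_panel_csv(path).values, rsv.values))
    print(path.read_text().splitlines()[0:5])
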