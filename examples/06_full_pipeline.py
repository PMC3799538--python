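"""Run the whole evaluation in one call and inspect the report bundle.

Equivalent to ``infopulse run-all --seed 2024 --outdir ...`` on the command
line.  The run directory holds every stage output (panel CSVs, effects,
pooled effects, regressions, benchmark JSON) plus report.md assembled from
them, and reruns with the same seed are byte-identical.
"""

import tempfile
from pathlib import Path

from infopulse import RunConfig, run_full_evaluation

with tempfile.TemporaryDirectory() as tmp:
    config = RunConfig(outdir=str(Path(tmp) / "run"), seed=2024, log_level="WARNING")
    result = run_full_evaluation(config)

    print("stage outputs:", sorted(p.name for p in result.outdir.iterdir()))
    for p in result.pooled:
        if p.grouping == "overall":
            print(f"pooled {p.metric}: {100 * p.effect:.1f}% "
                  f"({100 * p.ci_low:.1f} to {100 * p.ci_high:.1f}), k={p.k}")
    print("query/news ratio median:", round(result.ratios_summary["median"], 2))
    for metric, eq in result.benchmark["tax_equivalence"].items():
        print(f"tax equivalence ({metric}): {eq['equivalent_tax_pct']:.1f}%")
    print("\nreport preview:")
    print("\n".join(result.report_path.read_text().splitlines()[:8]))
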