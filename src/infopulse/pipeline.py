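"""End-to-end evaluation pipeline: simulate → estimate → pool → associate → benchmark → report.

The pipeline is a thin, deterministic orchestration of the library stages.
Every number in the report is read back from the stage CSV/JSON outputs, so
each table row is traceable to a stage artifact, and a rerun with the same
:class:`RunConfig` (and software version) reproduces byte-identical outputs.
Window truncations and nation-year exclusions are logged prominently —
silently dropping estimates is the one way the pooled results can be biased
without any individual number being wrong.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import association, benchmark, estimation, synthetic, timeseries
from .association import LagRegressionResult, effect_ratio, lagged_regression, summarize_effect_ratios
from .benchmark import TaxEvent, new_year_effect, tax_equivalence
from .estimation import CISettings, EffectEstimate, PooledEffect, estimate_pulse_effect, pool_effects
from .exceptions import ConfigError, DataError, InfopulseError, WindowError
from .synthetic import SyntheticConfig, SyntheticWorld, simulate_world
from .timeseries import Metric, PulseWindowSpec, TimeSeriesPanel, read_panel_csv, write_panel_csv

log = logging.getLogger("infopulse")

EFFECT_COLUMNS = [
    "nation", "year", "metric", "effect", "ci_low", "ci_high", "mean_event",
    "mean_reference", "n_event", "n_reference", "n_reference_before",
    "n_reference_after", "truncated_reference", "ci_method", "ci_level",
]


def derive_seed(seed: int, *parts: str) -> int:
    """Deterministic sub-seed below 2**31, stable in the labels, not in ordering."""
    key = zlib.crc32("|".join(parts).encode())
    return int(np.random.SeedSequence([int(seed), key]).generate_state(1)[0] % 2**31)


@dataclasses.dataclass
class RunConfig:
    """Fully serializable configuration of one evaluation run."""

    synthetic: SyntheticConfig = dataclasses.field(default_factory=SyntheticConfig)
    input_dir: str | None = None  # load panel CSVs instead of simulating
    event_halfwidth_weeks: int = 1
    reference_halfwidth_weeks: int = 12
    ci: CISettings = dataclasses.field(default_factory=CISettings)
    lags: tuple[int, ...] = (0, 1, 2)
    restrict_halfwidth_weeks: int = 13
    min_reference_per_side: int = 8
    pooling_method: str = "mean"
    tax_nation: str = "Mexico"
    tax_events: list[TaxEvent] = dataclasses.field(default_factory=benchmark.default_tax_events)
    new_year_baseline: str = "wntd_reference"
    outdir: str = "infopulse_run"
    seed: int = 0
    log_level: str = "INFO"
    make_plots: bool = False

    def __post_init__(self) -> None:
        if not self.synthetic.nations and self.input_dir is None:
            raise ConfigError("no nations configured and no input directory given")

    def wntd_spec(self) -> PulseWindowSpec:
        return PulseWindowSpec(
            anchor_month=self.synthetic.anchor_month,
            anchor_day=self.synthetic.anchor_day,
            event_halfwidth_weeks=self.event_halfwidth_weeks,
            reference_halfwidth_weeks=self.reference_halfwidth_weeks,
        )

    def new_year_spec(self) -> PulseWindowSpec:
        return PulseWindowSpec.new_year(
            event_halfwidth_weeks=self.event_halfwidth_weeks,
            reference_halfwidth_weeks=self.reference_halfwidth_weeks,
        )

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        syn = d["synthetic"]
        syn["missing_nation_years"] = sorted(
            [list(x) for x in self.synthetic.missing_nation_years]
        )
        syn["nations"] = list(self.synthetic.nations)
        for key in ("wntd_pulse", "wntd_news_pulse", "newyear_pulse"):
            val = syn[key]
            if isinstance(val, Mapping):
                syn[key] = {
                    (k if isinstance(k, str) else f"{k[0]}:{k[1]}"): v for k, v in val.items()
                }
        d["ci"] = dataclasses.asdict(self.ci)
        d["tax_events"] = [dataclasses.asdict(e) for e in self.tax_events]
        d["lags"] = list(self.lags)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            syn = dict(d["synthetic"])
            if "missing_nation_years" in syn:
                syn["missing_nation_years"] = frozenset(
                    (str(n), int(y)) for n, y in syn["missing_nation_years"]
                )
            for key in ("wntd_pulse", "wntd_news_pulse", "newyear_pulse"):
                val = syn.get(key)
                if isinstance(val, Mapping):
                    parsed = {}
                    for k, v in val.items():
                        if ":" in str(k):
                            nat, _, yr = str(k).partition(":")
                            parsed[(nat, int(yr))] = float(v)
                        else:
                            parsed[str(k)] = float(v)
                    syn[key] = parsed
            d["synthetic"] = SyntheticConfig(**syn)
        if "ci" in d and isinstance(d["ci"], dict):
            d["ci"] = CISettings(**d["ci"])
        if "tax_events" in d:
            d["tax_events"] = [
                e if isinstance(e, TaxEvent) else TaxEvent(**e) for e in d["tax_events"]
            ]
        if "lags" in d:
            d["lags"] = tuple(int(l) for l in d["lags"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# -- panel collection --------------------------------------------------------


def world_panels(world: SyntheticWorld) -> dict[str, dict[str, TimeSeriesPanel]]:
    """Nation → metric-name → panel, with news rates derived from counts."""
    out: dict[str, dict[str, TimeSeriesPanel]] = {}
    for nation in world.config.nations:
        out[nation] = {
            Metric.NEWS_CESSATION_COUNT.value: world.news_cessation[nation],
            Metric.NEWS_TOTAL_COUNT.value: world.news_total[nation],
            Metric.NEWS_RATE.value: world.news_rate(nation),
            Metric.QUERY_RSV.value: world.query_rsv[nation],
        }
    return out


def load_panels(input_dir: str | Path) -> dict[str, dict[str, TimeSeriesPanel]]:
    """Read every panel CSV under ``input_dir``; derive news rates from counts."""
    out: dict[str, dict[str, TimeSeriesPanel]] = {}
    paths = sorted(Path(input_dir).glob("*.csv"))
    if not paths:
        raise DataError(f"no panel CSVs found under {input_dir}")
    for path in paths:
        if path.name in ("ground_truth.csv", "taxes.csv"):
            continue
        panel = read_panel_csv(path)
        out.setdefault(panel.nation, {})[panel.metric.value] = panel
    for nation, metrics in out.items():
        if (
            Metric.NEWS_RATE.value not in metrics
            and Metric.NEWS_CESSATION_COUNT.value in metrics
            and Metric.NEWS_TOTAL_COUNT.value in metrics
        ):
            metrics[Metric.NEWS_RATE.value] = timeseries.compute_news_rate(
                metrics[Metric.NEWS_CESSATION_COUNT.value],
                metrics[Metric.NEWS_TOTAL_COUNT.value],
            )
    return out


def write_panels(panels: dict[str, dict[str, TimeSeriesPanel]], outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for nation in sorted(panels):
        for metric in sorted(panels[nation]):
            path = outdir / f"{nation}_{metric}.csv"
            write_panel_csv(panels[nation][metric], path)
            written.append(path)
    return written


# -- stages ------------------------------------------------------------------


def estimate_all_effects(
    panels: dict[str, dict[str, TimeSeriesPanel]],
    spec: PulseWindowSpec,
    years: range,
    ci: CISettings,
    seed: int,
    metrics: tuple[str, ...] = (Metric.NEWS_RATE.value, Metric.QUERY_RSV.value),
) -> tuple[list[EffectEstimate], list[dict]]:
    """Per nation-year-metric pulse effects, with an exclusion log for
    nation-years whose windows cannot be located (e.g. missing years)."""
    estimates: list[EffectEstimate] = []
    exclusions: list[dict] = []
    for nation in sorted(panels):
        for metric in metrics:
            if metric not in panels[nation]:
                continue
            panel = panels[nation][metric]
            for year in years:
                est_ci = dataclasses.replace(ci, seed=derive_seed(seed, nation, metric, str(year)))
                try:
                    est = estimate_pulse_effect(panel, spec, year, ci=est_ci)
                except InfopulseError as exc:
                    exclusions.append(
                        dict(nation=nation, metric=metric, year=year, reason=str(exc))
                    )
                    log.warning("excluded %s/%s/%s: %s", nation, metric, year, exc)
                    continue
                if est.truncated_reference:
                    log.warning(
                        "truncated reference for %s/%s/%s (%d before, %d after)",
                        nation, metric, year, est.n_reference_before, est.n_reference_after,
                    )
                estimates.append(est)
    if not estimates:
        raise DataError("no pulse effects could be estimated")
    return estimates, exclusions


def effects_to_frame(estimates: list[EffectEstimate]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(e) for e in estimates], columns=EFFECT_COLUMNS)


def pooled_to_frame(pooled: list[PooledEffect]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(p) for p in pooled])


def associate_all(
    panels: dict[str, dict[str, TimeSeriesPanel]],
    estimates: list[EffectEstimate],
    config: RunConfig,
) -> tuple[list[LagRegressionResult], list, dict, list[dict]]:
    """Lagged regressions per nation plus per-nation-year effect ratios."""
    regressions = []
    for nation in sorted(panels):
        metrics = panels[nation]
        if Metric.NEWS_RATE.value not in metrics or Metric.QUERY_RSV.value not in metrics:
            continue
        news, queries = timeseries.align_panels(
            [metrics[Metric.NEWS_RATE.value], metrics[Metric.QUERY_RSV.value]]
        )
        regressions.append(
            lagged_regression(
                news, queries, lags=config.lags, spec=config.wntd_spec(),
                restrict_halfwidth_weeks=config.restrict_halfwidth_weeks,
            )
        )
    by_key = {(e.nation, e.year, e.metric): e for e in estimates}
    ratios, undefined = [], []
    for (nation, year, metric), est in sorted(by_key.items()):
        if metric != Metric.NEWS_RATE.value:
            continue
        query_est = by_key.get((nation, year, Metric.QUERY_RSV.value))
        if query_est is None:
            continue
        try:
            ratios.append(effect_ratio(est, query_est))
        except DataError as exc:
            undefined.append(dict(nation=nation, year=year, reason=str(exc)))
            log.warning("effect ratio undefined for %s/%s: %s", nation, year, exc)
    summary = summarize_effect_ratios(ratios) if ratios else {}
    return regressions, ratios, summary, undefined


def benchmark_all(
    panels: dict[str, dict[str, TimeSeriesPanel]],
    pooled_overall: list[PooledEffect],
    config: RunConfig,
) -> dict:
    """New Year effects for the tax nation and per-metric tax equivalences."""
    nation = config.tax_nation
    if nation not in panels:
        raise ConfigError(f"tax nation {nation!r} has no panels")
    ny_spec = config.new_year_spec()
    wntd_spec = config.wntd_spec()
    result: dict = {"new_year_effects": [], "tax_equivalence": {}, "note": benchmark.TAX_CONFOUNDING_NOTE}
    pooled_by_metric = {p.metric: p for p in pooled_overall}
    for metric in (Metric.QUERY_RSV.value, Metric.NEWS_RATE.value):
        if metric not in panels[nation] or metric not in pooled_by_metric:
            continue
        panel = panels[nation][metric]
        ny_effects: dict[int, EffectEstimate] = {}
        for year in range(config.synthetic.start_year, config.synthetic.end_year + 1):
            ci = dataclasses.replace(
                config.ci, seed=derive_seed(config.seed, "newyear", nation, metric, str(year))
            )
            try:
                ny_effects[year] = new_year_effect(
                    panel, year, spec=ny_spec, baseline=config.new_year_baseline,
                    wntd_spec=wntd_spec, ci=ci,
                )
            except InfopulseError as exc:
                log.warning("New Year effect unavailable for %s/%s/%s: %s", nation, metric, year, exc)
        result["new_year_effects"].extend(dataclasses.asdict(e) for e in ny_effects.values())
        if len(ny_effects) >= 3:
            eq = tax_equivalence(ny_effects, config.tax_events, pooled_by_metric[metric])
            result["tax_equivalence"][metric] = {
                k: v for k, v in dataclasses.asdict(eq).items() if k != "note"
            }
    return result


# -- report ------------------------------------------------------------------


def _md_table(df: pd.DataFrame, floatfmt: str = "{:.3f}") -> str:
    df = df.copy()
    for col in df.columns:
        if pd.api.types.is_float_dtype(df[col]):
            df[col] = df[col].map(lambda v: floatfmt.format(v) if pd.notna(v) else "")
    header = "| " + " | ".join(str(c) for c in df.columns) + " |"
    sep = "|" + "|".join("---" for _ in df.columns) + "|"
    rows = ["| " + " | ".join(str(v) for v in rec) + " |" for rec in df.itertuples(index=False)]
    return "\n".join([header, sep, *rows])


def write_report(outdir: Path) -> Path:
    """Assemble report.md from the stage outputs already on disk."""
    effects = pd.read_csv(outdir / "effects.csv")
    pooled = pd.read_csv(outdir / "pooled.csv")
    assoc = pd.read_csv(outdir / "assoc.csv")
    ratios_summary = json.loads((outdir / "ratios_summary.json").read_text())
    bench = json.loads((outdir / "benchmark.json").read_text())
    exclusions = pd.read_csv(outdir / "exclusions.csv") if (outdir / "exclusions.csv").exists() else None

    parts = ["# Awareness-day pulse evaluation report", ""]
    parts += ["## Pooled pulse effects", ""]
    parts += [_md_table(pooled[pooled.grouping == "overall"][
        ["metric", "effect", "ci_low", "ci_high", "k"]]), ""]
    parts += ["## Effects by nation", ""]
    parts += [_md_table(pooled[pooled.grouping == "by_nation"][
        ["key", "metric", "effect", "ci_low", "ci_high", "k"]]), ""]
    parts += ["## Effects by year", ""]
    parts += [_md_table(pooled[pooled.grouping == "by_year"][
        ["key", "metric", "effect", "ci_low", "ci_high", "k"]]), ""]
    parts += ["## Nation-year estimates", ""]
    parts += [_md_table(effects[["nation", "year", "metric", "effect", "ci_low", "ci_high"]]), ""]
    parts += ["## News → query lagged regression", ""]
    parts += [_md_table(assoc), ""]
    if ratios_summary:
        parts += [
            "## Query/news effect-ratio summary",
            "",
            f"Median ratio {ratios_summary['median']:.3f} "
            f"(IQR {ratios_summary['q1']:.3f}–{ratios_summary['q3']:.3f}, "
            f"n = {ratios_summary['n']} nation-years). Ratios below 1 mean news "
            "lifts exceed query lifts (diminishing returns of coverage on interest).",
            "",
        ]
    parts += ["## New Year and tax benchmarking", ""]
    ny = pd.DataFrame(bench["new_year_effects"])
    if len(ny):
        parts += [_md_table(ny[["metric", "year", "effect", "ci_low", "ci_high"]]), ""]
    for metric, eq in bench["tax_equivalence"].items():
        parts += [
            f"Equivalent tax increase ({metric}): {eq['equivalent_tax_pct']:.2f}% "
            f"(95% CI {eq['ci_low']:.2f} to {eq['ci_high']:.2f}) at target effect "
            f"{eq['target_effect']:.3f} over {eq['n_years']} years.",
            "",
        ]
    parts += ["> " + bench["note"], ""]
    if exclusions is not None and len(exclusions):
        parts += ["## Excluded nation-years", "", _md_table(exclusions), ""]
    truncated = effects[effects.truncated_reference]
    if len(truncated):
        parts += [
            "## Truncated reference windows",
            "",
            _md_table(truncated[["nation", "year", "metric", "n_reference_before", "n_reference_after"]]),
            "",
        ]
    path = outdir / "report.md"
    path.write_text("\n".join(parts))
    return path


def _make_plots(panels, effects_df: pd.DataFrame, config: RunConfig, outdir: Path) -> None:
    """Convenience series + forest plots; requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plotdir = outdir / "plots"
    plotdir.mkdir(exist_ok=True)
    spec = config.wntd_spec()
    for nation in sorted(panels):
        if Metric.QUERY_RSV.value not in panels[nation]:
            continue
        panel = panels[nation][Metric.QUERY_RSV.value]
        fig, ax = plt.subplots(figsize=(9, 3))
        ax.plot(panel.dates, panel.values, lw=0.8)
        for year in range(config.synthetic.start_year, config.synthetic.end_year + 1):
            try:
                anchor = pd.Timestamp(spec.anchor_date(year))
            except ValueError:
                continue
            ax.axvspan(anchor - pd.Timedelta(weeks=1), anchor + pd.Timedelta(weeks=2),
                       color="tab:orange", alpha=0.25, lw=0)
        ax.set_title(f"{nation}: query RSV with event windows")
        ax.set_ylabel("RSV")
        fig.tight_layout()
        fig.savefig(plotdir / f"{nation}_query_rsv.png", dpi=100)
        plt.close(fig)
    fig, ax = plt.subplots(figsize=(6, 0.25 * len(effects_df) + 1))
    labels = effects_df.nation + " " + effects_df.year.astype(str) + " " + effects_df.metric
    y = np.arange(len(effects_df))
    ax.errorbar(
        effects_df.effect, y,
        xerr=[effects_df.effect - effects_df.ci_low, effects_df.ci_high - effects_df.effect],
        fmt="o", ms=3, lw=1,
    )
    ax.axvline(0, color="k", lw=0.8)
    ax.set_yticks(y, labels, fontsize=6)
    ax.set_xlabel("pulse effect")
    fig.tight_layout()
    fig.savefig(plotdir / "forest.png", dpi=100)
    plt.close(fig)


# -- orchestration -----------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class RunResult:
    outdir: Path
    estimates: list[EffectEstimate]
    pooled: list[PooledEffect]
    regressions: list[LagRegressionResult]
    ratios_summary: dict
    benchmark: dict
    report_path: Path


def run_full_evaluation(config: RunConfig) -> RunResult:
    """Execute every stage and write the report bundle under ``config.outdir``."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "run_config.yaml")

    if config.input_dir is not None:
        panels = load_panels(config.input_dir)
        log.info("loaded panels for %d nations from %s", len(panels), config.input_dir)
    else:
        world_cfg = dataclasses.replace(config.synthetic, seed=derive_seed(config.seed, "world"))
        world = simulate_world(world_cfg)
        panels = world_panels(world)
        paneldir = outdir / "panels"
        write_panels(panels, paneldir)
        world.ground_truth().to_csv(outdir / "ground_truth.csv", index=False)
        log.info("simulated %d nations into %s", len(panels), paneldir)

    years = range(config.synthetic.start_year, config.synthetic.end_year + 1)
    spec = config.wntd_spec()
    estimates, exclusions = estimate_all_effects(panels, spec, years, config.ci, config.seed)
    effects_df = effects_to_frame(estimates)
    effects_df.to_csv(outdir / "effects.csv", index=False)
    pd.DataFrame(exclusions, columns=["nation", "metric", "year", "reason"]).to_csv(
        outdir / "exclusions.csv", index=False
    )

    pooled: list[PooledEffect] = []
    for grouping in ("overall", "by_nation", "by_year"):
        pooled.extend(
            pool_effects(
                estimates, grouping=grouping, method=config.pooling_method,
                min_reference_per_side=config.min_reference_per_side,
            )
        )
    pooled_to_frame(pooled).to_csv(outdir / "pooled.csv", index=False)

    regressions, ratios, ratios_summary, undefined = associate_all(panels, estimates, config)
    pd.DataFrame(
        [
            dict(nation=r.nation, r2_full=r.r2_full, r2_wntd=r.r2_wntd,
                 n_full=r.n_full, n_wntd=r.n_wntd, intercept=r.intercept,
                 **{f"coef_lag{l}": r.coefficients[l] for l in r.lags},
                 **{f"simple_r2_lag{l}": r.simple_r2[l] for l in r.lags})
            for r in regressions
        ]
    ).to_csv(outdir / "assoc.csv", index=False)
    pd.DataFrame([dataclasses.asdict(r) for r in ratios]).to_csv(
        outdir / "ratios.csv", index=False
    )
    (outdir / "ratios_summary.json").write_text(json.dumps(ratios_summary, indent=2))

    pooled_overall = [p for p in pooled if p.grouping == "overall"]
    bench = benchmark_all(panels, pooled_overall, config)
    (outdir / "benchmark.json").write_text(json.dumps(bench, indent=2))

    report_path = write_report(outdir)
    if config.make_plots:
        _make_plots(panels, effects_df, config, outdir)
    log.info("report written to %s", report_path)
    return RunResult(
        outdir=outdir,
        estimates=estimates,
        pooled=pooled,
        regressions=regressions,
        ratios_summary=ratios_summary,
        benchmark=bench,
        report_path=report_path,
    )
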