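"""Configuration-driven orchestration: raw tables to signal tables in one call.

``run`` executes the whole screen — parse, deduplicate, join, reference-set
construction, case selection, descriptive summaries, contingency tables, the
four disproportionality statistics and their criteria — and writes an artifact
bundle: CSV tables, an ordered forest-plot table, optional PNG plots, and a
YAML manifest with the fully resolved configuration and the stage counts in
flowchart order (raw rows → deduplicated reports → reference size → cases).
Inputs are either a directory of FAERS-style ASCII files or an inline
synthetic-data configuration.
"""

from __future__ import annotations

import dataclasses
import datetime
import decimal
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd
import yaml

import faersig
from faersig import io as fio
from faersig.cohort import (
    CohortSpec,
    DrugLexicon,
    annual_trend,
    build_reference_set,
    select_cases,
    summarize,
)
from faersig.dispro import SignalCriteria, signal_screen
from faersig.synth import SynthConfig, generate

__all__ = ["RunConfig", "RunResult", "run", "forest_table",
           "format_percent", "format_case_proportion"]


def format_percent(value: float, decimals: int = 1) -> str:
    """Round-half-up percentage formatter used in presentation tables."""
    q = decimal.Decimal(10) ** -decimals
    return str(decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def format_case_proportion(cases: int, total: int) -> str:
    """Overall case proportion, 100·cases/total, as a 2-decimal percentage."""
    if total <= 0:
        raise ValueError("total must be positive")
    return format_percent(100.0 * cases / total, decimals=2)


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    output_dir: Path
    input_dir: Path | None = None
    synth: SynthConfig | None = None
    lexicon_path: Path | None = None
    target_pt: str = "Male infertility"
    role_filter: tuple[str, ...] = ("PS",)
    date_window: tuple[datetime.date, datetime.date] = (
        datetime.date(2004, 1, 1),
        datetime.date(2024, 9, 30),
    )
    restrict_sex: str | None = None
    bcpnn_mode: Literal["approx", "exact"] = "approx"
    criteria: SignalCriteria = field(default_factory=SignalCriteria)
    continuity_correction: bool = True
    fit_mgps: bool = True
    top_k_countries: int = 5
    make_plots: bool = False
    seed: int = 0

    def validate(self) -> None:
        if (self.input_dir is None) == (self.synth is None):
            raise ValueError("exactly one of input_dir / synth must be given")
        if self.synth is not None:
            self.synth.validate()
        if self.date_window[0] > self.date_window[1]:
            raise ValueError("date_window start must be <= end")

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"] = dataclasses.asdict(self.synth) if self.synth else None
        return _plainify(d)


def _plainify(obj):
    """Recursively convert a config tree to YAML-safe builtin types."""
    if isinstance(obj, Mapping):
        return {str(k): _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (datetime.date, datetime.datetime)):
        return obj.isoformat()
    return obj


@dataclass
class RunResult:
    """In-memory view of one run's artifact bundle."""

    reference: pd.DataFrame
    cases: pd.DataFrame
    signals: pd.DataFrame
    forest: pd.DataFrame
    stage_counts: dict[str, int]
    manifest: dict
    output_dir: Path


def _load_tables(input_dir: Path):
    raw_counts = {}
    frames = {}
    quarantined = {}
    for kind in ("DEMO", "DRUG", "REAC"):
        matches = sorted(input_dir.glob(f"{kind}*.txt"))
        if not matches:
            raise FileNotFoundError(f"no {kind}*.txt under {input_dir}")
        parts, qparts = [], []
        for path in matches:
            res = fio.parse_table(path, kind)
            parts.append(res.frame)
            qparts.append(res.quarantine.assign(file=path.name))
        frames[kind] = pd.concat(parts, ignore_index=True)
        quarantined[kind] = pd.concat(qparts, ignore_index=True)
        raw_counts[kind] = int(sum(len(p) for p in parts)
                               + sum(len(q) for q in qparts))
    return frames, quarantined, raw_counts


def run(config: RunConfig) -> RunResult:
    """Execute the full screen and write the artifact bundle.

    On any stage failure the manifest is still written (with the failing
    stage recorded) before the error propagates.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "faersig_version": faersig.__version__,
        "config": config.to_manifest(),
        "stage_counts": {},
    }
    stage = "setup"
    try:
        stage = "load"
        if config.synth is not None:
            tables = generate(config.synth)
            demo_raw, drug_raw, reac_raw = tables.demo, tables.drug, tables.reac
            quarantined = None
        else:
            frames, quarantined, _ = _load_tables(Path(config.input_dir))
            demo_raw, drug_raw, reac_raw = (
                frames["DEMO"], frames["DRUG"], frames["REAC"])
        counts = {"raw_demo_rows": int(len(demo_raw)),
                  "raw_drug_rows": int(len(drug_raw)),
                  "raw_reac_rows": int(len(reac_raw))}

        stage = "deduplicate"
        demo = fio.deduplicate(demo_raw)
        counts["deduplicated_reports"] = int(len(demo))

        stage = "join"
        joined = fio.join_reports(demo, drug_raw, reac_raw)
        counts["orphan_drug_mentions"] = joined.orphans["drug"]
        counts["orphan_reac_mentions"] = joined.orphans["reac"]

        stage = "reference_set"
        lexicon = (DrugLexicon.from_tsv(config.lexicon_path)
                   if config.lexicon_path else DrugLexicon.default())
        spec = CohortSpec(
            target_pt=config.target_pt,
            role_filter=tuple(config.role_filter),
            date_window=config.date_window,
            restrict_sex=config.restrict_sex,
        )
        reference = build_reference_set(joined, spec, lexicon)
        counts["reference_reports"] = int(len(reference))

        stage = "cases"
        cases = select_cases(reference, config.target_pt)
        counts["case_reports"] = int(len(cases))
        counts["case_proportion_pct"] = format_case_proportion(
            len(cases), len(reference))

        stage = "summaries"
        drugs = sorted({d for t in reference["asms"] for d in t})
        summary = summarize(reference, drugs=drugs,
                            top_k_countries=config.top_k_countries)
        trend = annual_trend(reference, drugs=drugs,
                             date_window=config.date_window)

        stage = "signals"
        signals = signal_screen(
            reference,
            config.target_pt,
            drugs=drugs,
            bcpnn_mode=config.bcpnn_mode,
            criteria=config.criteria,
            fit_mgps=config.fit_mgps,
            correction=config.continuity_correction,
        )
        forest = forest_table(signals)

        stage = "write"
        summary.age.to_csv(out / "table1_age.csv")
        summary.weight.to_csv(out / "table1_weight.csv")
        summary.reporter.to_csv(out / "table1_reporter.csv")
        summary.outcome.to_csv(out / "table1_outcome.csv")
        summary.countries.to_csv(out / "table2_countries.csv", index=False)
        trend.to_csv(out / "annual_trend.csv")
        signals.to_csv(out / "signals.csv", index=False)
        forest.to_csv(out / "forest.csv", index=False)
        if quarantined is not None:
            pd.concat(
                [q.assign(table=k) for k, q in quarantined.items()],
                ignore_index=True,
            ).to_csv(out / "quarantine.csv", index=False)
        if config.make_plots:
            _plot_trend(trend, out / "annual_trend.png")
            _plot_forest(forest, out / "forest.png")

        manifest["stage_counts"] = counts
        manifest["status"] = "ok"
        return RunResult(
            reference=reference, cases=cases, signals=signals, forest=forest,
            stage_counts=counts, manifest=manifest, output_dir=out,
        )
    except Exception as exc:
        manifest["status"] = "error"
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(_plainify(manifest), fh, sort_keys=False)


def forest_table(signals: pd.DataFrame) -> pd.DataFrame:
    """Signals ordered for a forest plot: ROR descending, ties by drug name.

    A ``null_line`` column at 1.0 marks the no-association reference for
    plotting.
    """
    ordered = signals.sort_values(
        ["ror", "drug"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    ordered["null_line"] = 1.0
    return ordered


def _plot_trend(trend: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 5))
    for col in trend.columns:
        if col == "all":
            continue
        ax.plot(trend.index, trend[col], marker="o", markersize=3, label=col)
    ax.set_xlabel("year")
    ax.set_ylabel("reports")
    ax.set_title("Annual adverse-event reports per drug")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_forest(forest: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 0.5 * max(len(forest), 4) + 1.5))
    y = range(len(forest))[::-1]
    ax.errorbar(
        forest["ror"], list(y),
        xerr=[forest["ror"] - forest["ror_lo95"],
              forest["ror_hi95"] - forest["ror"]],
        fmt="s", color="black", ecolor="gray", capsize=3,
    )
    ax.axvline(1.0, linestyle="--", color="red", linewidth=1)
    ax.set_yticks(list(y))
    ax.set_yticklabels(forest["drug"])
    ax.set_xscale("log")
    ax.set_xlabel("reporting odds ratio (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
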