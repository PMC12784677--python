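"""End-to-end orchestration: counts -> DE -> inheritance -> enrichment -> report.

The pipeline runs the three pairwise NB comparisons in a fixed orientation —
hybrid over parent1, hybrid over parent2, and parent2 over parent1 — so that
log2 fold-change signs are unambiguous; the orientation is echoed in the
report. It then intersects the DEG sets, classifies inheritance patterns,
summarizes them, and (optionally) runs over-representation of the
non-additive genes against each supplied GMT collection, correcting each
collection separately. Everything is deterministic given the inputs.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .diffexpr import call_degs, de_test, write_de_table
from .enrichment import enrich, read_gmt
from .inheritance import classify_all, summarize_patterns, write_calls
from .io import (
    CountMatrix,
    SampleDesign,
    read_counts,
    read_sample_design,
    size_factors,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "PipelineError", "run_pipeline", "write_report"]


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Paths, thresholds and options for one pipeline run.

    Thresholds default to the DEG rule |log2FC| > 1 with FDR < 0.05, a
    conserved-expression bound of 1.25 and an MPV-test alpha of 0.05.
    """

    counts: str | Path
    design: str | Path
    outdir: str | Path
    gmt: tuple[str, ...] = ()
    lfc: float = 1.0
    fdr: float = 0.05
    conserved_lfc: float = 1.25
    mpv_alpha: float = 0.05
    pseudocount: float = 1.0
    hybrid_group: str | None = None
    enrich_min_size: int = 5
    enrich_max_size: int = 2000
    no_enrich: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.lfc <= 0 or self.conserved_lfc <= 0:
            raise ValueError("fold-change thresholds must be positive")
        for name in ("fdr", "mpv_alpha"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        self.gmt = tuple(str(p) for p in self.gmt)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        """Load a YAML config; keyword overrides (CLI flags) win."""
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


@dataclass
class RunReport:
    """JSON-able run summary plus the tables the pipeline produced."""

    report: dict
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return out

    return wrap


def run_pipeline(
    config: PipelineConfig,
    counts: CountMatrix | None = None,
    design: SampleDesign | None = None,
) -> RunReport:
    """Execute the full analysis and return a :class:`RunReport`.

    ``counts``/``design`` may be passed in-memory; otherwise they are read
    from the configured paths.
    """
    if counts is None:
        counts = _stage("read_counts")(read_counts, config.counts)
    if design is None:
        design = _stage("read_design")(read_sample_design, config.design)
    _stage("validate_design")(design.validate_matrix, counts)
    p1, p2, hyb = design.analysis_groups(config.hybrid_group)
    factors = _stage("size_factors")(size_factors, counts)

    def _de(group_a: str, group_b: str) -> pd.DataFrame:
        return de_test(
            counts,
            design,
            group_a,
            group_b,
            pseudocount=config.pseudocount,
            lfc_threshold=config.lfc,
            q_threshold=config.fdr,
            factors=factors,
        )

    de_h_p1 = _stage("de_hybrid_vs_parent1")(_de, p1, hyb)
    de_h_p2 = _stage("de_hybrid_vs_parent2")(_de, p2, hyb)
    de_p2_p1 = _stage("de_parent2_vs_parent1")(_de, p1, p2)

    degs = {
        f"{hyb}_vs_{p1}": call_degs(de_h_p1, config.lfc, config.fdr),
        f"{hyb}_vs_{p2}": call_degs(de_h_p2, config.lfc, config.fdr),
        f"{p2}_vs_{p1}": call_degs(de_p2_p1, config.lfc, config.fdr),
    }
    sets = list(degs.values())
    triple = sets[0] & sets[1] & sets[2]
    assert len(triple) <= min(len(s) for s in sets)

    calls = _stage("classify")(
        classify_all,
        counts,
        design,
        de_h_p1,
        de_h_p2,
        de_p2_p1,
        alpha=config.mpv_alpha,
        conserved_threshold=config.conserved_lfc,
        hybrid_group=hyb,
        factors=factors,
    )
    if len(calls):
        summary = _stage("summarize")(summarize_patterns, calls)
    else:
        logger.warning("no gene is a DEG in any comparison; empty classification")
        summary = {
            "classified": 0,
            "per_class": {},
            "additive_count": 0,
            "nonadditive_count": 0,
            "conserved": 0,
            "ambiguous": 0,
            "additive_pct": None,
            "nonadditive_pct": None,
        }

    tables: dict[str, pd.DataFrame] = {
        f"de_{hyb}_vs_{p1}": de_h_p1,
        f"de_{hyb}_vs_{p2}": de_h_p2,
        f"de_{p2}_vs_{p1}": de_p2_p1,
        "inheritance_calls": calls,
    }

    report: dict = {
        "provenance": {
            "package": "heterosis",
            "version": __version__,
            "seed": config.seed,
            "config": {
                k: (str(v) if isinstance(v, Path) else v)
                for k, v in asdict(config).items()
            },
            "comparison_orientation": {
                "hybrid_vs_parents": "log2fc is hybrid over parent",
                "parents": "log2fc is parent2 over parent1",
            },
            "groups": {"parent1": p1, "parent2": p2, "hybrid": hyb},
        },
        "deg_counts": {name: len(s) for name, s in degs.items()},
        "deg_triple_intersection": len(triple),
        "classification": summary,
    }

    if config.gmt and not config.no_enrich:
        nonadditive = sorted(
            calls.loc[calls["additivity"] == "non-additive", "gene_id"]
        )
        universe = [
            g
            for g, expressed in zip(
                counts.gene_ids, (counts.counts.to_numpy() > 0).any(axis=1)
            )
            if expressed
        ]
        enrichment_summaries = {}
        for gmt_path in config.gmt:
            collection = _stage("read_gmt")(read_gmt, gmt_path)
            name = Path(gmt_path).stem
            result = _stage(f"enrich_{name}")(
                enrich,
                nonadditive,
                universe,
                collection,
                min_size=config.enrich_min_size,
                max_size=config.enrich_max_size,
                q_threshold=config.fdr,
            )
            tables[f"enrichment_{name}"] = result
            enrichment_summaries[name] = {
                "n_terms_tested": int(len(result)),
                "n_significant": int(result["significant"].sum()) if len(result) else 0,
                "top_terms": result.head(10).to_dict(orient="records"),
            }
        report["enrichment"] = enrichment_summaries

    # percentages must recompute exactly from the reported counts
    if summary["classified"]:
        assert summary["additive_count"] + summary["nonadditive_count"] == summary[
            "classified"
        ]
    return RunReport(report=report, tables=tables)


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text, encoding="utf-8")
    os.replace(tmp, path)


def write_report(run: RunReport, outdir: str | Path) -> list[Path]:
    """Write report.json plus one TSV per table; overwrites atomically."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    report_path = outdir / "report.json"
    _atomic_write(report_path, json.dumps(run.report, indent=2, default=float) + "\n")
    written.append(report_path)
    for name, table in run.tables.items():
        path = outdir / f"{name}.tsv"
        if name == "inheritance_calls":
            write_calls(table, path)
        elif name.startswith("de_"):
            write_de_table(table, path)
        else:
            table.to_csv(path, sep="\t", index=False)
        written.append(path)
    return written
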