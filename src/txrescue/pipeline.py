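"""End-to-end orchestration: counts -> QC -> FPM -> DE consensus -> rescue
classification (-> optional GO enrichment) -> report.

Stage order: read counts, restrict to protein-coding genes, normalize to
FPM, PCA sample QC (flagged samples dropped by default, after which FPM is
recomputed on the retained samples so library sizes reflect the analyzed
matrix), consensus DE for control-vs-disease and control-vs-disease+drug,
two-strategy rescue classification, bookkeeping summary, and — when an
ontology and annotation table are supplied — over-representation analysis of
the up- and downregulated drug-sensitive gene sets with common-child-term
identification.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from txrescue.counts import (
    CountMatrix,
    filter_protein_coding,
    normalize_fpm,
    pca_sample_qc,
    read_biotypes,
    read_counts,
    read_design,
)
from txrescue.de import run_de
from txrescue.enrichment import (
    adjust_pvalues,
    annotate_with_ancestors,
    common_child_terms,
    hypergeom_enrich,
    parse_obo,
    read_annotations,
    significant_terms,
)
from txrescue.rescue import classify_study, summarize_strategies

logger = logging.getLogger("txrescue")


@dataclass
class PipelineConfig:
    """All thresholds and switches of the analysis chain."""

    fpm_min: float = 3.0
    lfc_min_a: float = 1.0
    lfc_min_b: float = 1.0
    fdr_alpha: float = 0.05
    ci_level: float = 0.95
    ci_scale: str = "log2p1"
    go_alpha: float = 1e-6
    go_adjustment: str = "bonferroni"
    go_background: str = "annotation"  # "annotation" (whole genome) | "expressed"
    pseudocount: float = 1.0
    qc_multiplier: float = 3.0
    drop_flagged_samples: bool = True
    missing_biotype_policy: str = "drop"
    seed: int = 0

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = yaml.safe_load(text)
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


@dataclass
class RunReport:
    """Per-stage bookkeeping plus the emitted tables."""

    config: PipelineConfig
    stage_counts: dict[str, int]
    qc_flagged: list[str]
    summary: dict
    calls: pd.DataFrame
    de_tables: dict[str, pd.DataFrame]
    fig2b_table: pd.DataFrame
    enrichment_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    common_children: dict[str, dict] = field(default_factory=dict)


def _stage(name: str):
    logger.info("stage: %s", name)
    return name


def run_pipeline(
    counts: CountMatrix | str | Path,
    design: Mapping[str, str] | str | Path | None = None,
    biotypes: Mapping[str, str] | str | Path | None = None,
    config: PipelineConfig | None = None,
    obo_path: str | Path | None = None,
    annotation_path: str | Path | None = None,
) -> RunReport:
    """Run the full analysis chain; deterministic for fixed inputs + config."""
    config = config or PipelineConfig()
    stage = "load"
    try:
        if not isinstance(counts, CountMatrix):
            if design is None:
                raise ValueError("a design is required when reading counts from a file")
            if not isinstance(design, Mapping):
                design = read_design(design)
            counts = read_counts(counts, design)
        groups = set(counts.design.values())
        expected = {"control", "disease", "disease_drug"}
        if groups != expected:
            raise ValueError(f"design groups {sorted(groups)} != {sorted(expected)}")
        stage_counts = {"detected_genes": len(counts.gene_ids),
                        "samples": len(counts.sample_ids)}

        stage = _stage("protein_coding_filter")
        if biotypes is not None:
            if not isinstance(biotypes, Mapping):
                biotypes = read_biotypes(biotypes)
            n_before = len(counts.gene_ids)
            counts = filter_protein_coding(counts, biotypes, config.missing_biotype_policy)
            logger.info("protein-coding filter: %d -> %d genes", n_before,
                        len(counts.gene_ids))
        stage_counts["protein_coding_genes"] = len(counts.gene_ids)

        stage = _stage("fpm")
        am = normalize_fpm(counts)

        stage = _stage("sample_qc")
        qc = pca_sample_qc(am, config.qc_multiplier)
        if qc.flagged_samples:
            logger.warning("QC flagged samples: %s", qc.flagged_samples)
        if config.drop_flagged_samples and qc.flagged_samples:
            keep = [s for s in counts.sample_ids if s not in qc.flagged_samples]
            counts = counts.subset_samples(keep)
            am = normalize_fpm(counts)
        stage_counts["retained_samples"] = len(counts.sample_ids)

        stage = _stage("differential_expression")
        de_cd = run_de(counts, ("control", "disease"), config.fdr_alpha,
                       config.pseudocount)
        de_ce = run_de(counts, ("control", "disease_drug"), config.fdr_alpha,
                       config.pseudocount)
        de_de = run_de(counts, ("disease", "disease_drug"), config.fdr_alpha,
                       config.pseudocount)

        stage = _stage("rescue_classification")
        calls = classify_study(
            am, de_cd, de_ce,
            fpm_min=config.fpm_min,
            lfc_min_b=config.lfc_min_b,
            lfc_min_a=config.lfc_min_a,
            ci_level=config.ci_level,
            scale=config.ci_scale,  # type: ignore[arg-type]
            pseudocount=config.pseudocount,
        )
        summary = summarize_strategies(calls)
        stage_counts.update(
            {
                "regulated_genes": summary.n_regulated,
                "regulated_up": summary.n_up,
                "regulated_down": summary.n_down,
                "sensitive_strategy_a": int(calls["strategy_a"].sum()),
                "sensitive_strategy_b": int(calls["strategy_b"].sum()),
            }
        )

        enrichment_tables: dict[str, pd.DataFrame] = {}
        common_children: dict[str, dict] = {}
        if obo_path is not None and annotation_path is not None:
            stage = _stage("enrichment")
            dag = parse_obo(obo_path)
            direct = read_annotations(annotation_path)
            ann = annotate_with_ancestors(dag, direct)
            universe = set().union(*ann.values()) if ann else set()
            if config.go_background == "expressed":
                universe = universe & set(counts.gene_ids)
            for direction in ("up", "down"):
                sens = calls[(calls["direction"] == direction) & calls["strategy_a"]]
                query = set(sens["gene_id"]) & universe
                if not query:
                    enrichment_tables[direction] = pd.DataFrame(
                        columns=["term_id", "k", "n", "K", "N", "p",
                                 "enrichment_score", "p_adj"]
                    )
                    common_children[direction] = {"k_min": 2, "common_children": {},
                                                  "leaves": []}
                    continue
                res = adjust_pvalues(hypergeom_enrich(query, universe, ann),
                                     config.go_adjustment)
                enrichment_tables[direction] = res.sort_values("p").reset_index(drop=True)
                sig = significant_terms(res, config.go_alpha)
                report = common_child_terms(dag, sig)
                common_children[direction] = {
                    "k_min": report.k_min,
                    "common_children": report.common_children,
                    "leaves": report.leaves,
                }

        fig2b = summary.cells.copy()
        return RunReport(
            config=config,
            stage_counts=stage_counts,
            qc_flagged=qc.flagged_samples,
            summary=summary.to_dict(),
            calls=calls,
            de_tables={
                de_cd.comparison: de_cd.table,
                de_ce.comparison: de_ce.table,
                de_de.comparison: de_de.table,
            },
            fig2b_table=fig2b,
            enrichment_tables=enrichment_tables,
            common_children=common_children,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def write_report(report: RunReport, outdir: str | Path) -> list[Path]:
    """Write all report tables (TSV), the JSON summary and a run log.

    Column order is stable; the JSON summary embeds the config and its hash
    for provenance.  Returns the written paths.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def tsv(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        written.append(path)

    tsv(report.calls, "rescue_calls.tsv")
    tsv(report.fig2b_table, "strategy_summary.tsv")
    for name, table in report.de_tables.items():
        tsv(table, f"de_{name}.tsv")
    for direction, table in report.enrichment_tables.items():
        tsv(table, f"enrichment_{direction}.tsv")

    payload = {
        "config": asdict(report.config),
        "config_hash": report.config.digest(),
        "stage_counts": report.stage_counts,
        "qc_flagged": report.qc_flagged,
        "summary": report.summary,
        "common_children": report.common_children,
    }
    summary_path = out / "run_summary.json"
    summary_path.write_text(json.dumps(payload, indent=2, default=float))
    written.append(summary_path)

    log_path = out / "run_log.txt"
    lines = [f"{k}\t{v}" for k, v in report.stage_counts.items()]
    if report.qc_flagged:
        lines.append("qc_flagged\t" + ",".join(report.qc_flagged))
    log_path.write_text("\n".join(lines) + "\n")
    written.append(log_path)
    return written
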