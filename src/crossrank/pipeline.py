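"""End-to-end orchestration: simulate → integrate → rank → QC → map →
q-values → permutation evaluation → matrix selection → enrichment.

One global seed is fanned out to stage-specific seeds (stable CRC32 hash
of the stage name) so any stage can be re-run in isolation with the same
stream.  Re-running an identical configuration is byte-identical in every
output file; wall-clock timing goes to the logger only.
"""

from __future__ import annotations

import dataclasses
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment, evidence, gwas, qvalue, ranking, simulate
from . import io as crio
from .permutation import PermutationConfig, permutation_pvalues, select_best_matrix

log = logging.getLogger("crossrank")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(global_seed: int, stage: str) -> int:
    """Derived per-stage seed, stable across runs (CRC32 of the stage name)."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str | None = None
    input_dir: str | None = None  # when set, the simulate stage is skipped
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides
    qc: dict = field(default_factory=dict)        # QcConfig overrides
    permutation: dict = field(default_factory=dict)  # PermutationConfig overrides
    wsms: tuple[str, ...] = tuple(f"WSM{i}" for i in range(1, 11))
    top_threshold: float = 2.0
    flank_bp: int = 10_000
    fdr_method: str = "smoother"
    initial_sources: tuple[str, ...] = evidence.DEFAULT_INITIAL_SOURCES

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        for name in ("wsms", "initial_sources"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def defaults_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(PipelineConfig()), sort_keys=False)


@dataclass
class RunReport:
    config: PipelineConfig
    score_distributions: dict[str, pd.Series] = field(default_factory=dict)
    permutation_reports: dict = field(default_factory=dict)
    selected_wsm: str | None = None
    selection_table: pd.DataFrame | None = None
    top_genes: pd.DataFrame | None = None
    qbin_table: pd.DataFrame | None = None
    enrichment_table: pd.DataFrame | None = None
    qc_report: dict = field(default_factory=dict)
    mapped_percent: float | None = None

    def to_json_dict(self) -> dict:
        def df(d):
            return d.to_dict(orient="records") if d is not None else []

        return {
            "seed": self.config.seed,
            "selected_wsm": self.selected_wsm,
            "score_distributions": {
                w: {str(k): int(v) for k, v in s.items()}
                for w, s in self.score_distributions.items()
            },
            "permutation": {
                w: df(rep.table) for w, rep in self.permutation_reports.items()
            },
            "permutation_min_q": {
                w: rep.min_q() for w, rep in self.permutation_reports.items()
            },
            "selection": df(self.selection_table),
            "top_genes": df(self.top_genes),
            "qbin_table": df(self.qbin_table),
            "enrichment": df(self.enrichment_table),
            "qc": self.qc_report,
            "mapped_percent": self.mapped_percent,
            "n_top_genes": int(len(self.top_genes)) if self.top_genes is not None else 0,
        }


def _load_inputs(input_dir: str):
    d = Path(input_dir)
    genes = crio.read_gene_table(d / "genes.tsv")
    source_sets = {}
    for src in evidence.SOURCES:
        if src == "HuLink":
            continue
        path = d / f"evidence_{src}.tsv"
        if not path.exists():
            source_sets[src] = set()
            continue
        sp = simulate.SOURCE_SPECIES[src]
        omap = d / f"orthologs_{sp}.tsv"
        ids, _ = evidence.load_evidence_list(
            path, sp, ortholog_map=omap if omap.exists() else None
        )
        source_sets[src] = ids
    intervals = crio.read_intervals_bed(d / "linkage.bed")
    snps = crio.read_snp_table(d / "snps.tsv")
    gmt = crio.read_gmt(d / "annotations.gmt") if (d / "annotations.gmt").exists() else {}
    return genes, source_sets, intervals, snps, gmt


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    report = RunReport(config=cfg)
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        if cfg.input_dir:
            log.info("simulate: skipped (inputs supplied from %s)", cfg.input_dir)
            genes, source_sets, intervals, snps, gmt = _load_inputs(cfg.input_dir)
        else:
            sim_cfg = simulate.SimulationConfig(
                **{"seed": stage_seed(cfg.seed, "simulate"), **cfg.simulate}
            )
            study = simulate.simulate_study(sim_cfg)
            genes = study.genes
            source_sets = dict(study.evidence.source_sets)
            intervals = study.evidence.linkage_intervals
            snps = study.snps
            gmt = study.annotations
        log.info("simulate: %d genes, %d SNPs (%.2fs)", len(genes), len(snps),
                 time.perf_counter() - t0)

        stage = "integrate"
        source_sets["HuLink"] = evidence.assign_linkage(genes, intervals)
        profiles, _ = evidence.build_profiles(
            genes, source_sets, initial_sources=cfg.initial_sources
        )
        log.info("integrate: %d profiles, %d in initial list",
                 len(profiles), int(profiles["in_initial_list"].sum()))

        stage = "rank"
        ranked = {w: ranking.rank_genes(profiles, w) for w in cfg.wsms}
        report.score_distributions = {
            w: ranking.score_distribution(r) for w, r in ranked.items()
        }

        stage = "gwas-qc"
        qc_cfg = gwas.QcConfig(**cfg.qc)
        snps_clean, qc_rep = gwas.qc_filter(snps, qc_cfg)
        report.qc_report = qc_rep
        log.info("gwas-qc: %d/%d SNPs pass", qc_rep["n_passed"], qc_rep["n_input"])

        stage = "map"
        mapping, gene_index, frac = gwas.map_snps_to_genes(
            snps_clean, genes, flank_bp=cfg.flank_bp
        )
        report.mapped_percent = gwas.mapped_percent(
            sum(1 for v in mapping.values() if v), len(mapping)
        )
        log.info("map: %.1f%% of SNPs in gene±%d bp windows",
                 report.mapped_percent, cfg.flank_bp)

        stage = "permute"
        perm_cfg = PermutationConfig(
            **{
                "seed": stage_seed(cfg.seed, "permute"),
                "fdr_method": cfg.fdr_method,
                **cfg.permutation,
            }
        )
        reports = {}
        for w in cfg.wsms:
            rng = np.random.default_rng(stage_seed(perm_cfg.seed, f"permute:{w}"))
            reports[w] = permutation_pvalues(
                ranked[w], gene_index, snps_clean, genes, perm_cfg, rng=rng, wsm_name=w
            )
        report.permutation_reports = reports

        stage = "select"
        best, table = select_best_matrix(reports)
        report.selected_wsm = best
        report.selection_table = table
        log.info("select: %s", best)

        stage = "qvalue"
        top = ranking.select_top(ranked[best], cfg.top_threshold, "ge")
        report.top_genes = top[["gene_id", "symbol", "score"]]
        qv_top = qvalue.subset_q(
            snps_clean, top["gene_id"], gene_index=gene_index, pi0_method=cfg.fdr_method
        )
        report.qbin_table = qvalue.bin_q(qv_top).to_frame() if len(qv_top) else None

        stage = "enrich"
        if gmt:
            report.enrichment_table = enrichment.enrich(
                top["gene_id"], gmt, background=genes["gene_id"]
            )
    except Exception as exc:  # noqa: BLE001 — re-raise tagged with the stage
        if cfg.outdir:
            write_report(report, Path(cfg.outdir) / "failed")
        raise PipelineError(stage, exc) from exc

    if cfg.outdir:
        write_report(report, cfg.outdir)
    return report


def write_report(report: RunReport, outdir) -> None:
    """TSV tables + one JSON summary + a plain-text narrative.  Every number
    in the narrative also appears in the JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for w, dist in report.score_distributions.items():
        dist.rename("count").rename_axis("score").to_csv(
            outdir / f"score_distribution_{w}.tsv", sep="\t"
        )
    for w, rep in report.permutation_reports.items():
        rep.table.to_csv(outdir / f"permutation_{w}.tsv", sep="\t", index=False)
    if report.selection_table is not None:
        report.selection_table.to_csv(outdir / "selection.tsv", sep="\t", index=False)
    if report.top_genes is not None:
        report.top_genes.to_csv(outdir / "top_genes.tsv", sep="\t", index=False)
    if report.qbin_table is not None:
        report.qbin_table.to_csv(outdir / "qbin_table.tsv", sep="\t", index=False)
    if report.enrichment_table is not None:
        report.enrichment_table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    crio.write_json_report(report.to_json_dict(), outdir / "report.json")

    lines = []
    if report.selected_wsm:
        lines.append(f"selected weighting matrix: {report.selected_wsm}")
    for w, rep in report.permutation_reports.items():
        lines.append(f"{w}: observed min q over cutoffs = {rep.min_q():.6g}")
    if report.top_genes is not None:
        lines.append(f"top genes (score >= {report.config.top_threshold:g}): "
                     f"{len(report.top_genes)}")
    if report.mapped_percent is not None:
        lines.append(f"mapped SNP percent: {report.mapped_percent}")
    (outdir / "narrative.txt").write_text("\n".join(lines) + "\n")


def read_report_json(path) -> dict:
    import json

    with open(path) as fh:
        return json.load(fh)
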