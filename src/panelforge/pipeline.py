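"""End-to-end orchestration: consensus -> effects -> panels -> reports.

Stages are deterministic given their inputs; the only randomness in the
whole package lives in the simulator. A JSON-lines manifest records the
parameters, input checksums and per-stage record counts of each run so that
a result can be traced back to its exact inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .consensus import intersect_callsets, write_hc_tsv, write_hc_vcf
from .diversity import density_frame, density_report
from .effects import annotate_variants, summarize_impacts, worst_impact_per_snp
from .panels import (
    BIN_SIZE,
    FLANK_WINDOW,
    K_PER_GENE,
    LINKAGE_WINDOW,
    BinGrid,
    annotate_flanks,
    known_variant_positions,
    select_gene_panel,
    select_gwas_panel,
)
from .vario import read_fasta, read_gff3, read_vcf, write_panel

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run; see the CLI for file semantics."""

    vcf_deep_ref: str
    vcf_shotgun: str
    vcf_skim: str
    gff3: str
    fasta: str
    outdir: str
    min_support: int = 2
    bin_size: int = BIN_SIZE
    flank_window: int = FLANK_WINDOW
    k_per_gene: int = K_PER_GENE
    linkage_window: int = LINKAGE_WINDOW

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        for name in ("vcf_deep_ref", "vcf_shotgun", "vcf_skim", "gff3", "fasta"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise PipelineError("config", f"{name} file not found: {p}")
        if self.min_support < 1:
            raise PipelineError("config", "min_support must be >= 1")
        for name in ("bin_size", "flank_window", "k_per_gene", "linkage_window"):
            if getattr(self, name) < 1:
                raise PipelineError("config", f"{name} must be >= 1")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage, writing all artifacts and a manifest into outdir.

    Returns a name -> path map of the outputs: high-confidence VCF/TSV,
    per-effect TSV, impact summary TSV, both panel TSVs, density report and
    the JSON-lines manifest.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.jsonl"
    manifest = open(manifest_path, "w")

    def record(stage: str, **info) -> None:
        line = {"stage": stage, **info}
        manifest.write(json.dumps(line, sort_keys=True) + "\n")
        log.info("stage %s: %s", stage, info)

    inputs = {
        "deep_ref": config.vcf_deep_ref,
        "shotgun": config.vcf_shotgun,
        "skim_panel": config.vcf_skim,
        "gff3": config.gff3,
        "fasta": config.fasta,
    }
    record(
        "inputs",
        version=__version__,
        checksums={k: _sha256(v) for k, v in inputs.items()},
        parameters={
            "min_support": config.min_support,
            "bin_size": config.bin_size,
            "flank_window": config.flank_window,
            "k_per_gene": config.k_per_gene,
            "linkage_window": config.linkage_window,
        },
    )

    paths: dict[str, Path] = {"manifest": manifest_path}
    try:
        # --- consensus
        callsets = [
            read_vcf(config.vcf_deep_ref, "deep_ref"),
            read_vcf(config.vcf_shotgun, "shotgun"),
            read_vcf(config.vcf_skim, "skim_panel"),
        ]
        hc = intersect_callsets(callsets, min_support=config.min_support)
        known = known_variant_positions(callsets)
        annotate_flanks(hc, known, window=config.flank_window)
        genome = read_fasta(config.fasta)
        contigs = {c: len(s) for c, s in genome.items()}
        paths["hc_vcf"] = outdir / "high_confidence.vcf"
        paths["hc_tsv"] = outdir / "high_confidence.tsv"
        write_hc_vcf(hc, paths["hc_vcf"], contigs=contigs)
        write_hc_tsv(hc, paths["hc_tsv"])
        record(
            "consensus",
            n_input=[len(cs) for cs in callsets],
            n_high_confidence=len(hc),
            n_flank_clear=sum(1 for s in hc if s.flank_clear),
        )

        # --- effects
        genes = read_gff3(config.gff3)
        effects = annotate_variants([s.key for s in hc], genes, genome)
        summary = summarize_impacts(effects)
        paths["effects_tsv"] = outdir / "effects.tsv"
        with open(paths["effects_tsv"], "w") as fh:
            fh.write("chrom\tpos\tref\talt\tgene_id\ttranscript_id\teffect_type\timpact\n")
            for e in effects:
                fh.write(
                    f"{e.key.chrom}\t{e.key.pos}\t{e.key.ref}\t{e.key.alt}\t"
                    f"{e.gene_id or '.'}\t{e.transcript_id or '.'}\t{e.effect_type}\t{e.impact}\n"
                )
        paths["impact_summary"] = outdir / "impact_summary.tsv"
        summary.to_frame().to_csv(paths["impact_summary"], sep="\t", index=False)
        record(
            "effects",
            n_genes_annotated=sum(1 for g in genes if g.cds_valid),
            n_effects=summary.total,
            class_counts=summary.class_counts,
        )

        # --- panels
        grid = BinGrid(contigs, bin_size=config.bin_size)
        gwas = select_gwas_panel(hc, grid)
        paths["panel_gwas"] = outdir / "panel_gwas.tsv"
        write_panel(gwas, paths["panel_gwas"], "tsv")

        impact_by_snp = worst_impact_per_snp(effects)
        targets = [g for g in genes if g.is_target]
        if targets:
            gene_panel = select_gene_panel(
                hc,
                targets,
                impact_by_snp,
                k=config.k_per_gene,
                linkage_window=config.linkage_window,
            )
            paths["panel_genes"] = outdir / "panel_genes.tsv"
            write_panel(gene_panel, paths["panel_genes"], "tsv")
            record(
                "panels",
                gwas_size=len(gwas),
                gene_panel_size=len(gene_panel),
                gene_shortfalls=gene_panel.shortfalls,
            )
        else:
            record("panels", gwas_size=len(gwas), gene_panel_size=None)

        # --- reports
        gene_counts: dict[str, int] = {}
        for g in genes:
            gene_counts[g.chrom] = gene_counts.get(g.chrom, 0) + 1
        rows = density_report(hc, contigs, gene_counts)
        paths["density"] = outdir / "density_report.tsv"
        density_frame(rows).to_csv(paths["density"], sep="\t", index=False)
        record("reports", n_rows=len(rows))
    except PipelineError:
        manifest.close()
        raise
    except Exception as exc:  # tag unexpected failures with their stage context
        record("error", message=str(exc))
        manifest.close()
        raise
    manifest.close()
    return paths
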