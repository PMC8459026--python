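"""Descriptive reports: per-chromosome SNP density and the target-gene registry.

Mean inter-SNP distance is the integer floor of chromosome length over SNP
count. The genome-level mean is computed over scaffolded chromosomes only —
unplaced contigs are listed as their own row but excluded from the genome
mean, whose denominator would otherwise be inflated by the sparse calls
typical of unanchored sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .consensus import HighConfidenceSnp

GENOME_ROW = "Genome"


@dataclass(frozen=True)
class DensityReportRow:
    chrom: str
    length: int
    n_snps: int
    n_genes: int | None
    mean_snp_distance: int | None  # floor(length / n_snps); None if n_snps == 0 or unplaced


def density_report(
    snps: Mapping[str, int] | Iterable[HighConfidenceSnp],
    chrom_lengths: Mapping[str, int],
    gene_counts: Mapping[str, int] | None = None,
    unplaced: frozenset[str] | set[str] = frozenset(),
) -> list[DensityReportRow]:
    """Per-chromosome density rows plus a genome-level row.

    ``snps`` is either a {chrom: count} map or an iterable of high-confidence
    SNPs to be counted. Unplaced contig names get a row with the mean
    distance omitted and are excluded from the genome-level mean.
    """
    if isinstance(snps, Mapping):
        counts = dict(snps)
    else:
        counts = {}
        for s in snps:
            counts[s.key.chrom] = counts.get(s.key.chrom, 0) + 1
    unknown = set(counts) - set(chrom_lengths)
    if unknown:
        raise KeyError(f"SNPs on chromosomes absent from chrom_lengths: {sorted(unknown)}")

    rows = []
    for chrom in chrom_lengths:
        n = counts.get(chrom, 0)
        length = chrom_lengths[chrom]
        if chrom in unplaced or n == 0:
            mean = None
        else:
            mean = length // n
        ngenes = gene_counts.get(chrom) if gene_counts else None
        rows.append(DensityReportRow(chrom, length, n, ngenes, mean))

    scaff = [r for r in rows if r.chrom not in unplaced]
    tot_len = sum(r.length for r in scaff)
    tot_snps = sum(r.n_snps for r in scaff)
    tot_genes = (
        sum(r.n_genes for r in rows if r.n_genes is not None) if gene_counts else None
    )
    genome_mean = tot_len // tot_snps if tot_snps else None
    rows.append(DensityReportRow(GENOME_ROW, tot_len, tot_snps, tot_genes, genome_mean))
    return rows


def density_frame(rows: Sequence[DensityReportRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.chrom,
                r.length,
                r.n_snps,
                "" if r.n_genes is None else r.n_genes,
                "" if r.mean_snp_distance is None else r.mean_snp_distance,
            )
            for r in rows
        ],
        columns=["chrom", "length_bp", "n_snps", "n_genes", "mean_snp_distance_bp"],
    )


# ---------------------------------------------------------------------------
# Gene registry (enzyme family copy-number table)


def read_registry(path) -> pd.DataFrame:
    """Read a copy-number registry TSV: enzyme, family, description, then one
    integer copy-count column per species."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"enzyme", "family"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"registry missing columns: {sorted(missing)}")
    return df


def registry_species_columns(registry: pd.DataFrame) -> list[str]:
    meta = {"enzyme", "family", "description"}
    return [c for c in registry.columns if c not in meta]


def registry_totals(registry: pd.DataFrame) -> tuple[dict[str, int], int]:
    """Per-species total gene-copy counts and the number of distinct families."""
    species = registry_species_columns(registry)
    totals = {sp: int(registry[sp].sum()) for sp in species}
    for sp, tot in totals.items():
        if (registry[sp] < 0).any():
            raise ValueError(f"negative copy count in column {sp}")
    n_families = registry["family"].nunique()
    return totals, n_families
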