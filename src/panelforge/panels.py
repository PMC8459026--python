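"""Panel selection: the genome-wide binned max-MAF panel and the per-target-gene panel.

Shared eligibility filters (both panels):

* **conserved flanks** — no other known variant (from the union of *all* raw
  callset positions, not just high-confidence SNPs) within 50 bp on either
  side; the boundary case of a variant exactly 50 bp away fails, since "at
  least 50 bp of conserved sequence" requires 50 clear bases;
* **all three genotypic states** — hom-ref, het and hom-alt each observed at
  least once among the non-missing skim-panel genotypes;
* **defined MAF** — at least one called panel genotype.

The genome-wide panel tiles each chromosome with contiguous bins (default
5 kb, anchored at position 1, terminal partial bin included) and picks the
eligible SNP of highest MAF per bin, ties broken to the smallest position.
The gene panel picks k SNPs (default 2) per target gene, ranked by MAF
descending, then impact severity, then position; when a gene span holds
fewer than k eligible SNPs the candidate window widens by a linkage window
(default +/-5 kb) standing in for "tight linkage" with the gene.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .consensus import ALL_STATES, HighConfidenceSnp
from .effects import IMPACT_RANK, MODIFIER
from .vario import Callset, GeneModel, VariantKey

FLANK_WINDOW = 50
BIN_SIZE = 5000
K_PER_GENE = 2
LINKAGE_WINDOW = 5000


@dataclass(frozen=True)
class BinGrid:
    """Contiguous bins tiling each chromosome, anchored at position 1."""

    chrom_lengths: Mapping[str, int]
    bin_size: int = BIN_SIZE

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.chrom_lengths[chrom] / self.bin_size)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chrom_lengths)

    def bin_index(self, pos: int) -> int:
        return (pos - 1) // self.bin_size


@dataclass(frozen=True)
class PanelEntry:
    key: VariantKey
    maf: float | None
    states: frozenset[str]
    impact: str | None
    group: str  # "chrom:bin_index" or target gene id
    rank: int


@dataclass
class PanelSelection:
    panel_type: str  # "gwas" | "gene_targeted"
    entries: list[PanelEntry]
    parameters: dict = field(default_factory=dict)
    shortfalls: dict[str, int] = field(default_factory=dict)  # gene_id -> n selected (< k)

    def __len__(self) -> int:
        return len(self.entries)


def known_variant_positions(callsets: Iterable[Callset]) -> dict[str, np.ndarray]:
    """Union of every called position in every raw callset, sorted per chrom.

    This is the variant map against which flank conservation is judged:
    assay (primer/bait) design must clear *any* known variation, including
    sites that did not reach the high-confidence set.
    """
    pos: dict[str, set[int]] = {}
    for cs in callsets:
        for key in cs.records:
            pos.setdefault(key.chrom, set()).add(key.pos)
    return {c: np.array(sorted(s), dtype=np.int64) for c, s in pos.items()}


def flank_is_conserved(
    key: VariantKey,
    known_variants: Mapping[str, np.ndarray],
    window: int = FLANK_WINDOW,
) -> bool:
    """True iff no *other* known variant lies within ``window`` bp of the SNP
    (0 < |p - pos| <= window)."""
    positions = known_variants.get(key.chrom)
    if positions is None or len(positions) == 0:
        return True
    lo = bisect_left(positions, key.pos - window)
    hi = bisect_right(positions, key.pos + window)
    for p in positions[lo:hi]:
        if p != key.pos:
            return False
    return True


def annotate_flanks(
    snps: Sequence[HighConfidenceSnp],
    known_variants: Mapping[str, np.ndarray],
    window: int = FLANK_WINDOW,
) -> None:
    for s in snps:
        s.flank_clear = flank_is_conserved(s.key, known_variants, window)


def is_eligible(snp: HighConfidenceSnp) -> bool:
    return (
        bool(snp.flank_clear)
        and snp.maf is not None
        and snp.states_observed == ALL_STATES
    )


def select_gwas_panel(
    hc_snps: Sequence[HighConfidenceSnp],
    grid: BinGrid,
) -> PanelSelection:
    """One SNP per bin: the eligible SNP of maximal MAF, ties to the smallest
    position then key order; bins with no eligible SNP contribute nothing."""
    best: dict[tuple[str, int], HighConfidenceSnp] = {}
    for s in hc_snps:
        if not is_eligible(s):
            continue
        if s.key.chrom not in grid.chrom_lengths:
            raise KeyError(f"SNP chrom {s.key.chrom!r} absent from bin grid")
        b = (s.key.chrom, grid.bin_index(s.key.pos))
        cur = best.get(b)
        if cur is None or (-s.maf, s.key.pos, s.key) < (-cur.maf, cur.key.pos, cur.key):
            best[b] = s
    entries = []
    for (chrom, bidx) in sorted(best):
        s = best[(chrom, bidx)]
        entries.append(
            PanelEntry(s.key, s.maf, s.states_observed, None, f"{chrom}:{bidx}", rank=1)
        )
    return PanelSelection(
        "gwas", entries, parameters={"bin_size": grid.bin_size, "flank_window": FLANK_WINDOW}
    )


def select_gene_panel(
    hc_snps: Sequence[HighConfidenceSnp],
    targets: Sequence[GeneModel],
    impact_by_snp: Mapping[VariantKey, str] | None = None,
    k: int = K_PER_GENE,
    linkage_window: int = LINKAGE_WINDOW,
) -> PanelSelection:
    """k SNPs per target gene: MAF descending, then impact severity
    (HIGH > MODERATE > LOW > MODIFIER), then position ascending.

    Candidates are eligible SNPs inside the gene span; the span widens by
    ``linkage_window`` on both sides only when fewer than k in-gene
    candidates exist. Genes still short of k are reported in ``shortfalls``.
    """
    target_genes = [g for g in targets if g.is_target]
    if not target_genes:
        raise ValueError("no target genes supplied")
    impact_by_snp = impact_by_snp or {}

    by_chrom: dict[str, list[HighConfidenceSnp]] = {}
    for s in hc_snps:
        if is_eligible(s):
            by_chrom.setdefault(s.key.chrom, []).append(s)
    for lst in by_chrom.values():
        lst.sort(key=lambda s: s.key.pos)

    def in_window(chrom: str, lo: int, hi: int) -> list[HighConfidenceSnp]:
        lst = by_chrom.get(chrom, [])
        positions = [s.key.pos for s in lst]
        i = bisect_left(positions, lo)
        j = bisect_right(positions, hi)
        return lst[i:j]

    entries: list[PanelEntry] = []
    shortfalls: dict[str, int] = {}
    for gene in sorted(target_genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
        cand = in_window(gene.chrom, gene.start, gene.end)
        if len(cand) < k:
            cand = in_window(gene.chrom, gene.start - linkage_window, gene.end + linkage_window)
        ranked = sorted(
            cand,
            key=lambda s: (
                -s.maf,
                IMPACT_RANK[impact_by_snp.get(s.key, MODIFIER)],
                s.key.pos,
                s.key,
            ),
        )
        chosen = ranked[:k]
        if len(chosen) < k:
            shortfalls[gene.gene_id] = len(chosen)
        for rank, s in enumerate(chosen, 1):
            entries.append(
                PanelEntry(
                    s.key,
                    s.maf,
                    s.states_observed,
                    impact_by_snp.get(s.key, MODIFIER),
                    gene.gene_id,
                    rank,
                )
            )
    return PanelSelection(
        "gene_targeted",
        entries,
        parameters={"k_per_gene": k, "linkage_window": linkage_window, "flank_window": FLANK_WINDOW},
        shortfalls=shortfalls,
    )
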