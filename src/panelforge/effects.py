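"""Lightweight SnpEff-style effect classification for bi-allelic SNPs.

Each SNP is classified against each overlapping single-transcript gene model
(gene span padded by a 5 kb flank) into one effect type, which maps to a
four-level impact class:

==================  ========
effect type         impact
==================  ========
splice_acceptor_variant  HIGH
splice_donor_variant     HIGH
start_lost               HIGH
stop_gained              HIGH
stop_lost                HIGH
missense_variant         MODERATE
initiator_codon_variant  LOW
splice_region_variant    LOW
synonymous_variant       LOW
modifier_variant         MODIFIER
==================  ========

Decision order per transcript: splice donor (first 2 intron bases in
transcription order), splice acceptor (last 2 intron bases), intronic splice
region (intron bases 3-8 from either junction), CDS codon change (rebuilt on
the coding strand and translated with the standard nuclear code), exonic
splice region (the 3 exon bases adjacent to a junction, unless the CDS call
is of higher impact than LOW), and everything else in or near the gene —
UTR, deep intron, up/downstream flank — collapses to MODIFIER. Alternate
initiator codons CTG/TTG demote a destroyed ATG from start_lost to
initiator_codon_variant; any other substitution of the start codon is
start_lost.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .vario import GeneModel, VariantKey, revcomp

HIGH = "HIGH"
MODERATE = "MODERATE"
LOW = "LOW"
MODIFIER = "MODIFIER"

IMPACT_ORDER = (HIGH, MODERATE, LOW, MODIFIER)
IMPACT_RANK = {c: i for i, c in enumerate(IMPACT_ORDER)}

IMPACT_OF_EFFECT: dict[str, str] = {
    "splice_acceptor_variant": HIGH,
    "splice_donor_variant": HIGH,
    "start_lost": HIGH,
    "stop_gained": HIGH,
    "stop_lost": HIGH,
    "missense_variant": MODERATE,
    "initiator_codon_variant": LOW,
    "splice_region_variant": LOW,
    "synonymous_variant": LOW,
    "modifier_variant": MODIFIER,
}

#: effect types in the conventional summary-table row order
EFFECT_TYPES = tuple(IMPACT_OF_EFFECT)

STOP_CODONS = {"TAA", "TAG", "TGA"}
ALT_INITIATORS = {"CTG", "TTG"}

#: up/downstream window around the gene span still reported as MODIFIER
GENE_FLANK = 5000


@dataclass(frozen=True)
class SpliceWindows:
    """Splice-site geometry: donor/acceptor are the first/last 2 intron bases;
    the splice region covers intron bases ``intron_lo``..``intron_hi`` from a
    junction and the ``exon_width`` exon bases adjacent to a junction."""

    intron_lo: int = 3
    intron_hi: int = 8
    exon_width: int = 3


DEFAULT_WINDOWS = SpliceWindows()


@dataclass(frozen=True)
class EffectCall:
    key: VariantKey
    gene_id: str | None
    transcript_id: str | None
    effect_type: str

    @property
    def impact(self) -> str:
        return IMPACT_OF_EFFECT[self.effect_type]


class _TranscriptIndex:
    """Per-transcript coordinate machinery shared by all SNPs hitting it."""

    def __init__(self, gene: GeneModel, genome: Mapping[str, str]):
        self.gene = gene
        seq = genome[gene.chrom]
        fwd = gene.strand == "+"

        cds_asc = [(s, e) for s, e, _ in gene.cds]
        segs = cds_asc if fwd else cds_asc[::-1]  # transcription order
        self.coding_index: dict[int, int] = {}
        coding_parts = []
        i = 0
        for s, e in segs:
            positions = range(s, e + 1) if fwd else range(e, s - 1, -1)
            for pos in positions:
                self.coding_index[pos] = i
                i += 1
            part = seq[s - 1 : e]
            coding_parts.append(part if fwd else revcomp(part))
        self.coding_seq = "".join(coding_parts).upper()

        # introns between consecutive exons (ascending genomic order)
        self.donor: set[int] = set()
        self.acceptor: set[int] = set()
        self.intron_region: set[int] = set()
        self.intron_all: set[int] = set()
        w = DEFAULT_WINDOWS
        for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
            ilo, ihi = e1 + 1, s2 - 1
            if ilo > ihi:
                continue
            left2 = {p for p in (ilo, ilo + 1) if p <= ihi}
            right2 = {p for p in (ihi, ihi - 1) if p >= ilo}
            if fwd:
                self.donor |= left2
                self.acceptor |= right2
            else:
                self.donor |= right2
                self.acceptor |= left2
            for p in range(ilo, ihi + 1):
                self.intron_all.add(p)
                d = min(p - ilo, ihi - p) + 1  # 1-based distance into intron
                if w.intron_lo <= d <= w.intron_hi:
                    self.intron_region.add(p)

        # exon bases within exon_width of an intron junction
        self.exon_edge: set[int] = set()
        n_ex = len(gene.exons)
        for idx, (s, e) in enumerate(gene.exons):
            if idx > 0:  # left edge abuts an intron
                self.exon_edge |= set(range(s, min(e, s + w.exon_width - 1) + 1))
            if idx < n_ex - 1:  # right edge abuts an intron
                self.exon_edge |= set(range(max(s, e - w.exon_width + 1), e + 1))

    def classify(self, key: VariantKey, genome: Mapping[str, str]) -> str:
        gene = self.gene
        pos = key.pos
        ref_base = genome[gene.chrom][pos - 1].upper()
        if ref_base != key.ref:
            raise ValueError(
                f"reference mismatch at {key.chrom}:{key.pos}: genome has "
                f"{ref_base}, variant claims {key.ref}"
            )
        if pos in self.donor:
            return "splice_donor_variant"
        if pos in self.acceptor:
            return "splice_acceptor_variant"
        if pos in self.intron_region:
            return "splice_region_variant"
        if pos in self.coding_index:
            cds_call = self._cds_effect(pos, key.alt, gene.strand == "+")
            if pos in self.exon_edge and IMPACT_RANK[IMPACT_OF_EFFECT[cds_call]] >= IMPACT_RANK[LOW]:
                return "splice_region_variant"
            return cds_call
        if pos in self.exon_edge:
            return "splice_region_variant"
        return "modifier_variant"

    def _cds_effect(self, pos: int, alt: str, fwd: bool) -> str:
        i = self.coding_index[pos]
        alt_coding = alt if fwd else revcomp(alt)
        codon_start = (i // 3) * 3
        ref_codon = self.coding_seq[codon_start : codon_start + 3]
        within = i % 3
        alt_codon = ref_codon[:within] + alt_coding + ref_codon[within + 1 :]
        if codon_start == 0:
            if alt_codon != "ATG":
                return (
                    "initiator_codon_variant"
                    if alt_codon in ALT_INITIATORS
                    else "start_lost"
                )
            return "synonymous_variant"  # unreachable for SNPs (ref codon is ATG)
        ref_is_stop = ref_codon in STOP_CODONS
        alt_is_stop = alt_codon in STOP_CODONS
        if ref_is_stop and not alt_is_stop:
            return "stop_lost"
        if alt_is_stop and not ref_is_stop:
            return "stop_gained"
        if ref_is_stop and alt_is_stop:
            return "synonymous_variant"
        ref_aa = str(Seq(ref_codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        return "missense_variant" if ref_aa != alt_aa else "synonymous_variant"


def classify_effect(
    key: VariantKey, gene: GeneModel, genome: Mapping[str, str]
) -> list[EffectCall]:
    """Classify one SNP against one gene model. Returns [] for a gene whose
    CDS frame is inconsistent (such transcripts are skipped)."""
    if not gene.cds_valid:
        return []
    idx = _TranscriptIndex(gene, genome)
    effect = idx.classify(key, genome)
    return [EffectCall(key, gene.gene_id, gene.transcript_id, effect)]


def annotate_variants(
    keys: Iterable[VariantKey],
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    gene_flank: int = GENE_FLANK,
) -> list[EffectCall]:
    """Classify every SNP against every gene whose padded span contains it.

    One EffectCall per (SNP, transcript); SNPs hitting no padded gene span
    get a single intergenic modifier call so that totals count every SNP.
    """
    by_chrom: dict[str, list[tuple[int, int, _TranscriptIndex]]] = {}
    for g in genes:
        if not g.cds_valid:
            continue
        by_chrom.setdefault(g.chrom, []).append(
            (g.start - gene_flank, g.end + gene_flank, _TranscriptIndex(g, genome))
        )
    for lst in by_chrom.values():
        lst.sort(key=lambda t: t[0])

    out: list[EffectCall] = []
    for key in keys:
        hit = False
        for lo, hi, idx in by_chrom.get(key.chrom, ()):
            if lo > key.pos:
                break
            if lo <= key.pos <= hi:
                hit = True
                out.append(
                    EffectCall(key, idx.gene.gene_id, idx.gene.transcript_id, idx.classify(key, genome))
                )
        if not hit:
            out.append(EffectCall(key, None, None, "modifier_variant"))
    return out


@dataclass
class ImpactSummary:
    """Aggregate of effect calls in the shape of a SnpEff summary table."""

    effect_counts: dict[str, int]
    class_counts: dict[str, int]
    class_percent: dict[str, float] | None
    total: int
    n_snps_non_modifier: int | None = None
    n_genes: int | None = None

    def to_frame(self) -> pd.DataFrame:
        """Table with columns (impact class, effect type, count, percent):
        one header row per class followed by its member effect types."""
        rows = []
        for cls in IMPACT_ORDER:
            pct = "" if self.class_percent is None else f"{self.class_percent[cls]:.2f}"
            members = [t for t in EFFECT_TYPES if IMPACT_OF_EFFECT[t] == cls]
            if len(members) == 1:
                rows.append((cls, members[0], self.effect_counts.get(members[0], 0), pct))
            else:
                rows.append((cls, "", self.class_counts[cls], pct))
                for t in members:
                    rows.append(("", t, self.effect_counts.get(t, 0), ""))
        pct_total = "" if self.class_percent is None else "100.00"
        rows.append(("Total", "", self.total, pct_total))
        return pd.DataFrame(rows, columns=["impact_class", "effect_type", "count", "percent"])


def summarize_effect_counts(counts: Mapping[str, int]) -> ImpactSummary:
    """Build an ImpactSummary from per-effect-type counts alone."""
    unknown = set(counts) - set(EFFECT_TYPES)
    if unknown:
        raise ValueError(f"unknown effect types: {sorted(unknown)}")
    effect_counts = {t: int(counts.get(t, 0)) for t in EFFECT_TYPES}
    class_counts = {c: 0 for c in IMPACT_ORDER}
    for t, n in effect_counts.items():
        class_counts[IMPACT_OF_EFFECT[t]] += n
    total = sum(class_counts.values())
    if total:
        class_percent = {c: round(100.0 * n / total, 2) for c, n in class_counts.items()}
    else:
        class_percent = None
    return ImpactSummary(effect_counts, class_counts, class_percent, total)


def summarize_impacts(effects: Sequence[EffectCall]) -> ImpactSummary:
    """Summarize a list of effect calls, including distinct-SNP and
    distinct-gene tallies for the non-MODIFIER portion."""
    summary = summarize_effect_counts(Counter(e.effect_type for e in effects))
    summary.n_snps_non_modifier = len(
        {e.key for e in effects if e.impact != MODIFIER}
    )
    summary.n_genes = len(
        {e.gene_id for e in effects if e.gene_id is not None and e.impact != MODIFIER}
    )
    return summary


def worst_impact_per_snp(effects: Iterable[EffectCall]) -> dict[VariantKey, str]:
    """Per-SNP severity used for gene-panel ranking: HIGH > MODERATE > LOW > MODIFIER."""
    worst: dict[VariantKey, str] = {}
    for e in effects:
        cur = worst.get(e.key)
        if cur is None or IMPACT_RANK[e.impact] < IMPACT_RANK[cur]:
            worst[e.key] = e.impact
    return worst
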