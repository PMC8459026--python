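"""Independent brute-force oracles used to cross-check the implementation.

Each oracle deliberately takes the slow, obvious route (full retranslation,
O(n^2) scans, naive counting) so that agreement with the fast implementation
is meaningful.
"""

from __future__ import annotations

from Bio.Seq import Seq

from panelforge.vario import GeneModel, VariantKey

STOPS = {"TAA", "TAG", "TGA"}
ALT_STARTS = {"CTG", "TTG"}


def extract_cds(gene: GeneModel, genome_seq: str) -> str:
    """Concatenated coding sequence on the coding strand, by genome slicing."""
    parts = [genome_seq[s - 1 : e] for s, e, _ in gene.cds]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def retranslation_effect(key: VariantKey, gene: GeneModel, genome_seq: str) -> str | None:
    """Effect of a CDS SNP by mutating the genome, rebuilding the whole CDS
    and diffing the full translations. Returns None for non-CDS positions."""
    in_cds = any(s <= key.pos <= e for s, e, _ in gene.cds)
    if not in_cds:
        return None
    assert genome_seq[key.pos - 1] == key.ref
    mutated = genome_seq[: key.pos - 1] + key.alt + genome_seq[key.pos :]
    ref_cds = extract_cds(gene, genome_seq)
    alt_cds = extract_cds(gene, mutated)
    assert len(ref_cds) == len(alt_cds) and ref_cds != alt_cds

    if alt_cds[:3] != ref_cds[:3]:
        # the initiator codon itself was hit
        if alt_cds[:3] == "ATG":
            return "synonymous_variant"
        return "initiator_codon_variant" if alt_cds[:3] in ALT_STARTS else "start_lost"

    ref_prot = str(Seq(ref_cds).translate())  # includes terminal '*'
    alt_prot = str(Seq(alt_cds).translate())
    if ref_prot == alt_prot:
        return "synonymous_variant"
    diffs = [i for i, (a, b) in enumerate(zip(ref_prot, alt_prot)) if a != b]
    assert len(diffs) == 1
    i = diffs[0]
    if ref_prot[i] == "*" and alt_prot[i] != "*":
        return "stop_lost"
    if alt_prot[i] == "*" and ref_prot[i] != "*":
        return "stop_gained"
    return "missense_variant"


def splice_geometry(gene: GeneModel, intron_window=(3, 8), exon_width=3):
    """Donor/acceptor/splice-region position sets computed directly from the
    exon intervals (independent of the classifier's internals)."""
    donor, acceptor, intron_region, exon_edge = set(), set(), set(), set()
    fwd = gene.strand == "+"
    for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
        ilo, ihi = e1 + 1, s2 - 1
        left2 = {ilo, ilo + 1}
        right2 = {ihi - 1, ihi}
        donor |= left2 if fwd else right2
        acceptor |= right2 if fwd else left2
        for p in range(ilo, ihi + 1):
            d = min(p - ilo, ihi - p) + 1
            if intron_window[0] <= d <= intron_window[1]:
                intron_region.add(p)
    for idx, (s, e) in enumerate(gene.exons):
        if idx > 0:
            exon_edge |= set(range(s, s + exon_width))
        if idx < len(gene.exons) - 1:
            exon_edge |= set(range(e - exon_width + 1, e + 1))
    return donor, acceptor, intron_region, exon_edge


IMPACT = {
    "splice_acceptor_variant": 0,
    "splice_donor_variant": 0,
    "start_lost": 0,
    "stop_gained": 0,
    "stop_lost": 0,
    "missense_variant": 1,
    "initiator_codon_variant": 2,
    "splice_region_variant": 2,
    "synonymous_variant": 2,
    "modifier_variant": 3,
}


def expected_effect(key: VariantKey, gene: GeneModel, genome_seq: str) -> str:
    """Full expected classification combining splice geometry with the
    retranslation oracle, following the documented decision order."""
    donor, acceptor, intron_region, exon_edge = splice_geometry(gene)
    pos = key.pos
    if pos in donor:
        return "splice_donor_variant"
    if pos in acceptor:
        return "splice_acceptor_variant"
    if pos in intron_region:
        return "splice_region_variant"
    cds_call = retranslation_effect(key, gene, genome_seq)
    if cds_call is not None:
        if pos in exon_edge and IMPACT[cds_call] >= 2:
            return "splice_region_variant"
        return cds_call
    if pos in exon_edge:
        return "splice_region_variant"
    return "modifier_variant"


def naive_consensus(callset_keys: list[set], min_support: int) -> set:
    """Brute-force >= min_support-of-n filter by counting over all keys."""
    counts: dict = {}
    for keys in callset_keys:
        for k in keys:
            counts[k] = counts.get(k, 0) + 1
    return {k for k, c in counts.items() if c >= min_support}


def naive_flank_clear(pos: int, all_positions: list[int], window: int) -> bool:
    """O(n^2)-style all-pairs distance scan."""
    return all(not (0 < abs(p - pos) <= window) for p in all_positions)


def naive_gwas_argmax(eligible, bin_size: int):
    """Per-bin exhaustive argmax over (maf desc, pos asc, key asc).

    ``eligible`` is a list of (VariantKey, maf). Returns {(chrom, bin): key}.
    """
    by_bin: dict = {}
    for key, maf in eligible:
        by_bin.setdefault((key.chrom, (key.pos - 1) // bin_size), []).append((key, maf))
    out = {}
    for b, lst in by_bin.items():
        best = min(lst, key=lambda t: (-t[1], t[0].pos, t[0]))
        out[b] = best[0]
    return out
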