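"""Effect classification against gene models, checked by independent oracles."""

import numpy as np
import pytest

from panelforge.effects import (
    IMPACT_OF_EFFECT,
    annotate_variants,
    classify_effect,
    summarize_effect_counts,
    summarize_impacts,
    worst_impact_per_snp,
)
from panelforge.vario import GeneModel, VariantKey, revcomp

from .conftest import build_gene, make_cds
from .oracles import expected_effect

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _call(key, gene, genome):
    calls = classify_effect(key, gene, genome)
    assert len(calls) == 1
    return calls[0]


class TestPointExamples:
    def test_synonymous_third_codon_position(self):
        # CDS: ATG GGA ... -> GGA->GGG is Gly->Gly
        cds = "ATG" + "GGA" + "AAA" + "TAA"
        genome, gene = build_gene(cds, [12], [], strand="+")
        pos = gene.start + 5  # third base of codon 2
        assert genome["toy"][pos - 1] == "A"
        call = _call(VariantKey("toy", pos, "A", "G"), gene, genome)
        assert call.effect_type == "synonymous_variant"
        assert call.impact == "LOW"

    def test_stop_gained_tgg_to_tga(self):
        cds = "ATG" + "TGG" + "AAA" + "TAA"
        genome, gene = build_gene(cds, [12], [], strand="+")
        pos = gene.start + 5  # TGG -> TGA
        assert genome["toy"][pos - 1] == "G"
        call = _call(VariantKey("toy", pos, "G", "A"), gene, genome)
        assert call.effect_type == "stop_gained"
        assert call.impact == "HIGH"

    def test_splice_donor_first_intron_base(self):
        cds = make_cds(8, np.random.default_rng(1))
        genome, gene = build_gene(cds, [12, 12], [30], strand="+")
        donor_pos = gene.exons[0][1] + 1  # the G of the GT dinucleotide
        ref = genome["toy"][donor_pos - 1]
        assert ref == "G"
        call = _call(VariantKey("toy", donor_pos, ref, "C"), gene, genome)
        assert call.effect_type == "splice_donor_variant"
        assert call.impact == "HIGH"

    def test_start_lost_vs_initiator_codon(self):
        cds = "ATG" + "CCA" + "TAA"
        genome, gene = build_gene(cds, [9], [], strand="+")
        s = gene.start
        # ATG->CTG: recognised alternate initiator, LOW
        call = _call(VariantKey("toy", s, "A", "C"), gene, genome)
        assert call.effect_type == "initiator_codon_variant"
        # ATG->AGG: start destroyed outright, HIGH
        call = _call(VariantKey("toy", s + 1, "T", "G"), gene, genome)
        assert call.effect_type == "start_lost"

    def test_stop_lost(self):
        cds = "ATG" + "AAA" + "TAA"
        genome, gene = build_gene(cds, [9], [], strand="+")
        pos = gene.end  # TAA -> TAC
        call = _call(VariantKey("toy", pos, "A", "C"), gene, genome)
        assert call.effect_type == "stop_lost"

    def test_ref_mismatch_raises(self):
        cds = "ATG" + "AAA" + "TAA"
        genome, gene = build_gene(cds, [9], [], strand="+")
        wrong = "C" if genome["toy"][gene.start - 1] != "C" else "G"
        with pytest.raises(ValueError, match="mismatch"):
            classify_effect(VariantKey("toy", gene.start, wrong, "T"), gene, genome)

    def test_invalid_cds_transcript_skipped(self):
        genome, gene = build_gene("ATG" + "AAA" + "TAA", [9], [], strand="+")
        bad = GeneModel(
            gene_id="bad", transcript_id="bad.t1", chrom="toy", strand="+",
            exons=[(gene.start, gene.start + 7)], cds=[(gene.start, gene.start + 7, 0)],
        )
        assert not bad.cds_valid
        assert classify_effect(VariantKey("toy", gene.start + 3, genome["toy"][gene.start + 2], "A" if genome["toy"][gene.start + 2] != "A" else "C"), bad, genome) == []


def _enumerate_all(genome, gene, lo=None, hi=None):
    """Every (pos, alt) substitution over the padded gene span."""
    seq = genome[gene.chrom]
    lo = lo or max(1, gene.start - 20)
    hi = hi or min(len(seq), gene.end + 20)
    for pos in range(lo, hi + 1):
        ref = seq[pos - 1]
        for alt in "ACGT":
            if alt != ref:
                yield VariantKey(gene.chrom, pos, ref, alt)


@pytest.mark.parametrize("strand", ["+", "-"])
@pytest.mark.parametrize("n_exons", [2, 3])
def test_exhaustive_agreement_with_retranslation_oracle(strand, n_exons):
    """Every substitution at every position of a multi-exon toy gene agrees
    with the combined splice-geometry + full-retranslation oracle."""
    rng = np.random.default_rng(7 + n_exons)
    n_codons = 24
    cds = make_cds(n_codons, rng)
    exon_lens = {2: [30, 42], 3: [21, 24, 27]}[n_exons]
    intron_lens = [25] * (n_exons - 1)
    genome, gene = build_gene(cds, exon_lens, intron_lens, strand=strand, rng=rng)
    n_checked = 0
    for key in _enumerate_all(genome, gene):
        got = _call(key, gene, genome).effect_type
        want = expected_effect(key, gene, genome[gene.chrom])
        assert got == want, f"{key} ({strand}): got {got}, want {want}"
        n_checked += 1
    assert n_checked > 3 * (sum(exon_lens) + sum(intron_lens))


def test_strand_symmetry_on_mirrored_constructs():
    """Classifying a SNP against a minus-strand gene equals classifying the
    reverse-complemented SNP against the same construct built on plus."""
    rng = np.random.default_rng(23)
    cds = make_cds(15, rng)
    exon_lens, intron_lens = [18, 27], [30]
    genome_p, gene_p = build_gene(cds, exon_lens, intron_lens, strand="+", rng=np.random.default_rng(5))
    genome_m, gene_m = build_gene(cds, exon_lens, intron_lens, strand="-", rng=np.random.default_rng(5))
    L = len(genome_p["toy"])
    assert genome_m["toy"] != genome_p["toy"]
    for key in _enumerate_all(genome_p, gene_p, lo=gene_p.start, hi=gene_p.end):
        # the same construct coordinate, seen from the minus-strand placement
        mpos_offset = key.pos - gene_p.start  # offset into the sense gene sequence
        mpos = gene_m.end - mpos_offset
        mkey = VariantKey("toy", mpos, COMP[key.ref], COMP[key.alt])
        assert genome_m["toy"][mpos - 1] == mkey.ref
        assert _call(key, gene_p, genome_p).effect_type == _call(mkey, gene_m, genome_m).effect_type


class TestAnnotateAndSummary:
    def test_intergenic_and_flank_are_modifier(self):
        cds = "ATG" + "AAA" + "TAA"
        genome, gene = build_gene(cds, [9], [], upstream=300, downstream=300)
        keys = [
            VariantKey("toy", 5, genome["toy"][4], "A" if genome["toy"][4] != "A" else "C"),
            VariantKey("toy", gene.start - 30, genome["toy"][gene.start - 31],
                       "A" if genome["toy"][gene.start - 31] != "A" else "C"),
        ]
        calls = annotate_variants(keys, [gene], genome, gene_flank=50)
        assert [c.effect_type for c in calls] == ["modifier_variant"] * 2
        assert calls[0].gene_id is None  # beyond the flank: intergenic
        assert calls[1].gene_id == "g1"  # within the 50 bp flank

    def test_summary_counts_and_percents(self):
        counts = {"synonymous_variant": 1}
        s = summarize_effect_counts(counts)
        assert s.class_counts["LOW"] == 1 and s.class_percent["LOW"] == 100.0
        assert summarize_effect_counts({}).class_percent is None

    def test_summary_consistency_on_annotated_set(self):
        rng = np.random.default_rng(3)
        cds = make_cds(20, rng)
        genome, gene = build_gene(cds, [30, 30], [40], rng=rng)
        keys = list(_enumerate_all(genome, gene))
        calls = annotate_variants(keys, [gene], genome)
        s = summarize_impacts(calls)
        assert s.total == len(calls)
        assert sum(s.class_counts.values()) == sum(s.effect_counts.values()) == s.total
        assert abs(sum(s.class_percent.values()) - 100.0) <= 0.02
        non_mod = s.class_counts["HIGH"] + s.class_counts["MODERATE"] + s.class_counts["LOW"]
        assert s.n_snps_non_modifier <= non_mod
        worst = worst_impact_per_snp(calls)
        assert set(worst.values()) <= set(IMPACT_OF_EFFECT.values())
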