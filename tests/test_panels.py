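"""Panel selection: flank conservation, binned max-MAF, per-gene top-k."""

import numpy as np
import pytest

from panelforge.consensus import ALL_STATES, HighConfidenceSnp
from panelforge.panels import (
    BinGrid,
    PanelSelection,
    flank_is_conserved,
    is_eligible,
    select_gene_panel,
    select_gwas_panel,
)
from panelforge.vario import GeneModel, VariantKey, write_panel

from .oracles import naive_flank_clear, naive_gwas_argmax


def _snp(pos, maf=0.3, chrom="chr1", states=ALL_STATES, flank=True, ref="A", alt="G"):
    return HighConfidenceSnp(
        key=VariantKey(chrom, pos, ref, alt),
        support=frozenset({"deep_ref", "shotgun"}),
        maf=maf,
        n_called=20,
        states_observed=frozenset(states),
        flank_clear=flank,
    )


class TestFlank:
    def test_51bp_clear_on_both_sides(self):
        known = {"chr1": np.array([949, 1000, 1051])}
        assert flank_is_conserved(VariantKey("chr1", 1000, "A", "G"), known, 50)

    def test_exactly_50_fails(self):
        known = {"chr1": np.array([1000, 1050])}
        assert not flank_is_conserved(VariantKey("chr1", 1000, "A", "G"), known, 50)

    def test_self_and_colocated_variant_ignored(self):
        # another substitution at the same position is distance 0: not "nearby"
        known = {"chr1": np.array([1000])}
        assert flank_is_conserved(VariantKey("chr1", 1000, "A", "G"), known, 50)

    def test_agrees_with_all_pairs_scan(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            positions = sorted(set(rng.integers(1, 20_000, size=500).tolist()))
            known = {"chr1": np.array(positions)}
            for pos in positions:
                got = flank_is_conserved(VariantKey("chr1", pos, "A", "G"), known, 50)
                want = naive_flank_clear(pos, positions, 50)
                assert got == want, pos


class TestBinGrid:
    def test_bins_tile_chromosome(self):
        grid = BinGrid({"chr1": 12_000}, bin_size=5000)
        assert grid.n_bins("chr1") == 3  # terminal partial bin is a legal bin
        assert grid.bin_index(1) == 0
        assert grid.bin_index(5000) == 0
        assert grid.bin_index(5001) == 1
        assert grid.bin_index(12_000) == 2


class TestGwasPanel:
    def test_argmax_per_bin(self):
        snps = [_snp(100, 0.10), _snp(200, 0.30), _snp(300, 0.22)]
        sel = select_gwas_panel(snps, BinGrid({"chr1": 5000}))
        assert len(sel) == 1 and sel.entries[0].key.pos == 200

    def test_state_filter_empties_bin(self):
        snps = [_snp(100, 0.4, states={"hom_ref", "hom_alt"})]
        sel = select_gwas_panel(snps, BinGrid({"chr1": 5000}))
        assert len(sel) == 0

    def test_tie_breaks_to_smaller_position(self):
        snps = [_snp(400, 0.3), _snp(150, 0.3)]
        sel = select_gwas_panel(snps, BinGrid({"chr1": 5000}))
        assert sel.entries[0].key.pos == 150

    def test_matches_exhaustive_oracle_on_random_placements(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            snps = []
            for pos in sorted(set(rng.integers(1, 10_000, size=60).tolist())):
                eligible = rng.random() < 0.7
                snps.append(
                    _snp(
                        pos,
                        maf=round(float(rng.uniform(0, 0.5)), 3),
                        states=ALL_STATES if eligible else {"het"},
                    )
                )
            sel = select_gwas_panel(snps, BinGrid({"chr1": 10_000}, bin_size=5000))
            want = naive_gwas_argmax(
                [(s.key, s.maf) for s in snps if is_eligible(s)], 5000
            )
            got = {(e.key.chrom, int(e.group.split(":")[1])): e.key for e in sel.entries}
            assert got == want

    def test_removing_input_never_grows_panel(self):
        snps = [_snp(p, maf=0.1 + (p % 7) / 20) for p in range(100, 9000, 400)]
        grid = BinGrid({"chr1": 10_000})
        full = len(select_gwas_panel(snps, grid))
        assert full <= grid.total_bins
        for i in range(len(snps)):
            reduced = select_gwas_panel(snps[:i] + snps[i + 1 :], grid)
            assert len(reduced) <= full


def _gene(gene_id, start, end, chrom="chr1", target=True):
    return GeneModel(
        gene_id=gene_id, transcript_id=f"{gene_id}.t1", chrom=chrom, strand="+",
        exons=[(start, end)], cds=[], is_target=target,
    )


class TestGenePanel:
    def test_priority_maf_then_impact(self):
        gene = _gene("g1", 1000, 2000)
        snps = [_snp(1100, 0.4), _snp(1200, 0.4), _snp(1300, 0.3)]
        impacts = {snps[0].key: "MODIFIER", snps[1].key: "MODERATE", snps[2].key: "HIGH"}
        sel = select_gene_panel(snps, [gene], impacts, k=2)
        assert [e.key.pos for e in sel.entries] == [1200, 1100]  # MODERATE outranks MODIFIER
        assert [e.rank for e in sel.entries] == [1, 2]

    def test_linkage_fallback_only_on_shortfall(self):
        gene = _gene("g1", 1000, 2000)
        inside = [_snp(1500, 0.1), _snp(1600, 0.2)]
        nearby_better = _snp(2500, 0.5)  # higher MAF but outside the span
        sel = select_gene_panel(inside + [nearby_better], [gene], {}, k=2)
        assert {e.key.pos for e in sel.entries} == {1500, 1600}
        # with only one in-gene candidate the window widens
        sel2 = select_gene_panel([inside[0], nearby_better], [gene], {}, k=2, linkage_window=5000)
        assert {e.key.pos for e in sel2.entries} == {1500, 2500}

    def test_shortfall_reported(self):
        gene = _gene("g1", 1000, 2000)
        sel = select_gene_panel([_snp(1500, 0.1)], [gene], {}, k=2, linkage_window=100)
        assert sel.shortfalls == {"g1": 1}

    def test_empty_target_list_rejected(self):
        with pytest.raises(ValueError, match="target"):
            select_gene_panel([_snp(10)], [_gene("g", 1, 5, target=False)], {})

    def test_matches_sort_and_take_oracle(self):
        rank = {"HIGH": 0, "MODERATE": 1, "LOW": 2, "MODIFIER": 3}
        gene = _gene("g1", 1, 10_000)
        for seed in range(50):
            rng = np.random.default_rng(seed)
            snps, impacts = [], {}
            for pos in sorted(set(rng.integers(1, 10_000, size=30).tolist())):
                s = _snp(pos, maf=round(float(rng.uniform(0.01, 0.5)), 2))
                snps.append(s)
                impacts[s.key] = str(rng.choice(list(rank)))
            sel = select_gene_panel(snps, [gene], impacts, k=2)
            want = sorted(snps, key=lambda s: (-s.maf, rank[impacts[s.key]], s.key.pos, s.key))[:2]
            assert [e.key for e in sel.entries] == [s.key for s in want]


class TestDeterminismAndOutput:
    def test_selection_independent_of_input_order(self, tmp_path):
        rng = np.random.default_rng(4)
        snps = [_snp(p, maf=round(float(rng.uniform(0, 0.5)), 3)) for p in range(50, 9000, 111)]
        grid = BinGrid({"chr1": 10_000})
        a = select_gwas_panel(snps, grid)
        b = select_gwas_panel(list(reversed(snps)), grid)
        fa, fb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_panel(a, fa, "tsv")
        write_panel(b, fb, "tsv")
        assert fa.read_bytes() == fb.read_bytes()

    def test_panel_tsv_and_bed_shapes(self, tmp_path):
        sel = select_gene_panel([_snp(1500, 0.1), _snp(1600, 0.2)], [_gene("g1", 1000, 2000)], {}, k=2)
        tsv, bed = tmp_path / "p.tsv", tmp_path / "p.bed"
        write_panel(sel, tsv, "tsv")
        write_panel(sel, bed, "bed")
        lines = tsv.read_text().strip().splitlines()
        assert len(lines) == 3  # header + 2 SNPs
        bed_line = bed.read_text().splitlines()[0].split("\t")
        assert int(bed_line[2]) - int(bed_line[1]) == 1  # 0-based half-open point
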