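"""Shared fixtures and toy-construct builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from panelforge.vario import GeneModel, revcomp

STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOPS and a + b + c != "ATG"
]


def make_cds(n_codons: int, rng: np.random.Generator, stop: str = "TAA") -> str:
    """ATG + random sense codons + stop; legal CDS of 3*n_codons bases."""
    assert n_codons >= 2
    middle = "".join(rng.choice(SENSE_CODONS) for _ in range(n_codons - 2))
    return "ATG" + middle + stop


def build_gene(
    cds: str,
    exon_lens: list[int],
    intron_lens: list[int],
    strand: str = "+",
    chrom: str = "toy",
    upstream: int = 100,
    downstream: int = 100,
    rng: np.random.Generator | None = None,
    gene_id: str = "g1",
) -> tuple[dict[str, str], GeneModel]:
    """Place a CDS split into exons (with GT..AG introns) into a toy genome.

    Exon lengths must sum to len(cds). Coordinates are mirrored for the
    minus strand (the inserted sequence is reverse-complemented).
    """
    assert sum(exon_lens) == len(cds)
    assert len(intron_lens) == len(exon_lens) - 1
    if rng is None:
        rng = np.random.default_rng(0)
    parts = []
    off = 0
    exon_offsets = []  # (start, end) 0-based offsets in the sense gene sequence
    cursor = 0
    for i, elen in enumerate(exon_lens):
        exon_offsets.append((cursor, cursor + elen - 1))
        parts.append(cds[off : off + elen])
        off += elen
        cursor += elen
        if i < len(intron_lens):
            ilen = intron_lens[i]
            assert ilen >= 4
            body = "".join(rng.choice(list("ACGT")) for _ in range(ilen - 4))
            parts.append("GT" + body + "AG")
            cursor += ilen
    gene_seq = "".join(parts)
    flank_up = "".join(rng.choice(list("ACGT")) for _ in range(upstream))
    flank_dn = "".join(rng.choice(list("ACGT")) for _ in range(downstream))
    if strand == "+":
        genome_seq = flank_up + gene_seq + flank_dn
        start = upstream + 1
        exons = [(start + s, start + e) for s, e in exon_offsets]
    else:
        genome_seq = flank_up + revcomp(gene_seq) + flank_dn
        start = upstream + 1
        glen = len(gene_seq)
        exons = sorted((start + glen - 1 - e, start + glen - 1 - s) for s, e in exon_offsets)

    order = exons if strand == "+" else exons[::-1]
    phases = {}
    done = 0
    for s, e in order:
        phases[(s, e)] = (3 - done % 3) % 3
        done += e - s + 1
    model = GeneModel(
        gene_id=gene_id,
        transcript_id=f"{gene_id}.t1",
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds=[(s, e, phases[(s, e)]) for s, e in exons],
    )
    return {chrom: genome_seq}, model


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """A small default-parameter simulation, written to disk once per session."""
    from panelforge.synthgen import SimulationConfig, simulate_all

    cfg = SimulationConfig(seed=7)
    outdir = tmp_path_factory.mktemp("sim")
    paths = simulate_all(cfg, outdir)
    return cfg, paths
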