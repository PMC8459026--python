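"""Synthetic genome, gene-model, truth-SNP and callset generator.

Emulates the data layout of a shea-tree-style SNP-discovery study: one deep
phased callset from the reference accession, one deep unphased shotgun
callset from a second accession, and a skim-coverage resequencing panel of
31 genotypes with heavy genotype missingness. All three callsets are drawn
from a single shared truth set of segregating bi-allelic SNPs, plus
callset-private false positives, so that the downstream >=2-callset
consensus filter has a well-defined truth to recover.

Everything is driven by one :class:`numpy.random.Generator` seeded from the
config; identical seed + config gives byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .vario import BASES, Callset, GeneModel, VariantKey, revcomp, write_fasta, write_gff3, write_vcf

DEEP_REF = "deep_ref"
SHOTGUN = "shotgun"
SKIM_PANEL = "skim_panel"
DATASET_IDS = (DEEP_REF, SHOTGUN, SKIM_PANEL)

STOP_CODONS = ("TAA", "TAG", "TGA")

#: fatty-acid biosynthesis family labels cycled over simulated target genes
FAMILY_LABELS = ("KASI", "KASII", "KASIII", "FATB", "FAD2", "FAD3", "FAX2", "LACS")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the simulator, mirroring the emulated study's scale.

    Defaults follow the study design being emulated where it states a value:
    31-sample skim panel, ~1 SNP per 189 bp, ~33% GC, gene architecture of
    ~225 bp exons and ~1.1 kb introns with ~4 exons per gene. Error-model
    parameters (detection probability, false-positive rate, missingness) are
    the simulator's own, documented stand-ins.
    """

    n_chroms: int = 2
    genome_length_per_chrom: int = 250_000
    gc_content: float = 0.33
    n_genes: int = 24
    exons_per_gene: tuple[int, int] = (2, 7)
    mean_exon_len: int = 225
    mean_intron_len: int = 1134
    target_gene_fraction: float = 0.75
    snp_density: float = 1.0 / 189.0
    maf_alpha: float = 0.8
    maf_beta: float = 0.8
    panel_size: int = 31
    missing_rate: float = 0.35
    detect_prob: tuple[float, float, float] = (0.92, 0.90, 0.85)  # deep_ref, shotgun, skim
    fp_rate: float = 5e-4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc_content", "target_gene_fraction", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for p in self.detect_prob:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"detect_prob entries must be in [0,1], got {p}")
        if self.snp_density <= 0 or self.fp_rate < 0:
            raise ValueError("snp_density must be > 0 and fp_rate >= 0")
        if self.n_chroms < 1:
            raise ValueError("n_chroms must be >= 1")
        if self.panel_size < 1:
            raise ValueError("panel_size must be >= 1")
        lo, hi = self.exons_per_gene
        if not (1 <= lo <= hi):
            raise ValueError("exons_per_gene must be a (lo, hi) range with 1 <= lo <= hi")

    @property
    def n_target_genes(self) -> int:
        return round(self.n_genes * self.target_gene_fraction)


class GenePlacementError(RuntimeError):
    """Raised when genes cannot be placed on the configured genome."""


TRUTH_COLUMNS = ["chrom", "pos", "ref", "alt", "truth_af"]


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.array(list("ACGT")), size=length, p=p)


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n random sense (non-stop) codons."""
    out = []
    while len(out) < n:
        codon = "".join(rng.choice(np.array(list("ACGT")), size=3))
        if codon not in STOP_CODONS and codon != "ATG":
            out.append(codon)
    return "".join(out)


def _build_gene_sequence(rng: np.random.Generator, cfg: SimulationConfig) -> tuple[str, list[int], list[int]]:
    """Return (sense-strand gene sequence, exon lengths, intron lengths).

    The CDS is ATG + sense codons + stop, split across exons; introns carry
    canonical GT...AG splice dinucleotides. Exons coincide with CDS segments
    (no UTR), which keeps every exon base coding.
    """
    lo, hi = cfg.exons_per_gene
    n_exons = int(rng.integers(lo, hi + 1))
    exon_lens = [max(30, int(rng.poisson(cfg.mean_exon_len))) for _ in range(n_exons)]
    total = sum(exon_lens)
    exon_lens[-1] += (3 - total % 3) % 3  # make CDS length divisible by 3
    n_codons = sum(exon_lens) // 3
    cds = "ATG" + _random_codons(rng, n_codons - 2) + str(rng.choice(np.array(STOP_CODONS)))
    intron_lens = [max(60, int(rng.poisson(cfg.mean_intron_len))) for _ in range(n_exons - 1)]
    parts = []
    offset = 0
    for i, elen in enumerate(exon_lens):
        parts.append(cds[offset : offset + elen])
        offset += elen
        if i < n_exons - 1:
            ilen = intron_lens[i]
            body = "".join(_random_seq(rng, ilen - 4, cfg.gc_content))
            parts.append("GT" + body + "AG")
    return "".join(parts), exon_lens, intron_lens


def simulate_genome(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[GeneModel]]:
    """Simulate chromosome sequences and legal single-transcript gene models.

    Genes are placed non-overlapping, alternating strands, spread across
    chromosomes round-robin. Each CDS starts with ATG, ends with a stop, has
    length divisible by 3 and no internal stop codon on its coding strand.
    The first ``n_target_genes`` placed genes are flagged as members of the
    target family registry and labelled with cycling enzyme-family names.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    chrom_names = [f"chr{i + 1:02d}" for i in range(cfg.n_chroms)]
    chrom_arrays = {c: _random_seq(rng, cfg.genome_length_per_chrom, cfg.gc_content) for c in chrom_names}

    per_chrom = [cfg.n_genes // cfg.n_chroms + (1 if i < cfg.n_genes % cfg.n_chroms else 0) for i in range(cfg.n_chroms)]
    genes: list[GeneModel] = []
    gi = 0
    for ci, chrom in enumerate(chrom_names):
        n_here = per_chrom[ci]
        if n_here == 0:
            continue
        cursor = 1 + int(rng.integers(200, 1000))
        for _ in range(n_here):
            seq, exon_lens, intron_lens = _build_gene_sequence(rng, cfg)
            glen = len(seq)
            gap = int(rng.integers(300, 1500))
            start = cursor + gap  # 1-based
            if start + glen - 1 > cfg.genome_length_per_chrom - 200:
                raise GenePlacementError(
                    f"cannot place gene {gi + 1} on {chrom}: needs {glen} bp at {start} "
                    f"but chromosome length is {cfg.genome_length_per_chrom}; "
                    "increase genome_length_per_chrom or reduce n_genes/gene size"
                )
            strand = "+" if gi % 2 == 0 else "-"
            placed = seq if strand == "+" else revcomp(seq)
            chrom_arrays[chrom][start - 1 : start - 1 + glen] = list(placed)

            # exon coordinates in sense orientation, then mirror for -
            exons_sense: list[tuple[int, int]] = []
            off = 0
            for i, elen in enumerate(exon_lens):
                exons_sense.append((off, off + elen - 1))
                off += elen
                if i < len(intron_lens):
                    off += intron_lens[i]
            if strand == "+":
                exons = [(start + s, start + e) for s, e in exons_sense]
            else:
                exons = sorted((start + glen - 1 - e, start + glen - 1 - s) for s, e in exons_sense)

            # GFF3 phase per CDS segment, walked in transcription order
            order = exons if strand == "+" else exons[::-1]
            cds_by_interval = {}
            done = 0
            for s, e in order:
                cds_by_interval[(s, e)] = (3 - done % 3) % 3
                done += e - s + 1
            cds = [(s, e, cds_by_interval[(s, e)]) for s, e in exons]

            gid = f"gene{gi + 1:04d}"
            is_target = gi < cfg.n_target_genes
            genes.append(
                GeneModel(
                    gene_id=gid,
                    transcript_id=f"{gid}.t1",
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    cds=cds,
                    is_target=is_target,
                    family_label=FAMILY_LABELS[gi % len(FAMILY_LABELS)] if is_target else "",
                )
            )
            cursor = start + glen - 1
            gi += 1
    genome = {c: "".join(arr) for c, arr in chrom_arrays.items()}
    return genome, genes


def simulate_truth(
    genome: Mapping[str, str], cfg: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw the shared truth set of segregating bi-allelic SNPs.

    Sites are Bernoulli(snp_density) per bp; alt is a uniform non-reference
    base; the population alternate-allele frequency is Beta(maf_alpha,
    maf_beta), clipped away from fixation.
    """
    rows = []
    base_arr = np.array(list("ACGT"))
    for chrom in genome:
        seq = genome[chrom]
        mask = rng.random(len(seq)) < cfg.snp_density
        positions = np.flatnonzero(mask) + 1  # 1-based
        for pos in positions:
            ref = seq[pos - 1]
            if ref not in BASES:
                continue
            alt = str(rng.choice(base_arr[base_arr != ref]))
            af = float(np.clip(rng.beta(cfg.maf_alpha, cfg.maf_beta), 0.02, 0.98))
            rows.append((chrom, int(pos), ref, alt, af))
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def _hwe_genotypes(rng: np.random.Generator, p_alt: float, n: int) -> np.ndarray:
    """n diploid alt-allele counts under Hardy-Weinberg at frequency p_alt."""
    return (rng.random(n) < p_alt).astype(np.int8) + (rng.random(n) < p_alt).astype(np.int8)


def _carrier_genotype(rng: np.random.Generator, p_alt: float) -> int:
    """One genotype conditioned on carrying >=1 alt allele (a called sample)."""
    q = p_alt
    het, hom = 2 * q * (1 - q), q * q
    return 1 if rng.random() < het / (het + hom) else 2


def _gt_string(code: int, phased: bool, rng: np.random.Generator) -> str:
    if code == 1 and phased:
        return "0|1" if rng.random() < 0.5 else "1|0"
    if phased:
        return {0: "0|0", 2: "1|1"}[code]
    return {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}[code]


def simulate_callsets(
    genome: Mapping[str, str],
    truth: pd.DataFrame,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, Callset]:
    """Emulate the three callsets from the shared truth table.

    Each truth SNP enters each callset independently with the callset's
    detection probability. Skim-panel genotypes are Hardy-Weinberg draws at
    the truth allele frequency, then masked missing at ``missing_rate``;
    single-sample genotypes are drawn conditioned on carrying the alternate
    allele (a variant that is absent from the sample would not be called),
    and the deep reference callset is phased. False positives are Poisson at
    ``fp_rate`` per bp per callset, placed at positions private to one
    callset and absent from the truth set, so the >=2-callset rule removes
    them by construction.
    """
    det = dict(zip(DATASET_IDS, cfg.detect_prob))
    truth_pos = {(r.chrom, r.pos) for r in truth.itertuples()}

    panel_samples = [f"P{i + 1:03d}" for i in range(cfg.panel_size)]
    callsets = {
        DEEP_REF: Callset(DEEP_REF, ["KA01_like"], {}),
        SHOTGUN: Callset(SHOTGUN, ["shotgun_acc"], {}),
        SKIM_PANEL: Callset(SKIM_PANEL, panel_samples, {}),
    }

    for r in truth.itertuples():
        key = VariantKey(r.chrom, r.pos, r.ref, r.alt)
        af = r.truth_af
        detected = {ds: rng.random() < det[ds] for ds in DATASET_IDS}
        if detected[DEEP_REF]:
            code = _carrier_genotype(rng, af)
            callsets[DEEP_REF].records[key] = (_gt_string(code, True, rng),)
        if detected[SHOTGUN]:
            code = _carrier_genotype(rng, af)
            callsets[SHOTGUN].records[key] = (_gt_string(code, False, rng),)
        if detected[SKIM_PANEL]:
            codes = _hwe_genotypes(rng, af, cfg.panel_size)
            miss = rng.random(cfg.panel_size) < cfg.missing_rate
            codes = np.where(miss, -1, codes)
            callsets[SKIM_PANEL].records[key] = tuple(
                _gt_string(int(c), False, rng) for c in codes
            )

    # callset-private false positives at non-truth positions
    total_len = sum(len(s) for s in genome.values())
    chroms = list(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    used_fp: set[tuple[str, int]] = set()
    base_arr = np.array(list("ACGT"))
    for ds in DATASET_IDS:
        n_fp = int(rng.poisson(cfg.fp_rate * total_len))
        placed = 0
        while placed < n_fp:
            chrom = str(rng.choice(chroms, p=lengths / lengths.sum()))
            pos = int(rng.integers(1, len(genome[chrom]) + 1))
            if (chrom, pos) in truth_pos or (chrom, pos) in used_fp:
                continue
            ref = genome[chrom][pos - 1]
            if ref not in BASES:
                continue
            used_fp.add((chrom, pos))
            alt = str(rng.choice(base_arr[base_arr != ref]))
            key = VariantKey(chrom, pos, ref, alt)
            cs = callsets[ds]
            if ds == SKIM_PANEL:
                codes = np.zeros(cfg.panel_size, dtype=int)
                codes[rng.integers(0, cfg.panel_size)] = 1  # a spurious singleton het
                miss = rng.random(cfg.panel_size) < cfg.missing_rate
                codes = np.where(miss, -1, codes)
                cs.records[key] = tuple(_gt_string(int(c), False, rng) for c in codes)
            else:
                cs.records[key] = (_gt_string(1, ds == DEEP_REF, rng),)
            placed += 1

    for cs in callsets.values():
        cs.records = dict(sorted(cs.records.items()))
    return callsets


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_targets(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write the target-gene registry TSV (target-flagged genes only)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tfamily\tchrom\tstart\tend\tstrand\n")
        for g in genes:
            if g.is_target:
                fh.write(f"{g.gene_id}\t{g.family_label}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\n")


def simulate_all(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the full simulation and write every artifact to ``outdir``.

    Returns a name -> path map: genome FASTA, gene-model GFF3, target TSV,
    truth TSV and the three callset VCFs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    genome, genes = simulate_genome(cfg, rng)
    truth = simulate_truth(genome, cfg, rng)
    callsets = simulate_callsets(genome, truth, cfg, rng)

    paths = {
        "fasta": outdir / "genome.fa",
        "gff3": outdir / "genes.gff3",
        "targets": outdir / "targets.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(genome, paths["fasta"])
    write_gff3(genes, paths["gff3"])
    write_targets(genes, paths["targets"])
    write_truth(truth, paths["truth"])
    contigs = {c: len(s) for c, s in genome.items()}
    for ds, cs in callsets.items():
        p = outdir / f"{ds}.vcf"
        write_vcf(cs, p, contigs=contigs)
        paths[ds] = p
    return paths
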