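"""Core variant / gene-model data structures and FASTA, GFF3, VCF, BED, TSV I/O.

Coordinate conventions
----------------------
VCF and GFF3 positions are 1-based inclusive throughout the in-memory model;
BED output is converted to 0-based half-open at write time. Only bi-allelic
SNP records survive VCF ingest; multi-allelic sites, indels and symbolic
alleles are dropped and counted. Only the GT field of a VCF is consumed —
depth and quality recalibration are assumed to have happened upstream, in
the per-dataset calling pipelines that produced the input VCFs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from cyvcf2 import VCF

log = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

#: genotype codes: number of alternate alleles, or -1 for missing
GT_MISSING = -1
GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class VariantKey:
    """A bi-allelic SNP site: (chrom, pos, ref, alt), ordered lexicographically.

    The dataclass field order gives the total ordering used everywhere ties
    matter (sorted output, deterministic tie-breaks in panel selection).
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"non-ACGT allele in {self.chrom}:{self.pos} {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive, got {self.pos}")


def genotype_code(gt: str) -> int:
    """Collapse a diploid GT string to an alt-allele count.

    ``0/1``, ``1|0`` -> 1; ``1/1`` -> 2; ``./.`` and half-calls (``./1``) -> -1.
    """
    alleles = gt.replace("|", "/").split("/")
    if len(alleles) != 2 or "." in alleles:
        return GT_MISSING
    try:
        a, b = int(alleles[0]), int(alleles[1])
    except ValueError:
        return GT_MISSING
    if a not in (0, 1) or b not in (0, 1):
        return GT_MISSING
    return a + b


def genotype_codes(gts: Sequence[str]) -> list[int]:
    return [genotype_code(g) for g in gts]


@dataclass
class Callset:
    """One variant callset: an id, ordered sample names, and per-site genotypes.

    ``records`` maps each :class:`VariantKey` to a genotype-string tuple of
    length ``len(sample_ids)`` (raw GT spellings, phase-preserving).
    """

    dataset_id: str
    sample_ids: list[str]
    records: dict[VariantKey, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, gts in self.records.items():
            if len(gts) != len(self.sample_ids):
                raise ValueError(
                    f"{self.dataset_id}: genotype vector length {len(gts)} != "
                    f"{len(self.sample_ids)} samples at {key}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def keys(self) -> set[VariantKey]:
        return set(self.records)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class GeneModel:
    """A single-transcript protein-coding gene model.

    Exons and CDS segments are stored ascending by genomic coordinate
    (1-based inclusive) regardless of strand; transcription order is derived
    from ``strand``. ``cds`` carries the GFF3 phase per segment. ``cds_valid``
    is cleared when the summed CDS length is not divisible by 3; such genes
    are skipped by effect classification but still usable as panel targets.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int, int]]
    is_target: bool = False
    family_label: str = ""
    cds_valid: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon {s}-{e} inverted")
            if s <= prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = e
        for s, e, _ in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise ValueError(f"{self.gene_id}: CDS {s}-{e} outside exons")
        if self.cds_length % 3 != 0:
            self.cds_valid = False

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a genome FASTA into a plain {name: uppercase sequence} dict.

    Toy genomes here are small enough to hold in memory; this keeps genome
    access uniform between simulated dicts and files on disk.
    """
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=False, build_index=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path, dataset_id: str) -> Callset:
    """Read a VCF (v4.2, GT FORMAT) into a :class:`Callset`.

    Multi-allelic records, indels and symbolic alleles are dropped; the drop
    count is logged. Raises if the file carries no genotype columns.
    """
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no sample/GT columns")
    records: dict[VariantKey, tuple[str, ...]] = {}
    n_dropped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_dropped += 1
            continue
        if v.REF not in BASES or v.ALT[0] not in BASES:
            n_dropped += 1
            continue
        key = VariantKey(v.CHROM, v.POS, v.REF, v.ALT[0])
        gts = []
        for a, b, phased in ((g[0], g[1], g[2]) for g in v.genotypes):
            sep = "|" if phased else "/"
            sa = "." if a < 0 else str(a)
            sb = "." if b < 0 else str(b)
            gts.append(f"{sa}{sep}{sb}")
        if key in records:
            n_dropped += 1  # duplicate site: keep first occurrence
            continue
        records[key] = tuple(gts)
    vcf.close()
    if n_dropped:
        log.info("read_vcf(%s): dropped %d non-bi-allelic-SNP/duplicate records", path, n_dropped)
    cs = Callset(dataset_id=dataset_id, sample_ids=samples, records=records)
    return cs


def write_vcf(
    callset: Callset,
    path: str | Path,
    contigs: Mapping[str, int] | None = None,
    info_fields: Mapping[VariantKey, str] | None = None,
    extra_header: Iterable[str] = (),
) -> None:
    """Write a Callset as a minimal VCF v4.2 with a GT FORMAT field."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=panelforge\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        for line in extra_header:
            fh.write(line.rstrip("\n") + "\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(callset.sample_ids) + "\n")
        for key in sorted(callset.records):
            gts = callset.records[key]
            info = info_fields.get(key, ".") if info_fields else "."
            fh.write(
                f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t.\tPASS\t{info}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# GFF3


def _gff_attrs(field9: str) -> dict[str, str]:
    out = {}
    for part in field9.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse single-transcript gene models from a GFF3 file.

    Recognised feature types: gene, mRNA, exon, CDS. Gene-level attributes
    ``target`` ("1"/"0") and ``family`` populate the target-registry fields.
    A gene whose CDS length is not divisible by 3 is kept but flagged
    ``cds_valid=False`` (with a warning) so that effect classification skips
    it while panel selection does not.
    """
    genes: dict[str, dict] = {}
    mrna_to_gene: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(f)}")
            chrom, _, ftype, start, end, _, strand, phase, attrs = f
            start, end = int(start), int(end)
            a = _gff_attrs(attrs)
            if ftype == "gene":
                gid = a["ID"]
                genes[gid] = {
                    "gene_id": gid,
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [],
                    "cds": [],
                    "transcript_id": gid + ".t1",
                    "is_target": a.get("target", "0") == "1",
                    "family_label": a.get("family", ""),
                }
            elif ftype == "mRNA":
                parent = a["Parent"]
                mrna_to_gene[a["ID"]] = parent
                if parent in genes:
                    genes[parent]["transcript_id"] = a["ID"]
            elif ftype == "exon":
                gid = mrna_to_gene.get(a["Parent"], a["Parent"])
                genes[gid]["exons"].append((start, end))
            elif ftype == "CDS":
                gid = mrna_to_gene.get(a["Parent"], a["Parent"])
                ph = 0 if phase == "." else int(phase)
                genes[gid]["cds"].append((start, end, ph))
    models = []
    for g in genes.values():
        if not g["exons"] and g["cds"]:
            g["exons"] = [(s, e) for s, e, _ in g["cds"]]
        gm = GeneModel(**g)
        if not gm.cds_valid:
            log.warning(
                "read_gff3(%s): gene %s CDS length %d not divisible by 3; "
                "excluded from effect analysis",
                path,
                gm.gene_id,
                gm.cds_length,
            )
        models.append(gm)
    models.sort(key=lambda m: (m.chrom, m.start, m.gene_id))
    return models


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            tgt = "1" if g.is_target else "0"
            fam = f";family={g.family_label}" if g.family_label else ""
            fh.write(
                f"{g.chrom}\tpanelforge\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};target={tgt}{fam}\n"
            )
            fh.write(
                f"{g.chrom}\tpanelforge\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.transcript_id};Parent={g.gene_id}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tpanelforge\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"Parent={g.transcript_id}\n"
                )
            for s, e, ph in g.cds:
                fh.write(
                    f"{g.chrom}\tpanelforge\tCDS\t{s}\t{e}\t.\t{g.strand}\t{ph}\t"
                    f"Parent={g.transcript_id}\n"
                )


# ---------------------------------------------------------------------------
# Coordinate conversions (VCF/GFF3 1-based inclusive <-> BED 0-based half-open)


def to_bed(start1: int, end1: int) -> tuple[int, int]:
    return start1 - 1, end1


def from_bed(start0: int, end0: int) -> tuple[int, int]:
    return start0 + 1, end0


# ---------------------------------------------------------------------------
# Panel writing (duck-typed over panels.PanelSelection)

PANEL_TSV_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "maf",
    "states",
    "impact",
    "group",
    "rank",
]


def write_panel(selection, path: str | Path, fmt: str = "tsv") -> None:
    """Write a panel selection as TSV (metadata columns), BED, or VCF sites.

    The TSV ``group`` column holds the bin index (genome-wide panel) or the
    target gene id (gene panel).
    """
    fmt = fmt.lower()
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(PANEL_TSV_COLUMNS) + "\n")
            for e in selection.entries:
                states = ",".join(sorted(e.states)) if e.states else "."
                maf = "." if e.maf is None else f"{e.maf:.6g}"
                fh.write(
                    f"{e.key.chrom}\t{e.key.pos}\t{e.key.ref}\t{e.key.alt}\t"
                    f"{maf}\t{states}\t{e.impact or '.'}\t{e.group}\t{e.rank}\n"
                )
    elif fmt == "bed":
        with open(path, "w") as fh:
            for e in selection.entries:
                s0, e0 = to_bed(e.key.pos, e.key.pos)
                name = f"{e.key.ref}>{e.key.alt}|{e.group}"
                fh.write(f"{e.key.chrom}\t{s0}\t{e0}\t{name}\n")
    elif fmt == "vcf":
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=panelforge-panel\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for e in selection.entries:
                maf = "." if e.maf is None else f"{e.maf:.6g}"
                fh.write(
                    f"{e.key.chrom}\t{e.key.pos}\t.\t{e.key.ref}\t{e.key.alt}\t.\tPASS\t"
                    f"MAF={maf};GROUP={e.group}\n"
                )
    else:
        raise ValueError(f"unknown panel format: {fmt}")
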