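"""High-confidence SNP database: multi-callset intersection plus panel statistics.

A SNP is "high-confidence" when the identical (chrom, pos, ref, alt) site is
called in at least ``min_support`` of the input callsets (default 2 of 3).
Matching is strict on alleles: two callsets reporting different substitutions
at the same position do not support each other. Minor allele frequency and
the set of observed genotypic states are computed from the skim resequencing
panel only — the two deep single-sample callsets contribute presence, not
population statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .vario import (
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    GT_MISSING,
    Callset,
    VariantKey,
    genotype_codes,
)

HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
ALL_STATES = frozenset({HOM_REF, HET, HOM_ALT})

_STATE_OF_CODE = {GT_HOM_REF: HOM_REF, GT_HET: HET, GT_HOM_ALT: HOM_ALT}


@dataclass
class HighConfidenceSnp:
    """One consensus SNP with its supporting callsets and panel statistics.

    ``maf`` is None when no panel genotype was called (or the SNP is absent
    from the panel callset entirely); such SNPs are ineligible for panels.
    ``flank_clear`` is filled in later by the panel stage.
    """

    key: VariantKey
    support: frozenset[str]
    maf: float | None = None
    n_called: int = 0
    states_observed: frozenset[str] = frozenset()
    flank_clear: bool | None = None

    @property
    def maf_defined(self) -> bool:
        return self.maf is not None


def compute_maf(genotypes: Sequence[str] | Sequence[int]) -> tuple[float | None, int]:
    """Fold the alt-allele frequency of a genotype vector to a MAF <= 0.5.

    Missing genotypes (and half-calls) are excluded from numerator and
    denominator. Returns (maf, n_called); maf is None when every genotype is
    missing.
    """
    codes = _as_codes(genotypes)
    called = [c for c in codes if c != GT_MISSING]
    n = len(called)
    if n == 0:
        return None, 0
    p = sum(called) / (2 * n)
    return min(p, 1.0 - p), n


def genotype_states(genotypes: Sequence[str] | Sequence[int]) -> frozenset[str]:
    """The set of distinct non-missing genotype classes observed."""
    codes = _as_codes(genotypes)
    return frozenset(_STATE_OF_CODE[c] for c in codes if c != GT_MISSING)


def _as_codes(genotypes: Sequence[str] | Sequence[int]) -> list[int]:
    if genotypes and isinstance(genotypes[0], str):
        return genotype_codes(genotypes)  # type: ignore[arg-type]
    return list(genotypes)  # type: ignore[arg-type]


def intersect_callsets(
    callsets: Sequence[Callset],
    min_support: int = 2,
    panel_id: str = "skim_panel",
) -> list[HighConfidenceSnp]:
    """Intersect callsets into the high-confidence SNP list.

    Output contains exactly the keys present (identical chrom/pos/ref/alt)
    in >= ``min_support`` callsets, sorted by key. MAF, called-genotype count
    and observed states are attached from the callset whose dataset_id is
    ``panel_id`` when that callset contains the SNP.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if len(callsets) < min_support:
        raise ValueError(f"need >= {min_support} callsets, got {len(callsets)}")
    ids = [cs.dataset_id for cs in callsets]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate dataset_id among {ids}")

    support: dict[VariantKey, set[str]] = {}
    for cs in callsets:
        for key in cs.records:
            support.setdefault(key, set()).add(cs.dataset_id)

    panel = next((cs for cs in callsets if cs.dataset_id == panel_id), None)
    out: list[HighConfidenceSnp] = []
    for key in sorted(support):
        sup = support[key]
        if len(sup) < min_support:
            continue
        maf: float | None = None
        n_called = 0
        states: frozenset[str] = frozenset()
        if panel is not None and key in panel.records:
            gts = panel.records[key]
            maf, n_called = compute_maf(gts)
            states = genotype_states(gts)
        out.append(
            HighConfidenceSnp(
                key=key,
                support=frozenset(sup),
                maf=maf,
                n_called=n_called,
                states_observed=states,
            )
        )
    return out


def write_hc_vcf(snps: Iterable[HighConfidenceSnp], path, contigs=None) -> None:
    """Write the high-confidence set as a sites VCF with SUPPORT/MAF/STATES INFO tags."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=panelforge-consensus\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=SUPPORT,Number=.,Type=String,Description="Supporting callsets">\n')
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="Panel minor allele frequency">\n')
        fh.write('##INFO=<ID=STATES,Number=.,Type=String,Description="Observed genotypic states">\n')
        fh.write('##INFO=<ID=NCALLED,Number=1,Type=Integer,Description="Non-missing panel genotypes">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(snps, key=lambda s: s.key):
            maf = "." if s.maf is None else f"{s.maf:.6g}"
            states = ",".join(sorted(s.states_observed)) or "."
            sup = ",".join(sorted(s.support))
            fh.write(
                f"{s.key.chrom}\t{s.key.pos}\t.\t{s.key.ref}\t{s.key.alt}\t.\tPASS\t"
                f"SUPPORT={sup};MAF={maf};STATES={states};NCALLED={s.n_called}\n"
            )


def write_hc_tsv(snps: Iterable[HighConfidenceSnp], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tsupport\tmaf\tn_called\tstates\tflank_clear\n")
        for s in sorted(snps, key=lambda s: s.key):
            maf = "." if s.maf is None else f"{s.maf:.6g}"
            states = ",".join(sorted(s.states_observed)) or "."
            flank = "." if s.flank_clear is None else str(int(s.flank_clear))
            fh.write(
                f"{s.key.chrom}\t{s.key.pos}\t{s.key.ref}\t{s.key.alt}\t"
                f"{','.join(sorted(s.support))}\t{maf}\t{s.n_called}\t{states}\t{flank}\n"
            )
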