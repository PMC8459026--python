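# Methods

## Problem setting

`panelforge` rebuilds, as a reusable pipeline, the SNP-resource construction
used for semi-domesticated tree crops such as shea (*Vitellaria paradoxa*):
three heterogeneous variant callsets — a deep, phased callset from the
reference accession; a deep shotgun callset from a second accession; and a
skim-coverage (~1.8x) resequencing panel of 31 genotypes — are intersected
into a high-confidence SNP database, annotated with a lightweight
SnpEff-style effect classifier, and distilled into two ready-to-use
genotyping panels.

## Consensus model

A bi-allelic SNP is *high-confidence* when the identical
(chrom, pos, ref, alt) site is called in at least `min_support` callsets
(default 2 of 3). Matching is strict on alleles: two callsets reporting
different substitutions at one position do not corroborate each other. This
is the stricter of the two defensible readings of a "shared across at least
two datasets" rule; position-only matching would conflate distinct
substitutions.

Minor allele frequency and the observed genotypic states are computed from
the skim resequencing panel only: with one sample each, the two deep
callsets carry no population information. MAF is the folded alternate-allele
frequency `min(p, 1-p)` over non-missing genotypes (half-calls count as
missing); a SNP with zero called panel genotypes has undefined MAF and is
ineligible for panels.

## Effect classification

Each SNP is classified once per overlapping transcript (single-transcript
gene models; gene span padded by 5 kb). Decision order: splice donor (first
2 intron bases in transcription order), splice acceptor (last 2), intronic
splice region (intron bases 3–8 from either junction), CDS codon change,
exonic splice region (the 3 exon bases abutting a junction, unless the CDS
call is of higher impact than LOW), and otherwise MODIFIER (UTR, deep
intron, the 5 kb up/downstream flank, or intergenic). CDS calls rebuild the
affected codon on the coding strand (reverse complement for minus-strand
genes) and translate with the standard nuclear code: a destroyed ATG is
`start_lost` unless the new codon is an alternate initiator (CTG/TTG,
`initiator_codon_variant`); stop codons are {TAA, TAG, TGA}; otherwise
`stop_lost` / `stop_gained` / `missense` / `synonymous` by comparison of the
translated codons.

Impact is a pure function of effect type (HIGH: splice donor/acceptor,
start_lost, stop gained/lost; MODERATE: missense; LOW: initiator codon,
splice region, synonymous; MODIFIER: everything else). The splice-region
window (intron 3–8 bp, exon 1–3 bp) follows the convention of the standard
annotation tools; it is exposed in `effects.SpliceWindows`. Transcripts
whose summed CDS length is not divisible by 3 are skipped by the classifier
(with a warning) but remain usable as panel targets.

Indels, multi-nucleotide substitutions and regulatory-motif effects are out
of scope; the classifier is deliberately a small, testable subset of a full
annotation engine, checked exhaustively against a full-retranslation oracle.

## Panel selection

Both panels share three eligibility filters: **conserved flanks** (no other
known variant within 50 bp on either side — "at least 50 bp of conserved
sequence" is read strictly, so a variant exactly 50 bp away disqualifies;
the variant map is the union of *all* raw callset positions, not only
high-confidence SNPs, because assay design must clear any known variation),
**all three genotypic states** observed in the skim panel (maximizing
informativeness and transferability), and **defined MAF**.

* **Genome-wide panel** — chromosomes are tiled with contiguous 5 kb bins
  anchored at position 1 (the terminal partial bin is a legal bin); each bin
  contributes its eligible SNP of highest MAF, ties broken to the smallest
  position and then to full key order, so output is independent of input
  order.
* **Gene-targeted panel** — k = 2 SNPs per target gene, ranked by MAF
  descending, then impact severity (HIGH > MODERATE > LOW > MODIFIER), then
  position. Candidates are in-gene SNPs; only when a gene holds fewer than k
  does the window widen by ±5 kb ("tight linkage" stand-in; the source
  protocol gives no number, so it is a flag). Genes still short of k are
  reported as shortfalls rather than silently padded.

## Density and registry reports

Mean inter-SNP distance per chromosome is `floor(length / n_snps)` — the
floor convention is the one that reproduces all twelve printed values of
the shea per-chromosome table (rounding fails on one chromosome). The
genome-level mean excludes unplaced contigs, which reproduces the published
"1 SNP every 189 bp" (including them gives 191). The bundled fatty-acid
enzyme registry aggregates per-species gene-copy totals (45 in shea, 35 in
cacao, 30 *A. thaliana* queries) and counts distinct enzyme families.

## Synthetic-data generator

The simulator emulates the *shape* of the study data, not its sequences:
i.i.d. bases at 33% GC (no repeats or TEs), non-overlapping single-transcript
genes with ~225 bp exons, ~1.1 kb introns and 2–7 exons per gene (the
emulated genome's annotation statistics), a shared truth set of segregating
SNPs at density 1/189 bp with Beta(0.8, 0.8) allele frequencies (U-shaped
spectrum), and three callsets drawn from that truth.

Study-stated parameters are used verbatim: 31-sample panel, SNP density,
GC, gene architecture. Parameters the study does not state are the
simulator's own, chosen once on first-principles grounds and documented
here: per-callset detection probabilities (0.92, 0.90, 0.85 — deep callsets
detect more; the raw-to-consensus attrition in such studies implies
detection well below 1), false positives at 5e-4/bp placed private to one
callset at non-truth positions (which makes the consensus filter's purpose
testable: with perfect detection, precision is exactly 1), and skim
missingness 0.35 (at ~1.8x coverage a large minority of genotypes are
uncallable). Skim genotypes are Hardy–Weinberg draws at the truth frequency;
single-sample genotypes are drawn conditional on carrying the alternate
allele; the deep reference callset is phased (`0|1`).

Not modelled: read-level error, base quality, linkage disequilibrium,
indels, structural variation, population structure. Passing tests therefore
demonstrate the correctness of the *algorithms* under the stated sampling
model — not calling accuracy on real sequencing data, where error modes are
correlated across callsets and the ≥2-dataset rule is less surgical than it
is against private simulated false positives.

All randomness flows from a single `numpy.random.default_rng(seed)`;
identical seed and config give byte-identical files. Analysis stages are
seed-free, so re-running the pipeline on fixed inputs is byte-identical too.

## Numerical and degenerate-input choices

Ties everywhere break on the total key order (chrom, pos, ref, alt).
Percentages in the impact summary are rounded to 2 decimals and may sum to
100.00 ± 0.02. Empty inputs: an empty VCF body yields an empty callset; an
empty effect list yields an all-zero summary with percents flagged
undefined; an all-missing genotype vector yields undefined MAF. Duplicate
dataset ids and SNPs on chromosomes absent from the length table are errors.

## Problem sizes used in tests

The test and acceptance workloads are deliberately desk-scale: simulated
genomes of 0.5–0.6 Mb, a few thousand truth SNPs, 45-gene target
registries, exhaustive effect enumeration on toy genes of a few hundred
bases, and 50-replicate oracle comparisons — sizes at which the brute-force
oracles (full retranslation, O(n²) scans, naive counting) remain exact and
fast. The published resource's headline sizes (millions of SNPs from ~160 Gb
of sequencing) are functions of the real data and are reproduced only at the
level of their arithmetic (density, summary and registry tables), which the
test suite recomputes from the printed inputs.
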