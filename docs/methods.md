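# Methods

This note documents the models, conventions and numerical choices behind
`reseqlens`, and what the synthetic-data tests do and do not demonstrate
about real resequencing data.

## Scope and assumptions

The package targets resequencing of **inbred, effectively homozygous**
genomes (rice cultivars are the motivating case) against a single
reference assembly of chromosomes plus unanchored scaffolds. Three
consequences shape the design:

* variants are called as homozygous consensus differences (GT `1/1`);
  there are no genotype likelihoods, no heterozygous model, and minority
  alleles at a site are treated as noise to be removed by the call-rate
  filter;
* only **uniquely mapped** reads contribute to depth, coverage and
  calling; multi-mapped reads (MAPQ 0 plus an `XT:A:R` tag in the SAM
  dialect) are carried through IO but ignored by every statistic;
* read mapping and contig assembly are *external* steps: alignments and
  contigs are inputs. The synthetic module stands in for both with a
  perfect-mapper idealisation (below).

Coordinates are 0-based half-open internally; GFF3 and VCF are converted
at the file boundary.

## Two depth conventions

Depth for **coverage** purposes (`depth_track`) counts every
reference-consuming base (CIGAR M and D) of every unique read, with no
quality filter: a read covers a deleted span even though it carries no
base there, and an insertion consumes no reference. Depth for **allele
support** (`build_pileup`) additionally requires base quality ≥ 30.
The separation lets the same alignments express both a coverage table
(where the published arithmetic — mapped nucleotides ÷ average depth ≈
covered positions — only works if no quality filter is applied) and the
polymorphism filters (where it is).

**Average depth** divides total aligned depth by the number of positions
with depth ≥ 1, not by genome length. The bundled seven-cultivar mapping
table is arithmetically consistent only under this covered-positions
convention (≈3.3×10⁸ bp implied denominator for every cultivar), which is
asserted by a test.

## The three-filter consensus caller

At each pileup column the candidate alternative allele is the most
frequent non-reference base among quality-passing observations (ties break
to the lexicographically smaller base, deterministically). A SNP is
emitted iff

1. quality-filtered depth ≥ `min_depth` (default 5),
2. every supporting base has quality ≥ `min_base_quality` (default 30),
3. call rate = supporting bases / quality-filtered depth is **strictly**
   greater than `snp_call_rate` (default 0.90).

InDel evidence is read-level, so its call rate divides supporting reads by
*covering unique reads* (raw depth at the anchor) and must exceed
`indel_call_rate` (default 0.30). Insertions are observed at the base
before the inserted sequence, deletions at the first deleted base; emitted
records use the VCF anchor-base convention and are left-aligned
(shift-left normalisation) before output and before any truth-set
comparison. Only the majority alternative allele is evaluated per site —
appropriate for homozygous material where multi-allelic sites are
artefacts.

The strictness of the call-rate inequality matters at boundaries: 18 of 20
supporting bases is a rate of exactly 0.90 and is rejected. Under binomial
sampling at ~30× with 1% error this occasionally costs a true SNP
(observed single-sample recall can dip to ~0.97 while aggregate recall
over many seeds stays ≥ 0.99); precision is what the filter buys, and in
the synthetic tests it is exactly 1.0.

## Annotation

Region classification uses precedence CDS > UTR > intron across *all*
transcripts overlapping a position; a position inside a gene span but in
none of its segments is intron; outside every gene span is intergenic.
When several genes tie at equal precedence the lexicographically lowest
gene id wins, so results are deterministic. InDels are classified by their
leftmost affected reference base (anchor base for insertions, first
deleted base for deletions), consistent with VCF left-alignment.

For CDS SNPs the codon index is the cumulative coding-strand position
within the spliced CDS, corrected by the first segment's phase; on the
minus strand segments are walked right-to-left and reverse-complemented.
Both codons are translated with the standard genetic code; a stop codon is
an ordinary amino-acid state, so gain or loss of a stop is nonsynonymous.
If a SNP is CDS in several transcripts, the transcript with the longest
CDS carries the effect call. Summaries report per-sample percentages
averaged with an unweighted mean and sample standard deviation (ddof 1) —
the convention that reproduces the bundled study's 17.6±1.4% genic,
5.5±0.7% CDS and 3.0±0.4% nonsynonymous figures exactly from its table.

Partition identities (intergenic + genic = total; intron + UTRs + CDS =
genic; synonymous + nonsynonymous = CDS SNPs) are asserted as hard gates
before any summary table is written.

## Coverage bins and saturation

The twelve gene-coverage bins are: exactly 1.0 → "100"; half-open decile
bands [0.9,1.0) → "90≤" down to [0.1,0.2) → "10≤"; (0,0.1) → "0<"; exactly
0 → "0". These are the only edges under which twelve labels partition
[0, 1]; the boundary value 0.90 belongs to "90≤". CDS coverage uses the
union of CDS segments across transcripts at depth ≥ 1 (configurable), and
the saturation threshold is **inclusive** ≥ 0.9.

Subsampling retains an exact count of reads (or read pairs) drawn without
replacement — not Bernoulli thinning — for tight depth control. The
saturation curve uses *nested* subsamples by default: one seeded
permutation of the read set, with increasing prefixes for increasing
depth. Nesting makes the gene counts provably non-decreasing in depth,
which is the property the curve is meant to exhibit; independent
subsamples per depth are available (`nested=False`).

## Density comparison

Variant positions are histogrammed on a fixed window grid (1 Mb for real
chromosomes; scaled to 100 kb in the desk-scale synthetic runs so a
chromosome still spans multiple windows). Trailing partial windows are
kept and counted as-is. Shared high-density regions require **every**
sample strictly above the threshold in a window; adjacent qualifying
windows merge. Fold-difference flagging requires max(a,b) ≥ `min_count`
(default 50, the detection floor) and max / max(min, 1) > fold — the
pseudocount guards empty windows. "Windows below the floor" is reported
both per sample and under the any/all readings, since the underlying
question ("undetectable in any of the samples") is ambiguous; the caller
chooses.

## Seeded contig aligner

Contigs are anchored by exact 15-mer seeds against a sorted 2-bit k-mer
index of the reference (k-mers occurring more than 200 times are skipped
as repeats). Seed hits are clustered by diagonal band, clusters become
padded reference windows, and each window is resolved by a full
affine-gap Smith–Waterman alignment (match +1, mismatch −3, gap open −5,
gap extend −2, a length-L gap costing open + L·extend). Overlapping loci
keep only the best score; non-overlapping loci are reported separately, so
a repeat-derived contig yields one alignment per copy. Significance is
E = K·m·n·exp(−λS) with (λ, K) = (1.28, 0.46) precomputed for this scoring
scheme; changing the scheme requires supplying matching constants. The
kernel is verified against an independent dynamic-programming oracle
(Biopython `PairwiseAligner` with identical scoring) on pairs up to
200 bp.

Classification: exactly one chromosome locus → unique; ≥ 2 → multi; hits
only on unanchored scaffolds → unanchored; otherwise no hit. Chromosome
hits take precedence over unanchored hits. The unique fraction (aligned
contig span ÷ contig length) is binned into 20% bands; rescue candidates
need ≥ 0.8. A candidate is *newly mapped* iff its reference footprint
overlaps ≥ 1 base of a maximal zero-depth run of ≥ 100 bp (`min_run`
exposed as a flag — "many uncovered nucleotides" is inherently a
threshold choice), and a gene is *newly covered* iff its span overlaps
the intersection of a zero-depth run with such a footprint.

Read preprocessing before assembly truncates each read to its first
`trim_length` bases and keeps it only if **every** retained base has
quality strictly above 20 — the strict per-base reading, consistent with
the very low full-length pass rates that motivate trimming; a mean-quality
mode is not provided.

## Synthetic data: what it emulates, and what it does not

`generate_reference` builds i.i.d. uniform-base chromosomes with
non-overlapping gene models (CDS lengths always divisible by 3, GFF3
phases correct on both strands), exact repeat duplications placed in
intergenic gaps, and unanchored scaffolds. `plant_variants` draws
non-overlapping homozygous SNPs and 1–50 bp InDels per window from
Poisson expectations (defaults 300 SNPs/Mb with the empirical ~8:1
SNP:insertion ratio; published per-window densities span roughly 50–900
SNPs/Mb, and window overrides plant hotspots or cold windows). The truth
set satisfies an exact edit-replay invariant: applying it to the reference
reproduces the donor byte-for-byte.

`simulate_alignments` samples reads uniformly from the donor and computes
reference coordinates exactly through the truth ledger (CIGARs with M/I/D
and soft-clipped insertion overhangs). Reads falling entirely inside a
repeat copy are flagged multi-mapped; reads with more than half their
bases inside donor-only sequence, or overlapping a designated diverged
segment, join the unmapped pool. Base qualities follow a per-cycle mean
profile — by default declining linearly 38→22 along the read, which makes
the trimming pass rate rise as reads are trimmed shorter — with Gaussian
jitter (σ 3, clipped to [2, 41]); substitution errors are injected at
`base_error_rate` with no indel errors.

What passing tests therefore show: the *filters, statistics and
intersections are implemented correctly* under their stated definitions.
What they do not show: performance under real mapping ambiguity,
indel sequencing errors, GC or positional coverage bias, structural
variation beyond simple insertions, or heterozygosity — none of which the
generator models. Parameter-recovery results (100% precision/recall at
zero error; ≥ 99% aggregate recall at 1% error and 30×) are properties of
the idealised conditions, not claims about any real dataset.

A note on the recovery test conditions: they use a flat Q35 quality
profile so that the stated fold depth is also the quality-passing depth.
Under the default declining profile roughly half the bases fail the Q30
support filter, which halves the effective depth and would conflate two
different effects in one assertion; the declining profile is exercised
separately by the trimming tests.

## Problem sizes

Test and demonstration runs use genomes of 40 kb–1 Mb at 12–30×, hundreds
of genes, and 100 kb density windows — sizes chosen so the full suite and
the acceptance script each complete in minutes on one CPU while every
stage still has non-trivial structure (multiple windows per chromosome,
multi-exon genes on both strands, repeat copies, unmappable segments).
All generators and samplers take explicit seeds; identical seeds give
byte-identical outputs, which the pipeline test asserts on the whole
report bundle.

## Known limitations

* The caller evaluates only the majority alternative allele per site and
  emits no genotype likelihoods; it is not a general-purpose caller.
* E-value constants are fixed to the default scoring scheme; there is no
  Karlin–Altschul parameter estimation.
* InDels in CDS receive no frameshift sub-annotation, and an InDel
  overlapping a region boundary is classified by its leftmost affected
  base only.
* Paired-end simulation uses a fixed fragment length and reports the mate
  on the forward strand with a reversed quality profile; insert-size
  modelling is out of scope.
* The unanchored-scaffold coverage denominator is configurable
  (`chromosomes=` on the coverage functions) because published coverage
  denominators rarely state whether scaffolds are included; both readings
  are available.
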