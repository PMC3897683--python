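"""Filtered consensus SNP/InDel calling and truth-set validation.

Three filters gate every call, mirroring standard practice for homozygous
inbred resequencing:

1. depth — quality-filtered depth >= ``min_depth`` (default 5) for SNPs;
   covering-read depth for InDels;
2. base quality — only bases with Phred >= ``min_base_quality`` (default
   30) count as allele support for SNPs;
3. call rate — the fraction of covering observations supporting the
   variant allele must exceed ``snp_call_rate`` (default 0.90) for SNPs
   and ``indel_call_rate`` (default 0.30) for InDels. InDel support is
   read-level, so its denominator is covering unique reads rather than
   quality-passing bases.

Output calls are homozygous (GT 1/1) and left-aligned per VCF convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from reseqlens.formats import AlignedRead, PileupColumn, PileupCounts
from reseqlens.simulate import TruthVariantSet


@dataclass
class FilterConfig:
    min_depth: int = 5
    min_base_quality: int = 30
    snp_call_rate: float = 0.90
    indel_call_rate: float = 0.30

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        for r in (self.snp_call_rate, self.indel_call_rate):
            if not 0 < r <= 1:
                raise ValueError("call rates must be in (0, 1]")


@dataclass
class VariantCall:
    chromosome: str
    position: int  # 0-based; for InDels the anchor base (VCF convention)
    ref_allele: str
    alt_allele: str
    type: str  # 'SNP' | 'insertion' | 'deletion'
    filtered_depth: int
    call_rate: float
    passed: bool = True

    def __post_init__(self) -> None:
        if self.type == "SNP":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("SNP alleles must be single bases")
            if self.ref_allele == self.alt_allele:
                raise ValueError("SNP alt must differ from ref")
        if not 0 <= self.call_rate <= 1:
            raise ValueError("call_rate out of range")

    def key(self) -> Tuple[str, int, str, str, str]:
        return (self.chromosome, self.position, self.type, self.ref_allele, self.alt_allele)


@dataclass
class SiteStatistics:
    filtered_depth: int
    spectrum: Dict[str, int]
    alt_allele: Optional[str]
    alt_call_rate: float


def site_statistics(column: PileupColumn, ref_base: str) -> SiteStatistics:
    """Allele spectrum and candidate alt at one column.

    The candidate alt is the most frequent non-reference base among
    quality-passing observations; ties break lexicographically.
    """
    depth = column.filtered_depth
    alts = {b: n for b, n in column.base_counts.items() if b != ref_base}
    if not alts or depth == 0:
        return SiteStatistics(depth, dict(column.base_counts), None, 0.0)
    best = max(alts.items(), key=lambda kv: (kv[1], -ord(kv[0][0])))
    # max with (count, -ord) prefers higher count, then lexicographically
    # smaller base
    return SiteStatistics(depth, dict(column.base_counts), best[0], best[1] / depth)


def call_variants(
    pileup: Iterable[PileupColumn],
    reference: Dict[str, str],
    cfg: FilterConfig = FilterConfig(),
) -> Tuple[List[VariantCall], List[VariantCall]]:
    """Apply the three filters to a pileup stream; returns (passed, rejected).

    Rejected records are candidate sites (an alt allele or indel was
    observed) that failed the depth or call-rate filter — the rejected-site
    log. Sites with no variant observation produce nothing.
    """
    passed: List[VariantCall] = []
    rejected: List[VariantCall] = []
    for col in pileup:
        refseq = reference.get(col.chromosome)
        if refseq is None:
            raise KeyError(f"pileup chromosome {col.chromosome} not in reference")
        if col.position >= len(refseq):
            raise IndexError(
                f"pileup position {col.chromosome}:{col.position} outside reference"
            )
        ref_base = refseq[col.position]
        stats = site_statistics(col, ref_base)
        if stats.alt_allele is not None:
            call = VariantCall(
                chromosome=col.chromosome,
                position=col.position,
                ref_allele=ref_base,
                alt_allele=stats.alt_allele,
                type="SNP",
                filtered_depth=stats.filtered_depth,
                call_rate=stats.alt_call_rate,
            )
            if (
                stats.filtered_depth >= cfg.min_depth
                and stats.alt_call_rate > cfg.snp_call_rate
            ):
                passed.append(call)
            else:
                call.passed = False
                rejected.append(call)
        for (itype, allele), count in sorted(col.indel_observations.items()):
            depth = col.raw_depth  # covering unique reads: read-level evidence
            rate = count / depth if depth else 0.0
            if itype == "insertion":
                # pileup anchors the insertion at the base before it
                pos = col.position
                ref_allele = ref_base
                alt_allele = ref_base + allele
            else:
                # pileup anchors the deletion at the first deleted base;
                # VCF wants the base before
                pos = col.position - 1
                if pos < 0:
                    continue
                anchor = refseq[pos]
                ref_allele = anchor + allele
                alt_allele = anchor
            pos, ref_allele, alt_allele = left_align(
                refseq, pos, ref_allele, alt_allele
            )
            call = VariantCall(
                chromosome=col.chromosome,
                position=pos,
                ref_allele=ref_allele,
                alt_allele=alt_allele,
                type=itype,
                filtered_depth=depth,
                call_rate=rate,
            )
            if depth >= cfg.min_depth and rate > cfg.indel_call_rate:
                passed.append(call)
            else:
                call.passed = False
                rejected.append(call)
    return passed, rejected


def call_variants_from_alignments(
    alignments: Sequence[AlignedRead],
    reference: Dict[str, str],
    cfg: FilterConfig = FilterConfig(),
) -> Tuple[List[VariantCall], List[VariantCall]]:
    """Fast path: build the pileup and evaluate only candidate sites.

    Sites with no quality-passing non-reference base and no indel
    observation can never yield a call, so restricting evaluation to
    candidate columns is lossless; output is identical to running
    :func:`call_variants` over the full column stream.
    """
    counts = PileupCounts(alignments, reference, cfg.min_base_quality)

    def columns():
        for chrom in reference:
            for pos in counts.candidate_positions(chrom):
                yield counts.column(chrom, int(pos))

    return call_variants(columns(), reference, cfg)


def left_align(
    refseq: str, pos: int, ref: str, alt: str
) -> Tuple[int, str, str]:
    """Normalise an InDel to its leftmost equivalent representation.

    Standard VCF normalisation: trim the shared trailing base and shift
    left while the preceding reference base equals it. SNPs pass through.
    """
    if len(ref) == 1 and len(alt) == 1:
        return pos, ref, alt
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1] and ref[0] == alt[0]:
        ref, alt = ref[:-1], alt[:-1]
    while pos > 0 and ref[-1] == alt[-1]:
        prev = refseq[pos - 1]
        ref = prev + ref[:-1]
        alt = prev + alt[:-1]
        pos -= 1
    return pos, ref, alt


@dataclass
class ValidationResult:
    precision: Optional[float]  # None when no calls were made
    recall: float
    n_true_positive: int
    n_calls: int
    n_truth: int
    per_type: Dict[str, Dict[str, float]] = field(default_factory=dict)


def validate_against_truth(
    calls: Sequence[VariantCall],
    truth: TruthVariantSet,
    reference: Dict[str, str],
    include_novel: bool = False,
) -> ValidationResult:
    """Precision/recall of calls against the planted truth set.

    A call matches a truth record iff chromosome, left-aligned position,
    type and alleles all agree. Novel long insertions are excluded from
    the denominator by default: their reads are unmappable by design, so
    no reference-based caller can see them.
    """
    def norm_truth(r):
        pos, ref, alt = left_align(reference[r.chromosome], r.position, r.ref, r.alt)
        return (r.chromosome, pos, r.type, ref, alt)

    truth_keys = {
        norm_truth(r)
        for r in truth
        if include_novel or not r.novel
    }
    call_keys = set()
    for c in calls:
        pos, ref, alt = left_align(
            reference[c.chromosome], c.position, c.ref_allele, c.alt_allele
        )
        call_keys.add((c.chromosome, pos, c.type, ref, alt))
    tp = truth_keys & call_keys
    per_type: Dict[str, Dict[str, float]] = {}
    for vtype in ("SNP", "insertion", "deletion"):
        t = {k for k in truth_keys if k[2] == vtype}
        c = {k for k in call_keys if k[2] == vtype}
        per_type[vtype] = {
            "precision": len(t & c) / len(c) if c else float("nan"),
            "recall": len(t & c) / len(t) if t else float("nan"),
            "n_truth": len(t),
            "n_calls": len(c),
        }
    return ValidationResult(
        precision=len(tp) / len(call_keys) if call_keys else None,
        recall=len(tp) / len(truth_keys) if truth_keys else 0.0,
        n_true_positive=len(tp),
        n_calls=len(call_keys),
        n_truth=len(truth_keys),
        per_type=per_type,
    )


# ---------------------------------------------------------------------------
# VCF IO (v4.2, homozygous single-sample)
# ---------------------------------------------------------------------------


def write_vcf(
    calls: Sequence[VariantCall],
    chromosome_lengths: Dict[str, int],
    sample: str,
    path: str,
) -> None:
    order = {c: i for i, c in enumerate(chromosome_lengths)}
    lines = [
        "##fileformat=VCFv4.2",
        "##source=reseqlens",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Filtered depth">',
        '##INFO=<ID=CR,Number=1,Type=Float,Description="Call rate">',
        '##INFO=<ID=TYPE,Number=1,Type=String,Description="SNP/insertion/deletion">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for c, n in chromosome_lengths.items():
        lines.append(f"##contig=<ID={c},length={n}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    for call in sorted(calls, key=lambda c: (order.get(c.chromosome, 1e9), c.position)):
        info = f"DP={call.filtered_depth};CR={call.call_rate:.4f};TYPE={call.type}"
        lines.append(
            "\t".join(
                [
                    call.chromosome,
                    str(call.position + 1),
                    ".",
                    call.ref_allele,
                    call.alt_allele,
                    ".",
                    "PASS" if call.passed else "FAIL",
                    info,
                    "GT",
                    "1/1",
                ]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path: str) -> List[VariantCall]:
    import pysam

    out: List[VariantCall] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            ref = rec.ref
            alt = rec.alts[0] if rec.alts else ref
            vtype = rec.info.get("TYPE")
            if vtype is None:
                if len(ref) == 1 and len(alt) == 1:
                    vtype = "SNP"
                elif len(alt) > len(ref):
                    vtype = "insertion"
                else:
                    vtype = "deletion"
            out.append(
                VariantCall(
                    chromosome=rec.chrom,
                    position=rec.pos - 1,
                    ref_allele=ref,
                    alt_allele=alt,
                    type=vtype,
                    filtered_depth=int(rec.info.get("DP", 0)),
                    call_rate=float(rec.info.get("CR", 1.0)),
                    passed="PASS" in (rec.filter.keys() or ["PASS"]),
                )
            )
    return out


def write_rejected_log(rejected: Sequence[VariantCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#chromosome\tposition\tref\talt\ttype\tdepth\tcall_rate\n")
        for c in rejected:
            fh.write(
                f"{c.chromosome}\t{c.position}\t{c.ref_allele}\t{c.alt_allele}\t"
                f"{c.type}\t{c.filtered_depth}\t{c.call_rate:.4f}\n"
            )
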