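"""Variant annotation against gene models.

Every variant falls in exactly one region class — intergenic, intron, UTR
or CDS — with precedence CDS > UTR > intron across all transcripts
overlapping the position (a position that is CDS in any transcript is
CDS). For CDS SNPs the codon is located by cumulative coding-strand
position, spliced across CDS segments and phase-aware; minus-strand genes
are reverse-complemented before translation with the standard genetic
code. A stop codon counts as an amino-acid state, so ref->stop and
stop->ref changes are nonsynonymous.

InDels are classified by their leftmost affected reference base (the
anchor base for insertions, the first deleted base for deletions), the
VCF left-alignment convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from reseqlens.calling import VariantCall
from reseqlens.formats import GeneModel, Transcript

REGIONS = ("intergenic", "intron", "UTR", "CDS")


@dataclass
class VariantAnnotation:
    variant: VariantCall
    region: str  # one of REGIONS
    effect: str  # 'synonymous' | 'nonsynonymous' | 'not_applicable'
    gene_id: str = ""  # empty for intergenic

    def __post_init__(self) -> None:
        if self.effect != "not_applicable" and not (
            self.region == "CDS" and self.variant.type == "SNP"
        ):
            raise ValueError("effect applies only to CDS SNPs")


class GeneIndex:
    """Interval index over gene spans for point-classification queries."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = {g.gene_id: g for g in genes}
        self.trees: Dict[str, IntervalTree] = {}
        for g in genes:
            s, e = g.span
            self.trees.setdefault(g.chromosome, IntervalTree()).addi(s, e, g.gene_id)

    def overlapping(self, chromosome: str, position: int) -> List[GeneModel]:
        tree = self.trees.get(chromosome)
        if tree is None:
            return []
        return sorted(
            (self.genes[iv.data] for iv in tree.at(position)),
            key=lambda g: g.gene_id,
        )


def _point_region(t: Transcript, position: int) -> Optional[str]:
    for s, e, _ in t.cds_segments:
        if s <= position < e:
            return "CDS"
    for s, e in t.utr5_segments + t.utr3_segments:
        if s <= position < e:
            return "UTR"
    s = min(iv[0] for iv in t.exons)
    e = max(iv[1] for iv in t.exons)
    if s <= position < e:
        return "intron"
    return None


def classify_position(
    chromosome: str,
    position: int,
    index: GeneIndex,
    chromosome_length: Optional[int] = None,
) -> Tuple[str, str]:
    """Region class and gene id at a position (CDS > UTR > intron).

    When overlapping genes give equal precedence the lexicographically
    lowest gene id wins, deterministically.
    """
    if position < 0 or (chromosome_length is not None and position >= chromosome_length):
        raise IndexError(f"position {chromosome}:{position} outside chromosome")
    best: Tuple[int, str, str] = (len(REGIONS), "", "")
    rank = {"CDS": 0, "UTR": 1, "intron": 2}
    for g in index.overlapping(chromosome, position):
        for t in g.transcripts:
            r = _point_region(t, position)
            if r is not None and rank[r] < best[0]:
                best = (rank[r], r, g.gene_id)
    if best[1] == "":
        return "intergenic", ""
    return best[1], best[2]


def _spliced_cds(t: Transcript, strand: str, refseq: str) -> Tuple[str, List[int]]:
    """Coding sequence and, per genomic CDS position, its coding index."""
    segs = t.cds_segments if strand == "+" else list(reversed(t.cds_segments))
    seq_parts: List[str] = []
    for s, e, _ in segs:
        part = refseq[s:e]
        seq_parts.append(part if strand == "+" else str(Seq(part).reverse_complement()))
    phase = segs[0][2]
    return "".join(seq_parts)[phase:], [s for s, _, _ in segs]


def _coding_index(t: Transcript, strand: str, position: int) -> Optional[int]:
    """0-based index of a genomic position within the (phase-corrected)
    coding sequence, or None if outside the CDS."""
    segs = t.cds_segments if strand == "+" else list(reversed(t.cds_segments))
    cum = 0
    for s, e, _ in segs:
        if s <= position < e:
            offset = (position - s) if strand == "+" else (e - 1 - position)
            idx = cum + offset - segs[0][2]
            return idx if idx >= 0 else None
        cum += e - s
    return None


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def annotate_snp(
    snp: VariantCall,
    index: GeneIndex,
    reference: Dict[str, str],
) -> VariantAnnotation:
    """Annotate one SNP: region class plus synonymous/nonsynonymous effect.

    For a CDS SNP overlapping several transcripts' CDS, the transcript
    with the longest CDS carries the effect call.
    """
    if snp.type != "SNP":
        raise ValueError("annotate_snp expects a SNP")
    refseq = reference[snp.chromosome]
    if refseq[snp.position] != snp.ref_allele:
        raise ValueError(
            f"reference base at {snp.chromosome}:{snp.position} is "
            f"{refseq[snp.position]!r}, call says {snp.ref_allele!r}"
        )
    region, gene_id = classify_position(
        snp.chromosome, snp.position, index, len(refseq)
    )
    if region != "CDS":
        return VariantAnnotation(snp, region, "not_applicable", gene_id)

    candidates: List[Tuple[int, str, GeneModel, Transcript]] = []
    for g in index.overlapping(snp.chromosome, snp.position):
        for t in g.transcripts:
            if any(s <= snp.position < e for s, e, _ in t.cds_segments):
                candidates.append((t.cds_length(), t.transcript_id, g, t))
    candidates.sort(key=lambda x: (-x[0], x[1]))
    _, _, gene, tx = candidates[0]

    cds_seq, _ = _spliced_cds(tx, gene.strand, refseq)
    idx = _coding_index(tx, gene.strand, snp.position)
    if idx is None or idx >= len(cds_seq):
        return VariantAnnotation(snp, "CDS", "not_applicable", gene.gene_id)
    codon_start = (idx // 3) * 3
    codon = cds_seq[codon_start : codon_start + 3]
    if len(codon) < 3:
        return VariantAnnotation(snp, "CDS", "not_applicable", gene.gene_id)
    alt_base = snp.alt_allele if gene.strand == "+" else snp.alt_allele.translate(_COMPLEMENT)
    alt_codon = codon[: idx % 3] + alt_base + codon[idx % 3 + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    effect = "synonymous" if aa_ref == aa_alt else "nonsynonymous"
    return VariantAnnotation(snp, "CDS", effect, gene.gene_id)


def annotate_variant(
    variant: VariantCall,
    index: GeneIndex,
    reference: Dict[str, str],
) -> VariantAnnotation:
    """Annotate any variant; InDels get a region but no effect call."""
    if variant.type == "SNP":
        return annotate_snp(variant, index, reference)
    # leftmost affected reference base: anchor for insertions, first
    # deleted base for deletions
    pos = variant.position if variant.type == "insertion" else variant.position + 1
    pos = min(pos, len(reference[variant.chromosome]) - 1)
    region, gene_id = classify_position(
        variant.chromosome, pos, index, len(reference[variant.chromosome])
    )
    return VariantAnnotation(variant, region, "not_applicable", gene_id)


@dataclass
class AnnotationSummary:
    """Per-sample class counts plus cross-sample mean +/- sd percentages."""

    counts: pd.DataFrame  # rows: class labels; columns: samples
    percentages: pd.DataFrame  # rows: derived percentage names
    mean_sd: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    ROWS = [
        "total", "intergenic", "genic", "intron", "UTRs", "CDS",
        "synonymous", "nonsynonymous",
    ]


def count_classes(annotations: Sequence[VariantAnnotation]) -> Dict[str, int]:
    c = {row: 0 for row in AnnotationSummary.ROWS}
    for a in annotations:
        c["total"] += 1
        if a.region == "intergenic":
            c["intergenic"] += 1
        else:
            c["genic"] += 1
            key = {"intron": "intron", "UTR": "UTRs", "CDS": "CDS"}[a.region]
            c[key] += 1
            if a.effect in ("synonymous", "nonsynonymous"):
                c[a.effect] += 1
    return c


def summarize_annotation(
    per_sample: Dict[str, Sequence[VariantAnnotation]],
) -> AnnotationSummary:
    """Cross-sample summary with exact partition identities.

    Percentages (genic, CDS, nonsynonymous as % of total) are computed per
    sample and then averaged with an unweighted mean and sample standard
    deviation, the convention behind "x.x ± y.y %" statements.
    """
    counts = pd.DataFrame(
        {sample: count_classes(anns) for sample, anns in per_sample.items()}
    ).reindex(AnnotationSummary.ROWS)
    return summarize_annotation_counts(counts)


def summarize_annotation_counts(counts: pd.DataFrame) -> AnnotationSummary:
    """Summary from a class-count table (rows as AnnotationSummary.ROWS)."""
    for sample in counts.columns:
        col = counts[sample]
        if col["intergenic"] + col["genic"] != col["total"]:
            raise ValueError(f"{sample}: intergenic + genic != total")
        if col["intron"] + col["UTRs"] + col["CDS"] != col["genic"]:
            raise ValueError(f"{sample}: intron + UTRs + CDS != genic")
    pct = pd.DataFrame(
        {
            "genic_pct": 100 * counts.loc["genic"] / counts.loc["total"],
            "CDS_pct": 100 * counts.loc["CDS"] / counts.loc["total"],
            "nonsynonymous_pct": 100 * counts.loc["nonsynonymous"] / counts.loc["total"],
        }
    ).T
    mean_sd = {
        name: (
            float(np.mean(row)),
            float(np.std(row, ddof=1)) if len(row) > 1 else 0.0,
        )
        for name, row in pct.iterrows()
    }
    return AnnotationSummary(counts=counts, percentages=pct, mean_sd=mean_sd)
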