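"""Rescue of reference regions uncovered by read mapping.

Unmapped reads are 3'-trimmed and quality-filtered before assembly
(assembly itself is an external step; contigs are inputs here). Contigs
are aligned back to the reference with the seeded local aligner,
classified (unique / multi / unanchored / no hit), and the uniquely
placed, high-unique-fraction contigs are intersected with depth-0 regions
to find reference segments — and the genes on them — that reads alone
never covered.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from reseqlens.formats import DepthTrack, GeneModel
from reseqlens.seedalign import ContigAlignment

FASTQRead = Tuple[str, str, np.ndarray]

FRACTION_BINS = ("0-20", "20-40", "40-60", "60-80", "80-100")


# ---------------------------------------------------------------------------
# Read preprocessing
# ---------------------------------------------------------------------------


def trim_and_filter_reads(
    reads: Iterable[FASTQRead],
    trim_length: int,
    min_quality: int = 20,
) -> Tuple[List[FASTQRead], float]:
    """Truncate reads to their first ``trim_length`` bases and keep only
    those whose every retained base has quality strictly above
    ``min_quality``. Returns (kept reads, pass rate).

    Because per-cycle quality declines along the read, shorter trims give
    higher pass rates.
    """
    if trim_length <= 0:
        raise ValueError("trim_length must be positive")
    kept: List[FASTQRead] = []
    total = 0
    for rid, seq, qual in reads:
        total += 1
        if trim_length > len(seq):
            raise ValueError(f"{rid}: trim_length {trim_length} exceeds read length")
        q = qual[:trim_length]
        if (q > min_quality).all():
            kept.append((rid, seq[:trim_length], q))
    return kept, (len(kept) / total if total else 0.0)


# ---------------------------------------------------------------------------
# Assembly statistics
# ---------------------------------------------------------------------------


@dataclass
class AssemblyStats:
    contig_count: int
    n50: int
    longest: int
    count_gt_1kb: int
    total_bases_gt_1kb: int
    total_bases: int


def contig_stats(contigs: Dict[str, str]) -> AssemblyStats:
    """Assembly summary; N50 is the largest L such that contigs of length
    >= L hold at least half of all assembled bases. 'Longer than 1 kb'
    is strict (a 1,000 bp contig does not count)."""
    if not contigs:
        raise ValueError("empty contig set")
    lengths = sorted((len(s) for s in contigs.values()), reverse=True)
    total = sum(lengths)
    acc = 0
    n50 = lengths[-1]
    for L in lengths:
        acc += L
        if 2 * acc >= total:
            n50 = L
            break
    gt1kb = [L for L in lengths if L > 1000]
    return AssemblyStats(
        contig_count=len(lengths),
        n50=n50,
        longest=lengths[0],
        count_gt_1kb=len(gt1kb),
        total_bases_gt_1kb=sum(gt1kb),
        total_bases=total,
    )


# ---------------------------------------------------------------------------
# Contig classification
# ---------------------------------------------------------------------------


@dataclass
class ContigReport:
    contig_id: str
    classification: str  # 'unique' | 'multi' | 'unanchored' | 'no_hit'
    unique_fraction: float  # defined (non-nan) only for unique contigs
    fraction_bin: str  # 20%-band label, '' unless unique
    newly_mapped: bool = False


def classify_contigs(
    alignments: Sequence[ContigAlignment],
    contig_lengths: Dict[str, int],
    chromosome_names: Sequence[str],
    unanchored_names: Sequence[str] = (),
) -> List[ContigReport]:
    """Partition contigs by their passing alignment loci.

    Exactly one chromosome locus -> unique; two or more -> multi; hits
    only on unanchored scaffolds -> unanchored; nothing -> no_hit.
    Chromosome hits take precedence over unanchored ones. The unique
    fraction is the aligned contig span at the unique locus divided by
    contig length, binned into 20% bands.
    """
    chrom_set = set(chromosome_names)
    unanchored_set = set(unanchored_names)
    by_contig: Dict[str, List[ContigAlignment]] = defaultdict(list)
    for a in alignments:
        by_contig[a.contig_id].append(a)
    reports: List[ContigReport] = []
    for cid in contig_lengths:
        alns = by_contig.get(cid, [])
        chrom_loci = [a for a in alns if a.target in chrom_set]
        unanch_loci = [a for a in alns if a.target in unanchored_set]
        if len(chrom_loci) == 1:
            a = chrom_loci[0]
            frac = (a.contig_end - a.contig_start) / contig_lengths[cid]
            bin_idx = min(int(frac * 5), 4)
            reports.append(
                ContigReport(cid, "unique", frac, FRACTION_BINS[bin_idx])
            )
        elif len(chrom_loci) >= 2:
            reports.append(ContigReport(cid, "multi", float("nan"), ""))
        elif unanch_loci:
            reports.append(ContigReport(cid, "unanchored", float("nan"), ""))
        else:
            reports.append(ContigReport(cid, "no_hit", float("nan"), ""))
    return reports


def classification_counts(reports: Sequence[ContigReport]) -> Dict[str, int]:
    counts = {"unique": 0, "multi": 0, "unanchored": 0, "no_hit": 0}
    for r in reports:
        counts[r.classification] += 1
    counts["total"] = len(reports)
    return counts


# ---------------------------------------------------------------------------
# Depth-0 regions and newly covered genes
# ---------------------------------------------------------------------------


def depth_zero_regions(
    track: DepthTrack, min_run: int = 100
) -> List[Tuple[str, int, int]]:
    """Maximal runs of consecutive zero-depth positions, length >= min_run."""
    out: List[Tuple[str, int, int]] = []
    for chrom in track.chromosomes():
        arr = track[chrom]
        iszero = np.concatenate(([0], (arr == 0).astype(np.int8), [0]))
        d = np.diff(iszero)
        starts = np.nonzero(d == 1)[0]
        ends = np.nonzero(d == -1)[0]
        for s, e in zip(starts, ends):
            if e - s >= min_run:
                out.append((chrom, int(s), int(e)))
    return sorted(out)


def find_newly_mapped(
    reports: Sequence[ContigReport],
    alignments: Sequence[ContigAlignment],
    zero_regions: Sequence[Tuple[str, int, int]],
    gene_models: Sequence[GeneModel],
    min_unique_fraction: float = 0.8,
) -> Tuple[List[str], List[str]]:
    """Contigs covering depth-0 reference sequence, and the genes there.

    Candidates are unique contigs with unique fraction >= the threshold.
    A candidate is newly mapped iff its reference footprint overlaps at
    least one base of a depth-0 region; a gene is newly covered iff its
    span overlaps the intersection of a depth-0 region with such a
    footprint. Both lists are deduplicated and sorted.
    """
    candidate_ids = {
        r.contig_id
        for r in reports
        if r.classification == "unique" and r.unique_fraction >= min_unique_fraction
    }
    zero_by_chrom: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
    for c, s, e in zero_regions:
        zero_by_chrom[c].append((s, e))
    newly_contigs: set = set()
    covered_pieces: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
    for a in alignments:
        if a.contig_id not in candidate_ids:
            continue
        for zs, ze in zero_by_chrom.get(a.target, []):
            lo, hi = max(a.target_start, zs), min(a.target_end, ze)
            if hi > lo:
                newly_contigs.add(a.contig_id)
                covered_pieces[a.target].append((lo, hi))
    newly_genes: set = set()
    for g in gene_models:
        gs, ge = g.span
        for lo, hi in covered_pieces.get(g.chromosome, []):
            if lo < ge and gs < hi:
                newly_genes.add(g.gene_id)
                break
    return sorted(newly_contigs), sorted(newly_genes)
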