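"""Sequence/annotation/alignment containers and file IO.

Coordinates are 0-based half-open everywhere in memory; GFF3 and VCF are
converted at the file boundary (1-based inclusive per their standards).

Two depth conventions coexist deliberately:

* :func:`depth_track` counts every reference-consuming base of uniquely
  mapped reads, with no quality filter — this is the "sequencing depth"
  used for coverage percentages, CDS coverage and depth-0 regions.
* :func:`build_pileup` additionally tallies quality-filtered allele
  support (base quality >= 30 by default) — the substrate for consensus
  variant calling.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Sequence, Tuple

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Interval = Tuple[int, int]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


@dataclass
class Transcript:
    """One mRNA: exon, CDS (with GFF3 phase) and UTR segments, genomic order."""

    transcript_id: str
    exons: List[Interval]
    cds_segments: List[Tuple[int, int, int]]  # (start, end, phase)
    utr5_segments: List[Interval] = field(default_factory=list)
    utr3_segments: List[Interval] = field(default_factory=list)

    def cds_length(self) -> int:
        return sum(e - s for s, e, _ in self.cds_segments)


@dataclass
class GeneModel:
    """A gene with strand and one or more transcripts.

    Invariants (checked by :meth:`validate`): segments sorted and
    non-overlapping within a transcript; CDS length divisible by 3 after
    phase correction; CDS and UTR segments contained in exons.
    """

    gene_id: str
    chromosome: str
    strand: str  # '+' or '-'
    transcripts: List[Transcript]

    @property
    def span(self) -> Interval:
        starts = [iv[0] for t in self.transcripts for iv in t.exons]
        ends = [iv[1] for t in self.transcripts for iv in t.exons]
        return (min(starts), max(ends))

    def cds_union(self) -> List[Interval]:
        """Merged union of CDS segments across all transcripts."""
        ivs = sorted((s, e) for t in self.transcripts for s, e, _ in t.cds_segments)
        return merge_intervals(ivs)

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        for t in self.transcripts:
            for name, segs in (
                ("exon", t.exons),
                ("CDS", [(s, e) for s, e, _ in t.cds_segments]),
            ):
                for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
                    if s2 < e1:
                        raise ValueError(
                            f"{self.gene_id}/{t.transcript_id}: {name} segments "
                            "unsorted or overlapping"
                        )
            first_phase = self._first_phase(t)
            if (t.cds_length() - first_phase) % 3 != 0:
                raise ValueError(
                    f"{self.gene_id}/{t.transcript_id}: CDS length "
                    f"{t.cds_length()} not divisible by 3 after phase correction"
                )
            exon_cover = merge_intervals(t.exons)
            for s, e in ([(s, e) for s, e, _ in t.cds_segments]
                         + t.utr5_segments + t.utr3_segments):
                if not any(xs <= s and e <= xe for xs, xe in exon_cover):
                    raise ValueError(
                        f"{self.gene_id}/{t.transcript_id}: segment [{s},{e}) "
                        "outside exons"
                    )

    def _first_phase(self, t: Transcript) -> int:
        if not t.cds_segments:
            return 0
        # translation starts at the leftmost segment on '+', rightmost on '-'
        seg = t.cds_segments[0] if self.strand == "+" else t.cds_segments[-1]
        return seg[2]


def merge_intervals(intervals: Sequence[Interval]) -> List[Interval]:
    """Union of 0-based half-open intervals, sorted and merged."""
    out: List[Interval] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


# ---------------------------------------------------------------------------
# Reads, pileups, depth
# ---------------------------------------------------------------------------


@dataclass
class AlignedRead:
    """A mapped read (SAM subset). Qualities are Phred values, not ASCII."""

    read_id: str
    chromosome: str
    start: int  # 0-based leftmost reference position
    cigar: str
    sequence: str
    base_qualities: np.ndarray  # uint8 Phred, len == len(sequence)
    uniqueness: str = "unique"  # 'unique' | 'multiple'
    is_reverse: bool = False

    def __post_init__(self) -> None:
        if len(self.base_qualities) != len(self.sequence):
            raise ValueError(f"{self.read_id}: quality/sequence length mismatch")
        if cigar_query_length(self.cigar) != len(self.sequence):
            raise ValueError(
                f"{self.read_id}: CIGAR {self.cigar} inconsistent with "
                f"sequence length {len(self.sequence)}"
            )

    @property
    def reference_length(self) -> int:
        return cigar_reference_length(self.cigar)

    @property
    def end(self) -> int:
        return self.start + self.reference_length


def parse_cigar(cigar: str) -> List[Tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    return ops


def cigar_reference_length(cigar: str) -> int:
    return sum(n for n, op in parse_cigar(cigar) if op in "MDN=X")


def cigar_query_length(cigar: str) -> int:
    return sum(n for n, op in parse_cigar(cigar) if op in "MIS=X")


@dataclass
class PileupColumn:
    """Per-position tallies from uniquely mapped reads.

    ``raw_depth`` counts covering read bases (deleted spans included);
    ``base_counts`` and ``filtered_depth`` count only aligned bases with
    quality >= the pileup's threshold. Insertions are anchored at the base
    before the inserted sequence, deletions at the first deleted base.
    """

    chromosome: str
    position: int
    raw_depth: int
    filtered_depth: int
    base_counts: Dict[str, int]
    indel_observations: Dict[Tuple[str, str], int] = field(default_factory=dict)


class DepthTrack:
    """Per-base depth from uniquely mapped reads, one array per chromosome."""

    def __init__(self, data: Dict[str, np.ndarray]):
        self.data = {name: np.asarray(arr, dtype=np.int64) for name, arr in data.items()}

    def __getitem__(self, chromosome: str) -> np.ndarray:
        return self.data[chromosome]

    def chromosomes(self) -> List[str]:
        return list(self.data)

    def total_length(self, chromosomes: Sequence[str] | None = None) -> int:
        names = chromosomes if chromosomes is not None else self.data
        return sum(len(self.data[c]) for c in names)

    def total_depth(self, chromosomes: Sequence[str] | None = None) -> int:
        names = chromosomes if chromosomes is not None else self.data
        return int(sum(self.data[c].sum() for c in names))


def _check_sorted(alignments: Sequence[AlignedRead]) -> None:
    seen: Dict[str, int] = {}
    prev_chrom = None
    for r in alignments:
        if r.chromosome != prev_chrom:
            if r.chromosome in seen:
                raise ValueError("alignments not grouped by chromosome")
            seen[r.chromosome] = r.start
            prev_chrom = r.chromosome
        elif r.start < seen[r.chromosome]:
            raise ValueError("alignments not sorted by position")
        else:
            seen[r.chromosome] = r.start


def depth_track(
    alignments: Sequence[AlignedRead],
    chromosome_lengths: Dict[str, int],
) -> DepthTrack:
    """Depth from uniquely mapped reads; no base-quality filter.

    A read contributes 1 to every reference position its alignment span
    consumes (M and D CIGAR ops); insertions consume no reference.
    """
    _check_sorted(alignments)
    diffs = {c: np.zeros(n + 1, dtype=np.int64) for c, n in chromosome_lengths.items()}
    for r in alignments:
        if r.uniqueness != "unique":
            continue
        d = diffs[r.chromosome]
        d[r.start] += 1
        d[r.end] -= 1
    return DepthTrack({c: np.cumsum(d[:-1]) for c, d in diffs.items()})


class PileupCounts:
    """Vectorised per-chromosome tally arrays backing :func:`build_pileup`."""

    BASES = "ACGT"

    def __init__(
        self,
        alignments: Sequence[AlignedRead],
        reference: Dict[str, str],
        min_base_quality: int = 30,
    ):
        _check_sorted(alignments)
        self.min_base_quality = min_base_quality
        self.reference = reference
        lengths = {c: len(s) for c, s in reference.items()}
        self.raw: Dict[str, np.ndarray] = {}
        self.counts: Dict[str, np.ndarray] = {}  # (4, L) quality-filtered
        self.insertions: Dict[str, Dict[int, Counter]] = {c: {} for c in reference}
        self.deletions: Dict[str, Dict[int, Counter]] = {c: {} for c in reference}
        diffs = {c: np.zeros(n + 1, dtype=np.int64) for c, n in lengths.items()}
        for c, n in lengths.items():
            self.counts[c] = np.zeros((4, n), dtype=np.int32)

        simple: Dict[Tuple[str, int], List[AlignedRead]] = {}
        for r in alignments:
            if r.uniqueness != "unique":
                continue
            if r.chromosome not in lengths:
                raise KeyError(f"read {r.read_id}: unknown chromosome {r.chromosome}")
            if r.cigar == f"{len(r.sequence)}M":
                simple.setdefault((r.chromosome, len(r.sequence)), []).append(r)
            else:
                self._add_complex(r, diffs[r.chromosome])
        for (chrom, rlen), group in simple.items():
            self._add_simple_batch(chrom, rlen, group, diffs[chrom])
        self.raw = {c: np.cumsum(d[:-1]) for c, d in diffs.items()}

    def _add_simple_batch(
        self, chrom: str, rlen: int, group: List[AlignedRead], diff: np.ndarray
    ) -> None:
        starts = np.fromiter((r.start for r in group), dtype=np.int64, count=len(group))
        np.add.at(diff, starts, 1)
        np.add.at(diff, starts + rlen, -1)
        seqs = np.frombuffer(
            "".join(r.sequence for r in group).encode("ascii"), dtype=np.uint8
        ).reshape(len(group), rlen)
        quals = np.vstack([r.base_qualities for r in group])
        positions = starts[:, None] + np.arange(rlen)
        ok = quals >= self.min_base_quality
        n = self.counts[chrom].shape[1]
        for i, b in enumerate(self.BASES):
            sel = ok & (seqs == ord(b))
            if sel.any():
                self.counts[chrom][i] += np.bincount(
                    positions[sel], minlength=n
                ).astype(np.int32)

    def _add_complex(self, r: AlignedRead, diff: np.ndarray) -> None:
        chrom = r.chromosome
        refseq = self.reference[chrom]
        counts = self.counts[chrom]
        refpos, qpos = r.start, 0
        for n, op in parse_cigar(r.cigar):
            if op in "M=X":
                seg = np.frombuffer(
                    r.sequence[qpos : qpos + n].encode("ascii"), dtype=np.uint8
                )
                quals = r.base_qualities[qpos : qpos + n]
                ok = quals >= self.min_base_quality
                pos = np.arange(refpos, refpos + n)
                for i, b in enumerate(self.BASES):
                    sel = ok & (seg == ord(b))
                    if sel.any():
                        np.add.at(counts[i], pos[sel], 1)
                refpos += n
                qpos += n
            elif op == "I":
                allele = r.sequence[qpos : qpos + n]
                anchor = refpos - 1
                if anchor >= r.start:
                    site = self.insertions[chrom].setdefault(anchor, Counter())
                    site[allele] += 1
                qpos += n
            elif op in "DN":
                allele = refseq[refpos : refpos + n]
                site = self.deletions[chrom].setdefault(refpos, Counter())
                site[allele] += 1
                refpos += n
            elif op == "S":
                qpos += n
            elif op in "HP":
                pass
        diff[r.start] += 1
        diff[refpos] -= 1

    def column(self, chrom: str, position: int) -> PileupColumn:
        counts = self.counts[chrom][:, position]
        base_counts = {
            b: int(counts[i]) for i, b in enumerate(self.BASES) if counts[i]
        }
        indels: Dict[Tuple[str, str], int] = {}
        for allele, n in self.insertions[chrom].get(position, {}).items():
            indels[("insertion", allele)] = n
        for allele, n in self.deletions[chrom].get(position, {}).items():
            indels[("deletion", allele)] = n
        return PileupColumn(
            chromosome=chrom,
            position=position,
            raw_depth=int(self.raw[chrom][position]),
            filtered_depth=int(counts.sum()),
            base_counts=base_counts,
            indel_observations=indels,
        )

    def covered_positions(self, chrom: str) -> np.ndarray:
        return np.nonzero(self.raw[chrom])[0]

    def candidate_positions(self, chrom: str) -> np.ndarray:
        """Positions where any quality-passing non-reference base or any
        indel was observed — the only sites a consensus caller can emit."""
        refarr = np.frombuffer(self.reference[chrom].encode("ascii"), dtype=np.uint8)
        counts = self.counts[chrom]
        nonref = np.zeros(len(refarr), dtype=bool)
        for i, b in enumerate(self.BASES):
            nonref |= (counts[i] > 0) & (refarr != ord(b))
        pos = set(np.nonzero(nonref)[0].tolist())
        pos.update(self.insertions[chrom])
        pos.update(self.deletions[chrom])
        return np.array(sorted(pos), dtype=np.int64)


def build_pileup(
    alignments: Sequence[AlignedRead],
    reference: Dict[str, str],
    min_base_quality: int = 30,
) -> Iterator[PileupColumn]:
    """Stream pileup columns for every covered position, in reference order.

    Only uniquely mapped reads contribute. Requires alignments sorted by
    (chromosome, start); raises ``ValueError`` otherwise.
    """
    counts = PileupCounts(alignments, reference, min_base_quality)
    for chrom in reference:
        for pos in counts.covered_positions(chrom):
            yield counts.column(chrom, int(pos))


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fasta(path: str) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: Dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_fastq(path: str) -> List[Tuple[str, str, np.ndarray]]:
    out = []
    for rec in SeqIO.parse(path, "fastq"):
        quals = np.array(rec.letter_annotations["phred_quality"], dtype=np.uint8)
        out.append((rec.id, str(rec.seq), quals))
    return out


def write_fastq(reads: Iterable[Tuple[str, str, np.ndarray]], path: str) -> None:
    records = []
    for rid, seq, quals in reads:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in quals]
        records.append(rec)
    SeqIO.write(records, path, "fastq")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_UTR5_TYPES = {"five_prime_UTR", "5'UTR", "five_prime_utr"}
_UTR3_TYPES = {"three_prime_UTR", "3'UTR", "three_prime_utr"}


def parse_gene_models(path: str) -> List[GeneModel]:
    """Parse a GFF3 file into validated :class:`GeneModel` objects.

    1-based inclusive GFF3 coordinates become 0-based half-open. Raises
    ``ValueError`` naming the gene if a transcript's CDS length is not
    divisible by 3 after phase correction.
    """
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: List[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        transcripts: List[Transcript] = []
        for m in db.children(g, featuretype="mRNA", order_by="start"):
            exons = [(f.start - 1, f.end) for f in db.children(m, featuretype="exon", order_by="start")]
            cds = [
                (f.start - 1, f.end, int(f.frame) if f.frame not in (None, ".") else 0)
                for f in db.children(m, featuretype="CDS", order_by="start")
            ]
            utr5 = [
                (f.start - 1, f.end)
                for f in db.children(m, order_by="start")
                if f.featuretype in _UTR5_TYPES
            ]
            utr3 = [
                (f.start - 1, f.end)
                for f in db.children(m, order_by="start")
                if f.featuretype in _UTR3_TYPES
            ]
            transcripts.append(Transcript(m.id, exons, cds, utr5, utr3))
        model = GeneModel(g.id, g.seqid, g.strand, transcripts)
        model.validate()
        genes.append(model)
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str) -> None:
    """Emit gene models as GFF3 (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.chromosome, g.span[0], g.gene_id)):
        gs, ge = g.span
        lines.append(
            "\t".join(
                [g.chromosome, "reseqlens", "gene", str(gs + 1), str(ge), ".",
                 g.strand, ".", f"ID={g.gene_id}"]
            )
        )
        for t in g.transcripts:
            ts = min(iv[0] for iv in t.exons)
            te = max(iv[1] for iv in t.exons)
            lines.append(
                "\t".join(
                    [g.chromosome, "reseqlens", "mRNA", str(ts + 1), str(te), ".",
                     g.strand, ".", f"ID={t.transcript_id};Parent={g.gene_id}"]
                )
            )
            for s, e in t.exons:
                lines.append(_feature_line(g, t, "exon", s, e, "."))
            for s, e, phase in t.cds_segments:
                lines.append(_feature_line(g, t, "CDS", s, e, str(phase)))
            for s, e in t.utr5_segments:
                lines.append(_feature_line(g, t, "five_prime_UTR", s, e, "."))
            for s, e in t.utr3_segments:
                lines.append(_feature_line(g, t, "three_prime_UTR", s, e, "."))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _feature_line(g: GeneModel, t: Transcript, ftype: str, s: int, e: int, phase: str) -> str:
    return "\t".join(
        [g.chromosome, "reseqlens", ftype, str(s + 1), str(e), ".", g.strand,
         phase, f"Parent={t.transcript_id}"]
    )


# ---------------------------------------------------------------------------
# SAM (text subset)
# ---------------------------------------------------------------------------

_MULTI_TAG = ("XT", "R")  # MAPQ 0 + XT:A:R marks a multi-mapped read


def write_sam(
    alignments: Sequence[AlignedRead],
    chromosome_lengths: Dict[str, int],
    path: str,
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": n} for c, n in chromosome_lengths.items()],
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in alignments:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.query_sequence = r.sequence
            a.flag = 16 if r.is_reverse else 0
            a.reference_name = r.chromosome
            a.reference_start = r.start
            a.mapping_quality = 0 if r.uniqueness == "multiple" else 60
            a.cigarstring = r.cigar
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.base_qualities)
            )
            if r.uniqueness == "multiple":
                a.set_tag(_MULTI_TAG[0], _MULTI_TAG[1], value_type="A")
            out.write(a)


def read_sam(path: str) -> List[AlignedRead]:
    out: List[AlignedRead] = []
    with pysam.AlignmentFile(path, "r") as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            multi = a.mapping_quality == 0 and a.has_tag(_MULTI_TAG[0])
            out.append(
                AlignedRead(
                    read_id=a.query_name,
                    chromosome=a.reference_name,
                    start=a.reference_start,
                    cigar=a.cigarstring,
                    sequence=a.query_sequence,
                    base_qualities=np.array(a.query_qualities, dtype=np.uint8),
                    uniqueness="multiple" if multi else "unique",
                    is_reverse=a.is_reverse,
                )
            )
    return out


# ---------------------------------------------------------------------------
# BED / TSV
# ---------------------------------------------------------------------------


def write_bed(intervals: Iterable[Tuple[str, int, int]], path: str) -> None:
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path: str) -> List[Tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out
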