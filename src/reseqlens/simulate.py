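"""Seeded synthetic data: reference genomes, gene models, donors, reads, contigs.

The generator emulates the structure of an inbred rice resequencing study:
a chromosomal reference plus unanchored scaffolds, ~homozygous SNPs and
short InDels planted at configurable per-megabase densities, exact repeat
duplications that yield multi-mapped reads, and long novel donor insertions
whose reads cannot be placed on the reference and therefore land in the
unmapped-read pool.

Read placement uses a perfect-mapper idealisation: donor coordinates are
lifted to reference coordinates exactly through the planted-variant ledger,
so alignment CIGARs are correct by construction. Implementing an actual
read mapper is deliberately out of scope; mapping noise enters only through
sequencing errors (``base_error_rate``) and the declining per-cycle quality
profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from reseqlens.formats import AlignedRead, GeneModel, Transcript

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class GenomeSizingError(ValueError):
    """Requested content does not fit in the requested genome."""


class InfeasibleDensityError(ValueError):
    """Requested variant density exceeds available non-overlapping positions."""


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass
class GenomeSpec:
    """Shape of the synthetic reference genome.

    Defaults give a compact two-chromosome genome with one unanchored
    scaffold, dense enough in genes to exercise annotation and CDS-coverage
    statistics at desk scale.
    """

    chromosome_lengths: List[int] = field(default_factory=lambda: [1_000_000, 1_000_000])
    unanchored_lengths: List[int] = field(default_factory=lambda: [100_000])
    gene_count: int = 300
    mean_exons_per_gene: int = 4
    repeat_segment_count: int = 4
    repeat_length: int = 400
    novel_insertion_spec: List[Tuple[int, int]] = field(default_factory=lambda: [(2000, 2)])
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.chromosome_lengths + self.unanchored_lengths):
            raise ValueError("all sequence lengths must be > 0")


@dataclass
class VariantSpec:
    """Planted-variant densities (expected counts per megabase).

    ``snp_per_mb_windows`` overrides the uniform SNP rate for specific
    1 Mb windows, keyed by (chromosome, window index) — used to plant
    density hotspots and cold windows. Observed per-cultivar densities in
    japonica rice span roughly 50–900 SNPs/Mb; the defaults sit in the
    middle of that range with the empirical ~8:1 SNP:insertion ratio.
    """

    snp_per_mb: float = 300.0
    insertion_per_mb: float = 40.0
    deletion_per_mb: float = 45.0
    snp_per_mb_windows: Dict[Tuple[str, int], float] = field(default_factory=dict)
    window_size: int = 1_000_000
    max_indel_length: int = 50
    indel_length_decay: float = 0.5  # P(len) ∝ decay**(len-1), len = 1..max
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.snp_per_mb, self.insertion_per_mb, self.deletion_per_mb) < 0:
            raise ValueError("rates must be >= 0")

    def indel_length_weights(self) -> np.ndarray:
        w = self.indel_length_decay ** np.arange(self.max_indel_length)
        return w / w.sum()


@dataclass
class ReadSimConfig:
    """Single/paired short-read simulation parameters.

    ``quality_profile`` is the per-cycle mean Phred quality; the default is
    a linear decline along the read, reproducing the empirical pattern that
    3'-trimming raises the high-quality pass rate of unmapped reads.
    """

    read_length: int = 74
    target_depth: float = 30.0
    base_error_rate: float = 0.0
    quality_profile: Optional[np.ndarray] = None
    quality_sd: float = 3.0
    paired: bool = False
    fragment_length: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if not 36 <= self.read_length <= 150:
            raise ValueError("read_length must be in [36, 150]")
        if self.target_depth < 0:
            raise ValueError("target_depth must be >= 0")

    def profile(self) -> np.ndarray:
        if self.quality_profile is not None:
            p = np.asarray(self.quality_profile, dtype=float)
            if len(p) != self.read_length or p.min() < 2 or p.max() > 41:
                raise ValueError("quality_profile must have one mean in [2,41] per cycle")
            return p
        return np.linspace(38.0, 22.0, self.read_length)


# ---------------------------------------------------------------------------
# Truth set
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthVariant:
    """One planted variant, VCF-style: for InDels ``position`` is the
    anchor base, ``ref``/``alt`` include it."""

    chromosome: str
    position: int  # 0-based
    ref: str
    alt: str
    type: str  # 'SNP' | 'insertion' | 'deletion'
    novel: bool = False  # long novel donor insertion (unmappable reads)


class TruthVariantSet:
    """Planted variants; replaying them onto the reference reproduces the
    donor genome exactly (the edit-replay invariant)."""

    def __init__(self, records: Sequence[TruthVariant]):
        self.records: List[TruthVariant] = sorted(
            records, key=lambda r: (r.chromosome, r.position)
        )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_type(self, vtype: str, include_novel: bool = True) -> List[TruthVariant]:
        return [
            r for r in self.records
            if r.type == vtype and (include_novel or not r.novel)
        ]

    def apply_to(self, reference: Dict[str, str]) -> Dict[str, str]:
        """Replay all records onto ``reference`` and return the donor."""
        donor: Dict[str, str] = {}
        for chrom, seq in reference.items():
            recs = [r for r in self.records if r.chromosome == chrom]
            pieces: List[str] = []
            cursor = 0
            for r in recs:
                p = r.position
                if seq[p : p + len(r.ref)] != r.ref:
                    raise ValueError(
                        f"truth record {chrom}:{p} ref {r.ref!r} does not match reference"
                    )
                if r.type == "SNP":
                    pieces.append(seq[cursor:p])
                    pieces.append(r.alt)
                    cursor = p + 1
                elif r.type == "insertion":
                    pieces.append(seq[cursor : p + 1])
                    pieces.append(r.alt[1:])
                    cursor = p + 1
                elif r.type == "deletion":
                    pieces.append(seq[cursor : p + 1])
                    cursor = p + len(r.ref)
                else:
                    raise ValueError(f"unknown variant type {r.type}")
            pieces.append(seq[cursor:])
            donor[chrom] = "".join(pieces)
        return donor

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("#chromosome\tposition\tref\talt\ttype\tnovel\n")
            for r in self.records:
                fh.write(
                    f"{r.chromosome}\t{r.position}\t{r.ref}\t{r.alt}\t{r.type}\t"
                    f"{int(r.novel)}\n"
                )

    @classmethod
    def read_tsv(cls, path: str) -> "TruthVariantSet":
        recs = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                c, p, ref, alt, t, nov = line.rstrip("\n").split("\t")
                recs.append(TruthVariant(c, int(p), ref, alt, t, bool(int(nov))))
        return cls(recs)


# ---------------------------------------------------------------------------
# Reference generation
# ---------------------------------------------------------------------------


@dataclass
class ReferenceBundle:
    """A generated reference: sequences, gene models and repeat loci."""

    sequences: Dict[str, str]
    genes: List[GeneModel]
    repeats: List[Tuple[str, int, int]]  # every copy of every repeat segment
    chromosome_names: List[str]
    unanchored_names: List[str]

    def chromosome_lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _make_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    offset: int,
    mean_exons: int,
) -> Tuple[GeneModel, int]:
    """Build one random gene starting at ``offset``; returns (model, end)."""
    n_exons = max(1, int(rng.poisson(max(mean_exons - 1, 0))) + 1)
    cds_lens = [int(rng.integers(90, 300)) for _ in range(n_exons)]
    excess = sum(cds_lens) % 3
    if excess:
        cds_lens[-1] -= excess
    utr_left = int(rng.integers(30, 120))
    utr_right = int(rng.integers(30, 120))
    introns = [int(rng.integers(60, 200)) for _ in range(n_exons - 1)]
    strand = "+" if rng.random() < 0.5 else "-"

    exons: List[Tuple[int, int]] = []
    cds: List[Tuple[int, int, int]] = []
    pos = offset
    for i, clen in enumerate(cds_lens):
        ex_start = pos
        if i == 0:
            pos += utr_left
        cds.append((pos, pos + clen, 0))  # phases fixed below
        pos += clen
        if i == n_exons - 1:
            pos += utr_right
        exons.append((ex_start, pos))
        if i < n_exons - 1:
            pos += introns[i]
    utr_left_iv = [(offset, offset + utr_left)]
    utr_right_iv = [(exons[-1][1] - utr_right, exons[-1][1])]
    # GFF3 phase: bases to skip at segment start, in translation order
    order = cds if strand == "+" else list(reversed(cds))
    cum = 0
    phased = {}
    for s, e, _ in order:
        phased[(s, e)] = (3 - cum % 3) % 3
        cum += e - s
    cds = [(s, e, phased[(s, e)]) for s, e, _ in cds]
    utr5, utr3 = (utr_left_iv, utr_right_iv) if strand == "+" else (utr_right_iv, utr_left_iv)
    t = Transcript(f"{gene_id}.1", exons, cds, utr5, utr3)
    model = GeneModel(gene_id, chrom, strand, [t])
    return model, pos


def generate_reference(spec: GenomeSpec) -> ReferenceBundle:
    """Generate reference sequences, gene models and repeat duplications.

    Genes are placed left to right with random intergenic gaps, never
    overlapping; every transcript's CDS length is divisible by 3. Repeat
    segments are exact duplications copied to a second intergenic locus.
    Same spec (same seed) gives byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    chrom_names = [f"chr{i + 1:02d}" for i in range(len(spec.chromosome_lengths))]
    scaf_names = [f"scaffold{i + 1:02d}" for i in range(len(spec.unanchored_lengths))]
    sequences = {
        name: _random_seq(rng, n)
        for name, n in zip(chrom_names, spec.chromosome_lengths)
    }
    sequences.update(
        {name: _random_seq(rng, n) for name, n in zip(scaf_names, spec.unanchored_lengths)}
    )

    genes: List[GeneModel] = []
    gaps: List[Tuple[str, int, int]] = []  # intergenic gaps for repeat placement
    if spec.gene_count:
        per_chrom = np.full(len(chrom_names), spec.gene_count // len(chrom_names))
        per_chrom[: spec.gene_count % len(chrom_names)] += 1
        gi = 0
        for chrom, n_genes, length in zip(chrom_names, per_chrom, spec.chromosome_lengths):
            cursor = 0
            for _ in range(int(n_genes)):
                gap = int(rng.integers(300, 2000))
                model, end = _make_gene(
                    rng, f"GENE{gi + 1:05d}", chrom, cursor + gap, spec.mean_exons_per_gene
                )
                if end >= length:
                    raise GenomeSizingError(
                        f"gene_count {spec.gene_count} does not fit on {chrom} "
                        f"(length {length})"
                    )
                model.validate()
                genes.append(model)
                gaps.append((chrom, cursor, cursor + gap))
                gi += 1
                cursor = end
            gaps.append((chrom, cursor, length))
    else:
        gaps = [(c, 0, n) for c, n in zip(chrom_names, spec.chromosome_lengths)]

    repeats: List[Tuple[str, int, int]] = []
    if spec.repeat_segment_count:
        usable = [g for g in gaps if g[2] - g[1] >= spec.repeat_length + 20]
        if len(usable) < 2 * spec.repeat_segment_count:
            raise GenomeSizingError("not enough intergenic space for repeat segments")
        idx = rng.choice(len(usable), size=2 * spec.repeat_segment_count, replace=False)
        for k in range(spec.repeat_segment_count):
            (c1, s1, _), (c2, s2, _) = usable[idx[2 * k]], usable[idx[2 * k + 1]]
            src = (c1, s1 + 10, s1 + 10 + spec.repeat_length)
            dst = (c2, s2 + 10, s2 + 10 + spec.repeat_length)
            seq = sequences[src[0]][src[1] : src[2]]
            s = sequences[dst[0]]
            sequences[dst[0]] = s[: dst[1]] + seq + s[dst[2] :]
            repeats.extend([src, dst])

    return ReferenceBundle(sequences, genes, repeats, chrom_names, scaf_names)


# ---------------------------------------------------------------------------
# Variant planting
# ---------------------------------------------------------------------------

_OTHER = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


def plant_variants(
    reference: Dict[str, str],
    variant_spec: VariantSpec,
    novel_insertion_spec: Optional[Sequence[Tuple[int, int]]] = None,
) -> Tuple[Dict[str, str], TruthVariantSet]:
    """Plant non-overlapping homozygous variants; return (donor, truth).

    Per-window SNP counts are Poisson draws around the requested per-Mb
    expectations. Long novel insertions (``novel_insertion_spec`` as
    (length, count) pairs) are recorded in the truth set flagged
    ``novel=True``; their random sequences are absent from the reference.
    """
    if not reference:
        raise ValueError("reference is empty")
    rng = np.random.default_rng(variant_spec.seed)
    weights = variant_spec.indel_length_weights()
    records: List[TruthVariant] = []
    occupied_by_chrom = {c: np.zeros(len(s), dtype=bool) for c, s in reference.items()}

    def place(chrom: str, span: int, min_pos: int = 0) -> int:
        occupied = occupied_by_chrom[chrom]
        length = len(occupied)
        for _ in range(200):
            p = int(rng.integers(min_pos, length - span))
            if not occupied[p : p + span].any():
                occupied[p : p + span] = True
                return p
        raise InfeasibleDensityError(
            f"{chrom}: cannot place a variant of span {span}; density too high"
        )

    for chrom, seq in reference.items():
        length = len(seq)
        occupied = occupied_by_chrom[chrom]

        # InDels first (larger footprints), then SNPs
        n_ins = rng.poisson(variant_spec.insertion_per_mb * length / 1e6)
        n_del = rng.poisson(variant_spec.deletion_per_mb * length / 1e6)
        for _ in range(int(n_ins)):
            ilen = int(rng.choice(variant_spec.max_indel_length, p=weights)) + 1
            p = place(chrom, 1, min_pos=1)
            ins = _random_seq(rng, ilen)
            records.append(
                TruthVariant(chrom, p, seq[p], seq[p] + ins, "insertion")
            )
        for _ in range(int(n_del)):
            dlen = int(rng.choice(variant_spec.max_indel_length, p=weights)) + 1
            p = place(chrom, 1 + dlen, min_pos=1)
            records.append(
                TruthVariant(chrom, p, seq[p : p + 1 + dlen], seq[p], "deletion")
            )
        # SNPs window by window so hotspot/cold-window overrides apply
        w = variant_spec.window_size
        n_windows = (length + w - 1) // w
        for wi in range(n_windows):
            win_len = min(w, length - wi * w)
            rate = variant_spec.snp_per_mb_windows.get(
                (chrom, wi), variant_spec.snp_per_mb
            )
            n_snp = rng.poisson(rate * win_len / 1e6)
            if n_snp > 0.5 * win_len:
                raise InfeasibleDensityError(
                    f"{chrom} window {wi}: {n_snp} SNPs requested in {win_len} bp"
                )
            placed = 0
            attempts = 0
            while placed < n_snp and attempts < 50 * n_snp + 100:
                p = int(rng.integers(wi * w, wi * w + win_len))
                attempts += 1
                if occupied[p]:
                    continue
                occupied[p] = True
                alt = _OTHER[seq[p]][rng.integers(0, 3)]
                records.append(TruthVariant(chrom, p, seq[p], alt, "SNP"))
                placed += 1
            if placed < n_snp:
                raise InfeasibleDensityError(
                    f"{chrom} window {wi}: only placed {placed}/{n_snp} SNPs"
                )

    chroms = list(reference)
    if novel_insertion_spec:
        for ilen, count in novel_insertion_spec:
            for _ in range(count):
                chrom = chroms[int(rng.integers(len(chroms)))]
                p = place(chrom, 1, min_pos=1)
                ins = _random_seq(rng, ilen)
                records.append(
                    TruthVariant(
                        chrom, p, reference[chrom][p],
                        reference[chrom][p] + ins, "insertion", novel=True,
                    )
                )

    truth = TruthVariantSet(records)
    donor = truth.apply_to(reference)
    return donor, truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


class _LiftOver:
    """Donor→reference alignment blocks derived from the truth ledger."""

    def __init__(self, ref_len: int, records: Sequence[TruthVariant]):
        # blocks: (donor_start, donor_end, ref_start, is_insertion, is_novel)
        blocks: List[Tuple[int, int, int, bool, bool]] = []
        dpos = rpos = 0
        for r in sorted(records, key=lambda r: r.position):
            if r.type == "SNP":
                continue
            m = (r.position + 1) - rpos
            if r.type == "insertion":
                ilen = len(r.alt) - 1
                blocks.append((dpos, dpos + m, rpos, False, False))
                dpos += m
                rpos = r.position + 1
                blocks.append((dpos, dpos + ilen, -1, True, r.novel))
                dpos += ilen
            else:  # deletion
                dlen = len(r.ref) - 1
                blocks.append((dpos, dpos + m, rpos, False, False))
                dpos += m
                rpos = r.position + 1 + dlen
        blocks.append((dpos, dpos + (ref_len - rpos), rpos, False, False))
        self.blocks = [b for b in blocks if b[1] > b[0]]
        self.dstarts = np.array([b[0] for b in self.blocks], dtype=np.int64)
        self.donor_length = self.blocks[-1][1]

    def segments(self, s: int, e: int) -> List[Tuple[str, int, int]]:
        """Decompose donor interval [s,e) into ('M', length, ref_start) and
        ('I', length, -1 or novel marker) pieces."""
        out: List[Tuple[str, int, int]] = []
        i = int(np.searchsorted(self.dstarts, s, side="right")) - 1
        while i < len(self.blocks) and self.blocks[i][0] < e:
            bs, be, rstart, is_ins, is_novel = self.blocks[i]
            lo, hi = max(s, bs), min(e, be)
            if hi > lo:
                if is_ins:
                    out.append(("I" if not is_novel else "J", hi - lo, -1))
                else:
                    out.append(("M", hi - lo, rstart + (lo - bs)))
            i += 1
        return out


def simulate_alignments(
    donor: Dict[str, str],
    reference: Dict[str, str],
    truth: TruthVariantSet,
    cfg: ReadSimConfig,
    repeats: Optional[Sequence[Tuple[str, int, int]]] = None,
    uncovered_regions: Optional[Sequence[Tuple[str, int, int]]] = None,
) -> Tuple[List[AlignedRead], List[Tuple[str, str, np.ndarray]]]:
    """Sample reads uniformly from the donor and lift them to the reference.

    Returns (alignments sorted by (chromosome, start), unmapped reads).
    Reads with more than half their length inside inserted (donor-only)
    sequence are emitted as unmapped; reads falling entirely within a
    repeat-segment copy are flagged multi-mapped (MAPQ 0 in SAM output).
    ``uncovered_regions`` (reference coordinates) emulates reference
    segments too diverged for read mapping: reads overlapping them join
    the unmapped pool, leaving depth-0 reference runs behind.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.read_length
    profile = cfg.profile()
    alignments: List[AlignedRead] = []
    unmapped: List[Tuple[str, str, np.ndarray]] = []
    repeat_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for c, s, e in repeats or []:
        repeat_by_chrom.setdefault(c, []).append((s, e))
    uncovered_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for c, s, e in uncovered_regions or []:
        uncovered_by_chrom.setdefault(c, []).append((s, e))

    for chrom in reference:
        if L > len(reference[chrom]):
            raise GenomeSizingError(f"read_length {L} exceeds {chrom} length")
        lift = _LiftOver(len(reference[chrom]), [r for r in truth if r.chromosome == chrom])
        dseq = donor[chrom]
        if lift.donor_length != len(dseq):
            raise ValueError(f"{chrom}: donor length inconsistent with truth ledger")
        n_reads = int(round(cfg.target_depth * len(dseq) / L))
        if n_reads == 0:
            continue
        if cfg.paired:
            n_frag = max(n_reads // 2, 1)
            G = min(cfg.fragment_length, len(dseq))
            fstarts = rng.integers(0, len(dseq) - G + 1, size=n_frag)
            starts = np.concatenate([fstarts, fstarts + G - L])
            mates = np.concatenate(
                [np.zeros(n_frag, dtype=int), np.ones(n_frag, dtype=int)]
            )
            pair_ids = np.concatenate([np.arange(n_frag), np.arange(n_frag)])
        else:
            starts = rng.integers(0, len(dseq) - L + 1, size=n_reads)
            mates = np.zeros(n_reads, dtype=int)
            pair_ids = np.arange(n_reads)
        quals = np.clip(
            np.rint(rng.normal(profile, cfg.quality_sd, size=(len(starts), L))),
            2, 41,
        ).astype(np.uint8)
        if cfg.base_error_rate > 0:
            err_mask = rng.random((len(starts), L)) < cfg.base_error_rate
            err_shift = rng.integers(1, 4, size=(len(starts), L))
        else:
            err_mask = None
            err_shift = None

        base_to_idx = {b: i for i, b in enumerate("ACGT")}
        for i, s in enumerate(starts):
            s = int(s)
            mate = int(mates[i])
            rid = f"{chrom}_f{pair_ids[i]:07d}" + (f"/{mate + 1}" if cfg.paired else "")
            seq = dseq[s : s + L]
            if err_mask is not None and err_mask[i].any():
                chars = list(seq)
                for j in np.nonzero(err_mask[i])[0]:
                    b = chars[j]
                    if b in base_to_idx:
                        chars[j] = "ACGT"[(base_to_idx[b] + err_shift[i, j]) % 4]
                seq = "".join(chars)
            q = quals[i] if mate == 0 else quals[i][::-1]
            segs = lift.segments(s, s + L)
            inserted = sum(n for op, n, _ in segs if op in "IJ")
            if inserted > L / 2:
                unmapped.append((rid, seq, q))
                continue
            cigar_ops: List[Tuple[int, str]] = []
            pos0 = None
            prev_ref_end = None
            m_index = [k for k, (op, _, _) in enumerate(segs) if op == "M"]
            first_m, last_m = m_index[0], m_index[-1]
            for k, (op, n, rstart) in enumerate(segs):
                if op == "M":
                    if pos0 is None:
                        pos0 = rstart
                    if prev_ref_end is not None and rstart > prev_ref_end:
                        cigar_ops.append((rstart - prev_ref_end, "D"))
                    cigar_ops.append((n, "M"))
                    prev_ref_end = rstart + n
                else:
                    kind = "S" if (k < first_m or k > last_m) else "I"
                    cigar_ops.append((n, kind))
            # merge adjacent same-op runs
            merged: List[Tuple[int, str]] = []
            for n, op in cigar_ops:
                if merged and merged[-1][1] == op:
                    merged[-1] = (merged[-1][0] + n, op)
                else:
                    merged.append((n, op))
            cigar = "".join(f"{n}{op}" for n, op in merged)
            ref_end = prev_ref_end
            diverged = any(
                pos0 < ue and us < ref_end
                for us, ue in uncovered_by_chrom.get(chrom, [])
            )
            if diverged:
                unmapped.append((rid, seq, q))
                continue
            uniqueness = "unique"
            for rs, re_ in repeat_by_chrom.get(chrom, []):
                if rs <= pos0 and ref_end <= re_:
                    uniqueness = "multiple"
                    break
            alignments.append(
                AlignedRead(
                    read_id=rid,
                    chromosome=chrom,
                    start=pos0,
                    cigar=cigar,
                    sequence=seq,
                    base_qualities=q,
                    uniqueness=uniqueness,
                    is_reverse=bool(mate),
                )
            )
    alignments.sort(key=lambda r: (r.chromosome, r.start, r.read_id))
    return alignments, unmapped


# ---------------------------------------------------------------------------
# Contig simulation
# ---------------------------------------------------------------------------


@dataclass
class ContigSimSpec:
    """Counts and lengths of the four contig classes to emit.

    Stands in for an assembly of unmapped reads: contigs are exact copies
    of unique reference substrings, repeat-segment copies, unanchored-
    scaffold substrings, or novel random sequence absent from the reference.
    ``from_intervals`` additionally copies the given reference intervals
    verbatim (used to plant rescue scenarios)."""

    unique_count: int = 5
    unique_length: int = 500
    repeat_count: int = 2
    unanchored_count: int = 2
    unanchored_length: int = 400
    novel_count: int = 2
    novel_length: int = 500
    from_intervals: List[Tuple[str, int, int]] = field(default_factory=list)
    seed: int = 0


def simulate_contigs(
    reference: ReferenceBundle,
    spec: ContigSimSpec,
) -> Tuple[Dict[str, str], Dict[str, Dict]]:
    """Emit contigs of the requested classes; returns (contigs, truth).

    ``truth[contig_id]`` records the class and, where applicable, the
    source locus. Same seed gives identical output.
    """
    rng = np.random.default_rng(spec.seed)
    contigs: Dict[str, str] = {}
    truth: Dict[str, Dict] = {}

    def grab(chrom: str, length: int, avoid: Sequence[Tuple[int, int]] = ()) -> Tuple[int, str]:
        seq = reference.sequences[chrom]
        if length > len(seq):
            raise GenomeSizingError(f"substring of {length} bp exceeds {chrom}")
        for _ in range(100):
            s = int(rng.integers(0, len(seq) - length + 1))
            if not any(s < e and a < s + length for a, e in avoid):
                return s, seq[s : s + length]
        raise GenomeSizingError(f"cannot place {length} bp substring on {chrom}")

    i = 0
    repeat_avoid = {
        c: [(s, e) for rc, s, e in reference.repeats if rc == c]
        for c in reference.chromosome_names
    }
    for _ in range(spec.unique_count):
        chrom = reference.chromosome_names[int(rng.integers(len(reference.chromosome_names)))]
        s, seq = grab(chrom, spec.unique_length, avoid=repeat_avoid.get(chrom, []))
        cid = f"contig{i:04d}"
        contigs[cid] = seq
        truth[cid] = {"class": "unique", "locus": (chrom, s, s + spec.unique_length)}
        i += 1
    for k in range(spec.repeat_count):
        if not reference.repeats:
            break
        c, s, e = reference.repeats[k % len(reference.repeats)]
        cid = f"contig{i:04d}"
        contigs[cid] = reference.sequences[c][s:e]
        truth[cid] = {"class": "repeat", "locus": (c, s, e)}
        i += 1
    for _ in range(spec.unanchored_count):
        if not reference.unanchored_names:
            break
        scaf = reference.unanchored_names[int(rng.integers(len(reference.unanchored_names)))]
        s, seq = grab(scaf, spec.unanchored_length)
        cid = f"contig{i:04d}"
        contigs[cid] = seq
        truth[cid] = {"class": "unanchored", "locus": (scaf, s, s + spec.unanchored_length)}
        i += 1
    for _ in range(spec.novel_count):
        cid = f"contig{i:04d}"
        contigs[cid] = _random_seq(rng, spec.novel_length)
        truth[cid] = {"class": "novel"}
        i += 1
    for chrom, s, e in spec.from_intervals:
        cid = f"contig{i:04d}"
        contigs[cid] = reference.sequences[chrom][s:e]
        truth[cid] = {"class": "planted", "locus": (chrom, s, e)}
        i += 1
    return contigs, truth
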