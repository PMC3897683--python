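"""Genome/CDS coverage statistics, read subsampling and depth saturation.

Conventions:

* genome coverage = percent of reference positions with depth >= a
  threshold (default 5), relative to the supplied reference's length;
* average depth = total aligned depth divided by the number of *covered*
  positions (depth >= 1), not by genome length — the convention implied by
  the arithmetic of published mapped-nucleotide / depth / coverage tables;
* CDS coverage of a gene = covered fraction of the union of its CDS
  segments across transcripts (depth >= 1 by default, "covered by reads");
* gene-coverage bins: 100 (exactly complete), then half-open 10-point
  bands [0.9,1), [0.8,0.9) ... [0.1,0.2), (0,0.1), and exactly 0 — twelve
  labels that partition [0,1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from reseqlens.formats import AlignedRead, DepthTrack, GeneModel, depth_track

BIN_LABELS = [
    "100", "90<=", "80<=", "70<=", "60<=", "50<=", "40<=", "30<=",
    "20<=", "10<=", "0<", "0",
]


@dataclass
class CoverageSummary:
    mapped_nucleotides: int
    genome_coverage_ge5: float  # percent
    average_depth: float  # fold, covered-positions denominator


@dataclass
class GeneCoverageBin:
    label: str
    gene_count: int


def genome_coverage(
    track: DepthTrack,
    min_depth: int = 5,
    chromosomes: Sequence[str] | None = None,
) -> float:
    """Percent of reference positions with depth >= ``min_depth``."""
    names = list(chromosomes) if chromosomes is not None else track.chromosomes()
    total = track.total_length(names)
    if total == 0:
        raise ValueError("empty reference: coverage denominator undefined")
    covered = sum(int((track[c] >= min_depth).sum()) for c in names)
    return 100.0 * covered / total


def average_depth(
    track: DepthTrack, chromosomes: Sequence[str] | None = None
) -> float:
    """Mean depth over covered positions (depth >= 1)."""
    names = list(chromosomes) if chromosomes is not None else track.chromosomes()
    covered = sum(int((track[c] >= 1).sum()) for c in names)
    if covered == 0:
        raise ValueError("no covered positions: average depth undefined")
    total = sum(int(track[c].sum()) for c in names)
    return total / covered


def coverage_summary(
    track: DepthTrack,
    min_depth: int = 5,
    chromosomes: Sequence[str] | None = None,
) -> CoverageSummary:
    names = list(chromosomes) if chromosomes is not None else track.chromosomes()
    return CoverageSummary(
        mapped_nucleotides=track.total_depth(names),
        genome_coverage_ge5=genome_coverage(track, min_depth, names),
        average_depth=average_depth(track, names),
    )


def cds_coverage(
    track: DepthTrack, gene: GeneModel, min_depth: int = 1
) -> float:
    """Covered fraction of the gene's CDS union, in [0, 1]."""
    union = gene.cds_union()
    total = sum(e - s for s, e in union)
    if total == 0:
        raise ValueError(f"{gene.gene_id}: zero CDS length")
    arr = track[gene.chromosome]
    covered = 0
    for s, e in union:
        if e > len(arr):
            raise IndexError(f"{gene.gene_id}: CDS [{s},{e}) outside reference")
        covered += int((arr[s:e] >= min_depth).sum())
    return covered / total


def bin_genes_by_coverage(fractions: Dict[str, float]) -> List[GeneCoverageBin]:
    """Partition genes into the twelve coverage bins (counts sum to total)."""
    counts = {label: 0 for label in BIN_LABELS}
    for gene_id, f in fractions.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{gene_id}: coverage fraction {f} outside [0,1]")
        if f == 1.0:
            counts["100"] += 1
        elif f == 0.0:
            counts["0"] += 1
        else:
            # epsilon guards float ratios like 3/10 landing a hair below a
            # bin edge; denominators are gene lengths, far below 1e9
            decile = min(int(f * 10 + 1e-9), 9)
            counts["0<" if decile == 0 else f"{decile * 10}<="] += 1
    return [GeneCoverageBin(label, counts[label]) for label in BIN_LABELS]


def realized_depth(
    alignments: Sequence[AlignedRead], genome_length: int
) -> float:
    """Aligned reference-consuming nucleotides of unique reads / genome length."""
    total = sum(r.reference_length for r in alignments if r.uniqueness == "unique")
    return total / genome_length


def subsample_alignments(
    alignments: Sequence[AlignedRead],
    target_depth: float,
    current_depth: float,
    seed: int,
) -> List[AlignedRead]:
    """Randomly retain reads so realized depth scales to ``target_depth``.

    Exact-count sampling without replacement (not Bernoulli thinning) for
    tight depth control; paired reads are retained or dropped as a pair.
    Original order is preserved; the same seed reproduces the same subset.
    """
    if not 0 < target_depth <= current_depth:
        raise ValueError("need 0 < target_depth <= current_depth")
    if target_depth == current_depth:
        return list(alignments)
    units: Dict[str, List[int]] = {}
    for i, r in enumerate(alignments):
        units.setdefault(r.read_id.split("/")[0], []).append(i)
    unit_ids = list(units)
    n_keep = int(round(len(unit_ids) * target_depth / current_depth))
    rng = np.random.default_rng(seed)
    keep_units = rng.choice(len(unit_ids), size=n_keep, replace=False)
    keep = sorted(i for u in keep_units for i in units[unit_ids[u]])
    return [alignments[i] for i in keep]


def saturation_curve(
    alignments: Sequence[AlignedRead],
    gene_models: Sequence[GeneModel],
    depths: Sequence[float],
    chromosome_lengths: Dict[str, int],
    coverage_threshold: float = 0.9,
    min_depth: int = 1,
    seed: int = 0,
    nested: bool = True,
) -> Dict[float, int]:
    """Genes with CDS coverage >= threshold at each subsampled depth.

    With ``nested=True`` (default) the subsamples at increasing depth are
    prefixes of one seeded permutation of the read set, which guarantees
    the gene counts are non-decreasing in depth.
    """
    genome_length = sum(chromosome_lengths.values())
    current = realized_depth(alignments, genome_length)
    for d in depths:
        if d > current * 1.0001:
            raise ValueError(f"target depth {d} exceeds current depth {current:.2f}")

    units: Dict[str, List[int]] = {}
    for i, r in enumerate(alignments):
        units.setdefault(r.read_id.split("/")[0], []).append(i)
    unit_ids = list(units)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(unit_ids))

    result: Dict[float, int] = {}
    for d in sorted(depths):
        if nested:
            n_keep = int(round(len(unit_ids) * min(d / current, 1.0)))
            keep = sorted(
                i for u in perm[:n_keep] for i in units[unit_ids[u]]
            )
            sub = [alignments[i] for i in keep]
        else:
            sub = subsample_alignments(alignments, d, current, seed=seed + int(d * 1000))
        track = depth_track(sub, chromosome_lengths)
        count = sum(
            1
            for g in gene_models
            if cds_coverage(track, g, min_depth) >= coverage_threshold
        )
        result[d] = count
    return result
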