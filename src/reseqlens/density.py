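"""Per-megabase variant density tables and cross-sample region flagging.

Windows are fixed-grid [i*W, (i+1)*W) with W = 1 Mb by default; a trailing
partial window is kept and counted as-is (not density-normalised). Shared
high-density regions are windows where *every* sample exceeds the
threshold (default > 500 variants per window); fold-difference regions
compare two samples with a pseudocount-guarded ratio and an
informativeness floor on the larger count. Adjacent qualifying windows
merge into one region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from reseqlens.calling import VariantCall


@dataclass
class WindowCounts:
    sample: str
    window_size: int
    counts: Dict[str, np.ndarray]  # chromosome -> per-window counts

    def total(self) -> int:
        return int(sum(a.sum() for a in self.counts.values()))

    def chromosome_total(self, chromosome: str) -> int:
        return int(self.counts[chromosome].sum())


@dataclass
class FlaggedRegion:
    chromosome: str
    start: int  # bp, window-aligned
    end: int
    kind: str  # 'shared_high_density' | 'fold_difference'
    samples: Tuple[str, ...]
    statistic: float  # min count across samples, or fold ratio

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("region end must exceed start")


def window_counts(
    variants: Sequence[VariantCall],
    chromosome_lengths: Dict[str, int],
    window_size: int = 1_000_000,
    sample: str = "",
) -> WindowCounts:
    """Histogram of variant positions on the fixed window grid."""
    counts = {
        c: np.zeros((n + window_size - 1) // window_size, dtype=np.int64)
        for c, n in chromosome_lengths.items()
    }
    for v in variants:
        if v.chromosome not in chromosome_lengths:
            raise KeyError(f"variant chromosome {v.chromosome} unknown")
        if not 0 <= v.position < chromosome_lengths[v.chromosome]:
            raise IndexError(
                f"variant at {v.chromosome}:{v.position} beyond chromosome end"
            )
        counts[v.chromosome][v.position // window_size] += 1
    return WindowCounts(sample=sample, window_size=window_size, counts=counts)


def chromosome_table(
    per_sample: Dict[str, Sequence[VariantCall]],
    chromosome_names: Sequence[str],
) -> pd.DataFrame:
    """Per-chromosome SNP/insertion/deletion counts with totals.

    Rows are a (type, chromosome) MultiIndex including a 'Total' row per
    type; columns are samples.
    """
    types = ("SNP", "insertion", "deletion")
    rows = []
    for t in types:
        for c in list(chromosome_names) + ["Total"]:
            rows.append((t, c))
    data = {}
    for sample, variants in per_sample.items():
        col = {}
        for t in types:
            per_chrom = {c: 0 for c in chromosome_names}
            for v in variants:
                if v.type == t and v.chromosome in per_chrom:
                    per_chrom[v.chromosome] += 1
            for c in chromosome_names:
                col[(t, c)] = per_chrom[c]
            col[(t, "Total")] = sum(per_chrom.values())
        data[sample] = col
    df = pd.DataFrame(data)
    return df.reindex(pd.MultiIndex.from_tuples(rows, names=["type", "chromosome"]))


def _check_grids(all_counts: Sequence[WindowCounts]) -> None:
    first = all_counts[0]
    for wc in all_counts[1:]:
        if wc.window_size != first.window_size or set(wc.counts) != set(first.counts):
            raise ValueError("window grids differ between samples")
        for c in first.counts:
            if len(wc.counts[c]) != len(first.counts[c]):
                raise ValueError(f"window grid length differs on {c}")


def _merge_windows(
    flags: np.ndarray, chromosome: str, window_size: int, chrom_len_windows: int,
    kind: str, samples: Tuple[str, ...], stat_per_window: np.ndarray,
) -> List[FlaggedRegion]:
    regions: List[FlaggedRegion] = []
    i = 0
    while i < len(flags):
        if flags[i]:
            j = i
            while j + 1 < len(flags) and flags[j + 1]:
                j += 1
            stat = float(stat_per_window[i : j + 1].max())
            regions.append(
                FlaggedRegion(
                    chromosome=chromosome,
                    start=i * window_size,
                    end=(j + 1) * window_size,
                    kind=kind,
                    samples=samples,
                    statistic=stat,
                )
            )
            i = j + 1
        else:
            i += 1
    return regions


def shared_high_density_regions(
    all_counts: Sequence[WindowCounts],
    threshold: int = 500,
) -> List[FlaggedRegion]:
    """Windows where every sample's count exceeds ``threshold``, merged."""
    if not all_counts:
        return []
    _check_grids(all_counts)
    samples = tuple(wc.sample for wc in all_counts)
    regions: List[FlaggedRegion] = []
    w = all_counts[0].window_size
    for chrom in all_counts[0].counts:
        stack = np.vstack([wc.counts[chrom] for wc in all_counts])
        flags = (stack > threshold).all(axis=0)
        regions.extend(
            _merge_windows(
                flags, chrom, w, len(flags), "shared_high_density", samples,
                stack.min(axis=0),
            )
        )
    return regions


def fold_difference_regions(
    a: WindowCounts,
    b: WindowCounts,
    fold: float = 5.0,
    min_count: int = 50,
) -> List[FlaggedRegion]:
    """Windows where the two samples differ more than ``fold``-fold.

    A window qualifies when max(a,b) >= min_count (informativeness floor)
    and max / max(min, 1) > fold (pseudocount guards empty windows).
    Symmetric in (a, b).
    """
    _check_grids([a, b])
    regions: List[FlaggedRegion] = []
    for chrom in a.counts:
        ca, cb = a.counts[chrom], b.counts[chrom]
        hi = np.maximum(ca, cb)
        lo = np.minimum(ca, cb)
        ratio = hi / np.maximum(lo, 1)
        flags = (hi >= min_count) & (ratio > fold)
        regions.extend(
            _merge_windows(
                flags, chrom, a.window_size, len(flags), "fold_difference",
                (a.sample, b.sample), ratio,
            )
        )
    return regions


@dataclass
class DensityFloorReport:
    """Windows below a density floor, per sample and jointly.

    'below the floor in any sample' and 'below in all samples' are both
    reported because the underlying question is ambiguous; interpretation
    is left to the caller.
    """

    floor: int
    per_sample_minimum: Dict[str, int]
    below_floor_per_sample: Dict[str, List[Tuple[str, int, int]]]
    below_floor_any: List[Tuple[str, int, int]] = field(default_factory=list)
    below_floor_all: List[Tuple[str, int, int]] = field(default_factory=list)


def density_floor_report(
    all_counts: Sequence[WindowCounts],
    floor: int = 50,
) -> DensityFloorReport:
    """Report windows whose variant count falls below ``floor``."""
    _check_grids(all_counts)
    w = all_counts[0].window_size
    per_sample: Dict[str, List[Tuple[str, int, int]]] = {}
    minima: Dict[str, int] = {}
    for wc in all_counts:
        windows = []
        mins = []
        for chrom, arr in wc.counts.items():
            mins.append(int(arr.min()) if len(arr) else 0)
            for i in np.nonzero(arr < floor)[0]:
                windows.append((chrom, int(i) * w, (int(i) + 1) * w))
        per_sample[wc.sample] = sorted(windows)
        minima[wc.sample] = min(mins) if mins else 0
    any_set = sorted(set().union(*[set(v) for v in per_sample.values()])) if per_sample else []
    all_set = (
        sorted(set.intersection(*[set(v) for v in per_sample.values()]))
        if per_sample
        else []
    )
    return DensityFloorReport(
        floor=floor,
        per_sample_minimum=minima,
        below_floor_per_sample=per_sample,
        below_floor_any=any_set,
        below_floor_all=all_set,
    )


def write_window_table(wc: WindowCounts, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#sample\tchromosome\twindow_start\twindow_end\tcount\n")
        for chrom, arr in wc.counts.items():
            for i, n in enumerate(arr):
                fh.write(
                    f"{wc.sample}\t{chrom}\t{i * wc.window_size}\t"
                    f"{(i + 1) * wc.window_size}\t{int(n)}\n"
                )


def regions_to_bed(regions: Sequence[FlaggedRegion]) -> List[Tuple[str, int, int, str]]:
    return [
        (r.chromosome, r.start, r.end, f"{r.kind}:{r.statistic:.1f}")
        for r in sorted(regions, key=lambda r: (r.chromosome, r.start))
    ]
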