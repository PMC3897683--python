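"""Seeded local alignment of contigs against a reference.

Exact k-mer seeds (default k = 15) locate candidate loci; each seed
cluster is then resolved with a full affine-gap Smith-Waterman alignment
of the contig against the local reference window. Scoring follows the
classic nucleotide-search scheme: match +1, mismatch -3, gap open -5,
gap extend -2, where a gap of length L costs open + L*extend (the first
gap base costs 7).

Significance uses the Karlin-Altschul form E = K * m * n * exp(-lambda*S)
with (lambda, K) precomputed for the default scoring scheme; supplying a
different scheme requires supplying matching constants, as full parameter
estimation is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

MATCH = 1
MISMATCH = -3
GAP_OPEN = -5
GAP_EXTEND = -2

# Karlin-Altschul constants for the +1/-3, 5/2 gapped scheme
LAMBDA = 1.28
KA_K = 0.46

NEG_INF = -(10 ** 8)


@dataclass
class ContigAlignment:
    """One local alignment of a contig to a reference sequence."""

    contig_id: str
    target: str
    target_start: int
    target_end: int
    contig_start: int
    contig_end: int
    percent_identity: float
    score: int
    e_value: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("identity out of [0,100]")


@njit(cache=True)
def _sw_kernel(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = len(q), len(t)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    F = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    open_cost = -(gap_open + gap_extend)
    ext_cost = -gap_extend
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i - 1, j] - open_cost
            if E[i - 1, j] - ext_cost > e:
                e = E[i - 1, j] - ext_cost
            E[i, j] = e
            f = H[i, j - 1] - open_cost
            if F[i, j - 1] - ext_cost > f:
                f = F[i, j - 1] - ext_cost
            F[i, j] = f
            s = match if q[i - 1] == t[j - 1] else mismatch
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback from (bi, bj) in state H
    i, j = bi, bj
    matches = 0
    aln_len = 0
    state = 0  # 0 = H, 1 = E (gap in target, up), 2 = F (gap in query, left)
    while i > 0 and j > 0:
        if state == 0:
            h = H[i, j]
            if h == 0:
                break
            s = match if q[i - 1] == t[j - 1] else mismatch
            if h == H[i - 1, j - 1] + s:
                if q[i - 1] == t[j - 1]:
                    matches += 1
                aln_len += 1
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            aln_len += 1
            if E[i, j] == E[i - 1, j] - ext_cost:
                i -= 1
            else:
                i -= 1
                state = 0
        else:
            aln_len += 1
            if F[i, j] == F[i, j - 1] - ext_cost:
                j -= 1
            else:
                j -= 1
                state = 0
    return best, i, bi, j, bj, matches, aln_len


def smith_waterman(
    query: str,
    target: str,
    match: int = MATCH,
    mismatch: int = MISMATCH,
    gap_open: int = GAP_OPEN,
    gap_extend: int = GAP_EXTEND,
) -> Tuple[int, int, int, int, int, int, int]:
    """Best local alignment of query vs target.

    Returns (score, q_start, q_end, t_start, t_end, matches, aln_len) with
    half-open intervals. Gap of length L costs -(gap_open + L*gap_extend).
    """
    q = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
    t = np.frombuffer(target.encode("ascii"), dtype=np.uint8)
    if len(q) == 0 or len(t) == 0:
        return 0, 0, 0, 0, 0, 0, 0
    score, qs, qe, ts, te, matches, aln_len = _sw_kernel(
        q, t, match, mismatch, gap_open, gap_extend
    )
    return int(score), int(qs), int(qe), int(ts), int(te), int(matches), int(aln_len)


def e_value(score: int, query_length: int, database_length: int,
            lam: float = LAMBDA, k: float = KA_K) -> float:
    return k * query_length * database_length * math.exp(-lam * score)


_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    for i in range(k):
        out = (out << 2) | codes[i : i + n]
    return out


class ReferenceIndex:
    """Sorted k-mer index over the reference sequences."""

    def __init__(self, reference: Dict[str, str], k: int = 15, max_occurrences: int = 200):
        if not reference:
            raise ValueError("empty reference")
        self.k = k
        self.max_occurrences = max_occurrences
        self.reference = reference
        self.total_length = sum(len(s) for s in reference.values())
        self._index: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for name, seq in reference.items():
            kmers = _kmer_codes(seq, k)
            order = np.argsort(kmers, kind="stable")
            self._index[name] = (kmers[order], order.astype(np.int64))

    def seed_hits(self, query: str, target: str) -> Tuple[np.ndarray, np.ndarray]:
        """(query_pos, target_pos) arrays for every shared k-mer."""
        qk = _kmer_codes(query, self.k)
        skmers, spos = self._index[target]
        lo = np.searchsorted(skmers, qk, side="left")
        hi = np.searchsorted(skmers, qk, side="right")
        counts = hi - lo
        keep = (counts > 0) & (counts <= self.max_occurrences)
        qpos_list: List[np.ndarray] = []
        tpos_list: List[np.ndarray] = []
        for qi in np.nonzero(keep)[0]:
            tpos_list.append(spos[lo[qi] : hi[qi]])
            qpos_list.append(np.full(int(counts[qi]), qi, dtype=np.int64))
        if not qpos_list:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        return np.concatenate(qpos_list), np.concatenate(tpos_list)


def _cluster_windows(
    qpos: np.ndarray, tpos: np.ndarray, qlen: int, tlen: int,
    band: int = 100, pad: int = 60,
) -> List[Tuple[int, int]]:
    """Candidate target windows from seed hits, merged when overlapping."""
    diag = tpos - qpos
    order = np.argsort(diag, kind="stable")
    diag = diag[order]
    windows: List[Tuple[int, int]] = []
    start = 0
    for i in range(1, len(diag) + 1):
        if i == len(diag) or diag[i] - diag[i - 1] > band:
            d_lo, d_hi = int(diag[start]), int(diag[i - 1])
            lo = max(0, d_lo - pad)
            hi = min(tlen, d_hi + qlen + pad)
            windows.append((lo, hi))
            start = i
    windows.sort()
    merged = [windows[0]]
    for lo, hi in windows[1:]:
        if lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def align_contigs(
    contigs: Dict[str, str],
    reference: Dict[str, str],
    e_value_max: float = 1e-10,
    k: int = 15,
    index: Optional[ReferenceIndex] = None,
) -> List[ContigAlignment]:
    """Align every contig to the reference; keep hits with E <= threshold.

    Non-overlapping loci on the same or different targets are reported as
    separate alignments (so a repeat-derived contig yields several).
    """
    idx = index if index is not None else ReferenceIndex(reference, k=k)
    out: List[ContigAlignment] = []
    for cid, cseq in contigs.items():
        hits: List[ContigAlignment] = []
        for target, tseq in reference.items():
            qpos, tpos = idx.seed_hits(cseq, target)
            if len(qpos) == 0:
                continue
            for lo, hi in _cluster_windows(qpos, tpos, len(cseq), len(tseq)):
                score, qs, qe, ts, te, matches, aln_len = smith_waterman(
                    cseq, tseq[lo:hi]
                )
                if score <= 0 or aln_len == 0:
                    continue
                ev = e_value(score, len(cseq), idx.total_length)
                if ev > e_value_max:
                    continue
                hits.append(
                    ContigAlignment(
                        contig_id=cid,
                        target=target,
                        target_start=lo + ts,
                        target_end=lo + te,
                        contig_start=qs,
                        contig_end=qe,
                        percent_identity=100.0 * matches / aln_len,
                        score=score,
                        e_value=ev,
                    )
                )
        out.extend(_dedupe_overlapping(hits))
    return out


def _dedupe_overlapping(hits: List[ContigAlignment]) -> List[ContigAlignment]:
    """Keep the best-scoring alignment among overlapping target loci."""
    kept: List[ContigAlignment] = []
    for h in sorted(hits, key=lambda a: -a.score):
        clash = any(
            k.target == h.target
            and h.target_start < k.target_end
            and k.target_start < h.target_end
            for k in kept
        )
        if not clash:
            kept.append(h)
    kept.sort(key=lambda a: (a.target, a.target_start))
    return kept
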