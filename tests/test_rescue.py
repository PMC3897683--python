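"""Read trimming, assembly stats, seeded aligner and the rescue stage."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reseqlens.formats import DepthTrack, GeneModel, Transcript, depth_track
from reseqlens.rescue import (
    classification_counts,
    classify_contigs,
    contig_stats,
    depth_zero_regions,
    find_newly_mapped,
    trim_and_filter_reads,
)
from reseqlens.seedalign import (
    ContigAlignment,
    ReferenceIndex,
    align_contigs,
    e_value,
    smith_waterman,
)
from reseqlens.simulate import (
    ContigSimSpec,
    GenomeSpec,
    ReadSimConfig,
    VariantSpec,
    generate_reference,
    plant_variants,
    simulate_alignments,
    simulate_contigs,
)


# ---------------------------------------------------------------------------
# Trimming / QC
# ---------------------------------------------------------------------------


def _read(rid, length, quals):
    return (rid, "A" * length, np.asarray(quals, dtype=np.uint8))


def test_trim_keeps_prefix():
    kept, rate = trim_and_filter_reads([_read("r", 74, [30] * 74)], 50)
    assert len(kept[0][1]) == 50 and len(kept[0][2]) == 50
    assert rate == 1.0


def test_quality_threshold_is_strict():
    """A base at exactly quality 20 inside the kept prefix drops the read."""
    quals = [30] * 74
    quals[10] = 20
    kept, rate = trim_and_filter_reads([_read("r", 74, quals)], 50)
    assert kept == [] and rate == 0.0
    # the offending base beyond the trim point is irrelevant
    quals = [30] * 74
    quals[60] = 5
    kept, _ = trim_and_filter_reads([_read("r", 74, quals)], 50)
    assert len(kept) == 1


def test_pass_rate_rises_as_trim_shortens():
    """With declining per-cycle quality, shorter trims pass more reads."""
    rng = np.random.default_rng(3)
    profile = np.linspace(38, 16, 74)
    reads = [
        _read(f"r{i}", 74, np.clip(rng.normal(profile, 3), 2, 41).astype(np.uint8))
        for i in range(400)
    ]
    rates = [
        trim_and_filter_reads(reads, t)[1] for t in (74, 60, 50, 40)
    ]
    brute = [
        sum(1 for _, _, q in reads if (q[:t] > 20).all()) / len(reads)
        for t in (74, 60, 50, 40)
    ]
    assert rates == brute
    assert rates == sorted(rates)  # non-decreasing as trim shortens
    with pytest.raises(ValueError):
        trim_and_filter_reads(reads, 0)


# ---------------------------------------------------------------------------
# Assembly stats
# ---------------------------------------------------------------------------


def test_n50_examples():
    assert contig_stats({"c": "A" * 1500}).n50 == 1500
    stats = contig_stats(
        {f"c{i}": "A" * n for i, n in enumerate([5, 4, 3, 2, 1])}
    )
    assert stats.n50 == 4  # 5+4 = 9 >= 15/2
    assert stats.longest == 5 and stats.total_bases == 15
    boundary = contig_stats({f"c{i}": "A" * 999 for i in range(3)})
    assert boundary.count_gt_1kb == 0  # strictly longer than 1,000
    single = contig_stats({"c": "A" * 1500})
    assert single.count_gt_1kb == 1 and single.total_bases_gt_1kb == 1500
    with pytest.raises(ValueError):
        contig_stats({})


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.lists(st.integers(min_value=1, max_value=5000), min_size=1, max_size=40))
def test_n50_matches_definition_scan(lengths):
    """N50 equals the brute-force definition on any multiset of lengths."""
    stats = contig_stats({f"c{i}": "A" * n for i, n in enumerate(lengths)})
    total = sum(lengths)
    candidates = [
        L for L in set(lengths)
        if sum(x for x in lengths if x >= L) * 2 >= total
    ]
    assert stats.n50 == max(candidates)


# ---------------------------------------------------------------------------
# Seeded aligner
# ---------------------------------------------------------------------------


def _pairwise_oracle(q, t):
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -3
    aligner.open_gap_score = -7  # first gap base: open(-5) + extend(-2)
    aligner.extend_gap_score = -2
    return aligner.score(q, t)


@pytest.mark.parametrize("seed", range(6))
def test_smith_waterman_matches_dynamic_programming_oracle(seed):
    """Kernel scores equal a full DP oracle on pairs up to 200 bp."""
    rng = np.random.default_rng(seed)
    n, m = int(rng.integers(40, 200)), int(rng.integers(40, 200))
    q = "".join(rng.choice(list("ACGT"), size=n))
    if seed % 2:
        # embed a mutated copy so alignments are non-trivial
        start = int(rng.integers(0, m - 30))
        core = list(q[:60])
        for j in rng.integers(0, len(core), size=5):
            core[int(j)] = "ACGT"[int(rng.integers(4))]
        t = "".join(rng.choice(list("ACGT"), size=start)) + "".join(core)
        t += "".join(rng.choice(list("ACGT"), size=max(0, m - len(t))))
    else:
        t = "".join(rng.choice(list("ACGT"), size=m))
    score, qs, qe, ts, te, matches, aln_len = smith_waterman(q, t)
    assert score == int(_pairwise_oracle(q, t))
    assert 0 <= qs <= qe <= len(q) and 0 <= ts <= te <= len(t)
    assert matches <= aln_len


def test_smith_waterman_exact_substring():
    t = "ACGTACGTGGCCAATTCCGGAACGT"
    q = t[4:20]
    score, qs, qe, ts, te, matches, aln_len = smith_waterman(q, t)
    assert score == len(q) == matches == aln_len
    assert (qs, qe, ts, te) == (0, 16, 4, 20)


def test_unique_contig_alignment(small_reference):
    """A 500 bp copy of a unique reference substring aligns to exactly one
    locus at 100% identity with E below threshold."""
    chrom = small_reference.chromosome_names[0]
    seq = small_reference.sequences[chrom][7000:7500]
    alns = align_contigs({"c": seq}, small_reference.sequences)
    assert len(alns) == 1
    a = alns[0]
    assert (a.target, a.target_start, a.target_end) == (chrom, 7000, 7500)
    assert a.percent_identity == 100.0
    assert a.e_value <= 1e-10
    assert a.contig_start == 0 and a.contig_end == 500


def test_novel_contig_no_hit(small_reference):
    rng = np.random.default_rng(5)
    novel = "".join(rng.choice(list("ACGT"), size=500))
    assert align_contigs({"c": novel}, small_reference.sequences) == []


def test_e_value_monotone_in_score():
    assert e_value(50, 500, 1_000_000) > e_value(100, 500, 1_000_000)
    assert e_value(30, 500, 1_000_000) >= 0


def test_empty_reference_rejected():
    with pytest.raises(ValueError):
        ReferenceIndex({})


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def test_classification_partition(small_reference):
    contigs, truth = simulate_contigs(small_reference, ContigSimSpec(seed=9))
    alns = align_contigs(contigs, small_reference.sequences)
    reports = classify_contigs(
        alns, {c: len(s) for c, s in contigs.items()},
        small_reference.chromosome_names, small_reference.unanchored_names,
    )
    counts = classification_counts(reports)
    assert (
        counts["unique"] + counts["multi"] + counts["unanchored"] + counts["no_hit"]
        == counts["total"] == len(contigs)
    )
    expected = {"unique": "unique", "repeat": "multi", "unanchored": "unanchored",
                "novel": "no_hit"}
    for r in reports:
        assert r.classification == expected[truth[r.contig_id]["class"]]
        if r.classification == "unique":
            assert r.unique_fraction == pytest.approx(1.0)
            assert r.fraction_bin == "80-100"


def test_partial_alignment_fraction_bin():
    a = ContigAlignment("c", "chr01", 100, 350, 0, 250, 99.0, 240, 1e-40)
    reports = classify_contigs([a], {"c": 500}, ["chr01"])
    assert reports[0].unique_fraction == pytest.approx(0.5)
    assert reports[0].fraction_bin == "40-60"


# ---------------------------------------------------------------------------
# Depth-0 regions and rescue
# ---------------------------------------------------------------------------


def test_depth_zero_runs():
    arr = np.ones(1000)
    assert depth_zero_regions(DepthTrack({"chr01": arr})) == []
    arr[100:400] = 0  # 300 bp
    arr[600:750] = 0  # 150 bp
    arr[900:950] = 0  # 50 bp, below min_run
    got = depth_zero_regions(DepthTrack({"chr01": arr}), min_run=100)
    assert got == [("chr01", 100, 400), ("chr01", 600, 750)]
    # brute-force scan oracle on random data
    rng = np.random.default_rng(8)
    arr = (rng.random(2000) < 0.7).astype(int)
    got = depth_zero_regions(DepthTrack({"chr01": arr}), min_run=3)
    for c, s, e in got:
        assert (arr[s:e] == 0).all()
        assert s == 0 or arr[s - 1] != 0
        assert e == len(arr) or arr[e] != 0
        assert e - s >= 3


def test_find_newly_mapped_trivial_empty():
    assert find_newly_mapped([], [], [], []) == ([], [])


def test_planted_rescue_scenario():
    """A gene inside an uncovered segment is recovered by the contig copied
    from that segment, and only that gene."""
    spec = GenomeSpec(
        chromosome_lengths=[60_000], unanchored_lengths=[], gene_count=8,
        repeat_segment_count=0, novel_insertion_spec=[], seed=60,
    )
    ref = generate_reference(spec)
    target_gene = ref.genes[3]
    gs, ge = target_gene.span
    region = (target_gene.chromosome, max(0, gs - 200), ge + 200)
    donor, truth = plant_variants(
        ref.sequences, VariantSpec(snp_per_mb=100, seed=61)
    )
    aln, unmapped = simulate_alignments(
        donor, ref.sequences, truth,
        ReadSimConfig(read_length=74, target_depth=25, seed=62),
        uncovered_regions=[region],
    )
    track = depth_track(aln, ref.chromosome_lengths())
    zero = depth_zero_regions(track, min_run=100)
    contigs, _ = simulate_contigs(
        ref,
        ContigSimSpec(
            unique_count=2, repeat_count=0, unanchored_count=0, novel_count=1,
            from_intervals=[region], seed=63,
        ),
    )
    alns = align_contigs(contigs, ref.sequences)
    reports = classify_contigs(
        alns, {c: len(s) for c, s in contigs.items()},
        ref.chromosome_names, ref.unanchored_names,
    )
    nm_contigs, nm_genes = find_newly_mapped(reports, alns, zero, ref.genes)
    assert nm_genes == [target_gene.gene_id]
    assert len(nm_contigs) == 1
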