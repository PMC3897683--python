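"""IO round-trips and the pileup/depth engines against brute-force oracles."""

import numpy as np
import pytest

from reseqlens.formats import (
    AlignedRead,
    GeneModel,
    Transcript,
    build_pileup,
    depth_track,
    parse_gene_models,
    read_fasta,
    read_sam,
    write_fasta,
    write_gene_models,
    write_sam,
)

from conftest import make_read


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def test_gff3_coordinate_conversion(tmp_path):
    """A single-exon gene with CDS 1..300 (+) parses to interval [0, 300)."""
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t1\t300\t.\t+\t.\tID=g1\n"
        "chr1\tsrc\tmRNA\t1\t300\t.\t+\t.\tID=g1.1;Parent=g1\n"
        "chr1\tsrc\texon\t1\t300\t.\t+\t.\tParent=g1.1\n"
        "chr1\tsrc\tCDS\t1\t300\t.\t+\t0\tParent=g1.1\n"
    )
    models = parse_gene_models(str(gff))
    assert len(models) == 1
    assert models[0].transcripts[0].cds_segments == [(0, 300, 0)]
    assert models[0].strand == "+"


def test_gff3_minus_strand_segments_in_genomic_order(tmp_path):
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t1\t500\t.\t-\t.\tID=g1\n"
        "chr1\tsrc\tmRNA\t1\t500\t.\t-\t.\tID=g1.1;Parent=g1\n"
        "chr1\tsrc\texon\t1\t120\t.\t-\t.\tParent=g1.1\n"
        "chr1\tsrc\texon\t301\t500\t.\t-\t.\tParent=g1.1\n"
        "chr1\tsrc\tCDS\t1\t100\t.\t-\t1\tParent=g1.1\n"
        "chr1\tsrc\tCDS\t301\t500\t.\t-\t0\tParent=g1.1\n"
    )
    models = parse_gene_models(str(gff))
    segs = models[0].transcripts[0].cds_segments
    assert segs == [(0, 100, 1), (300, 500, 0)]  # genomic order, phase kept
    assert models[0].strand == "-"


def test_gff3_bad_cds_length_names_gene(tmp_path):
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t1\t100\t.\t+\t.\tID=badgene\n"
        "chr1\tsrc\tmRNA\t1\t100\t.\t+\t.\tID=badgene.1;Parent=badgene\n"
        "chr1\tsrc\texon\t1\t100\t.\t+\t.\tParent=badgene.1\n"
        "chr1\tsrc\tCDS\t1\t100\t.\t+\t0\tParent=badgene.1\n"
    )
    with pytest.raises(ValueError, match="badgene"):
        parse_gene_models(str(gff))


def test_gene_models_roundtrip(tmp_path, small_reference):
    path = tmp_path / "models.gff3"
    write_gene_models(small_reference.genes, str(path))
    parsed = parse_gene_models(str(path))
    assert parsed == sorted(
        small_reference.genes, key=lambda g: (g.chromosome, g.span[0], g.gene_id)
    )


# ---------------------------------------------------------------------------
# FASTA / SAM round trips
# ---------------------------------------------------------------------------


def test_fasta_roundtrip(tmp_path, small_reference):
    path = tmp_path / "ref.fa"
    write_fasta(small_reference.sequences, str(path))
    assert read_fasta(str(path)) == small_reference.sequences


def test_sam_roundtrip(tmp_path):
    reads = [
        make_read("chr1", 10, "ACGTACGTAC", read_id="a"),
        make_read("chr1", 20, "ACGTACGTAC", read_id="b", uniqueness="multiple"),
        make_read(
            "chr1", 30, "ACGTACGTAC", cigar="4M2I4M", read_id="c",
            qualities=[30, 31, 32, 33, 34, 35, 36, 37, 38, 39],
        ),
    ]
    path = tmp_path / "a.sam"
    write_sam(reads, {"chr1": 1000}, str(path))
    back = read_sam(str(path))
    assert [r.read_id for r in back] == ["a", "b", "c"]
    assert back[1].uniqueness == "multiple"
    assert back[2].cigar == "4M2I4M"
    assert np.array_equal(back[2].base_qualities, reads[2].base_qualities)


# ---------------------------------------------------------------------------
# Pileup and depth
# ---------------------------------------------------------------------------


def _brute_force_pileup(reads, refseq, minq=30):
    """Independent per-position tally walking each CIGAR by hand."""
    import re

    raw = {}
    counts = {}
    for r in reads:
        if r.uniqueness != "unique":
            continue
        refpos, qpos = r.start, 0
        for n, op in [(int(x), o) for x, o in re.findall(r"(\d+)(\D)", r.cigar)]:
            if op == "M":
                for i in range(n):
                    raw[refpos + i] = raw.get(refpos + i, 0) + 1
                    if r.base_qualities[qpos + i] >= minq:
                        key = (refpos + i, r.sequence[qpos + i])
                        counts[key] = counts.get(key, 0) + 1
                refpos += n
                qpos += n
            elif op == "D":
                for i in range(n):
                    raw[refpos + i] = raw.get(refpos + i, 0) + 1
                refpos += n
            elif op in "IS":
                qpos += n
    return raw, counts


def test_single_read_depth_span():
    refseq = {"chr1": "A" * 300}
    reads = [make_read("chr1", 100, "A" * 50)]
    track = depth_track(reads, {"chr1": 300})
    assert track["chr1"][99] == 0
    assert (track["chr1"][100:150] == 1).all()
    assert track["chr1"][150] == 0
    cols = list(build_pileup(reads, refseq))
    assert len(cols) == 50 and all(c.raw_depth == 1 for c in cols)


def test_pileup_matches_brute_force():
    rng = np.random.default_rng(5)
    refseq = "".join(rng.choice(list("ACGT"), size=500))
    reads = []
    for i in range(80):
        start = int(rng.integers(0, 440))
        L = int(rng.integers(20, 60))
        seq = "".join(rng.choice(list("ACGT"), size=L))
        quals = rng.integers(20, 41, size=L)
        cigar = f"{L}M"
        if i % 7 == 0 and L > 20:  # some reads with indels
            cigar = f"10M2D{L - 10}M" if i % 2 else f"10M3I{L - 13}M"
        reads.append(
            make_read("chr1", start, seq, cigar=cigar, qualities=quals, read_id=f"r{i}")
        )
    reads.sort(key=lambda r: r.start)
    raw_oracle, count_oracle = _brute_force_pileup(reads, refseq)
    cols = {c.position: c for c in build_pileup(reads, {"chr1": refseq})}
    assert set(cols) == set(raw_oracle)
    for pos, col in cols.items():
        assert col.raw_depth == raw_oracle[pos]
        for b, n in col.base_counts.items():
            assert n == count_oracle.get((pos, b), 0)
        assert sum(col.base_counts.values()) == col.filtered_depth
        assert col.filtered_depth <= col.raw_depth


def test_quality_threshold_edge():
    """A base at quality 29 counts in raw depth but not filtered depth."""
    refseq = {"chr1": "ACGT" * 10}
    r1 = make_read("chr1", 0, "ACGT", quality=29)
    r2 = make_read("chr1", 0, "ACGT", quality=30)
    cols = {c.position: c for c in build_pileup([r1, r2], refseq)}
    assert cols[0].raw_depth == 2
    assert cols[0].filtered_depth == 1


def test_depth_track_oracle_and_conservation():
    rng = np.random.default_rng(9)
    reads = []
    for i in range(60):
        start = int(rng.integers(0, 900))
        L = int(rng.integers(30, 80))
        reads.append(make_read("chr1", start, "A" * L, read_id=f"r{i}"))
    reads.sort(key=lambda r: r.start)
    track = depth_track(reads, {"chr1": 1000})
    brute = np.zeros(1000, dtype=int)
    for r in reads:
        brute[r.start : r.end] += 1
    assert np.array_equal(track["chr1"], brute)
    assert track["chr1"].sum() == sum(r.reference_length for r in reads)


def test_deletion_covers_depth_insertion_does_not():
    refseq = {"chr1": "ACGTACGTACGTACGTACGT"}
    rdel = make_read("chr1", 0, "ACGTACGT", cigar="4M4D4M")
    rins = make_read("chr1", 0, "ACGTTTACGT", cigar="4M2I4M")
    t = depth_track([rdel], {"chr1": 20})
    assert (t["chr1"][:12] == 1).all()  # deleted span still covered
    t = depth_track([rins], {"chr1": 20})
    assert (t["chr1"][:8] == 1).all() and t["chr1"][8] == 0


def test_multimapped_reads_excluded():
    reads = [make_read("chr1", 0, "AAAA", uniqueness="multiple")]
    track = depth_track(reads, {"chr1": 10})
    assert track["chr1"].sum() == 0
    assert list(build_pileup(reads, {"chr1": "A" * 10})) == []


def test_unsorted_alignments_rejected():
    reads = [make_read("chr1", 50, "AAAA"), make_read("chr1", 10, "AAAA")]
    with pytest.raises(ValueError, match="sorted"):
        depth_track(reads, {"chr1": 100})


def test_indel_anchoring():
    """Insertions anchor at the base before; deletions at the first deleted base."""
    refseq = {"chr1": "ACGTACGTACGTACGTACGT"}
    rins = make_read("chr1", 2, "GTAAACGT", cigar="2M3I3M")
    rdel = make_read("chr1", 2, "GTGTAC", cigar="2M2D4M")
    cols = {c.position: c for c in build_pileup([rins, rdel], refseq)}
    assert cols[3].indel_observations == {("insertion", "AAA"): 1}
    assert cols[4].indel_observations == {("deletion", "AC"): 1}


def test_gene_model_invariants_enforced():
    with pytest.raises(ValueError, match="divisible by 3"):
        GeneModel(
            "g", "chr1", "+",
            [Transcript("t", [(0, 100)], [(0, 100, 0)])],
        ).validate()
    with pytest.raises(ValueError, match="outside exons"):
        GeneModel(
            "g", "chr1", "+",
            [Transcript("t", [(0, 50)], [(0, 99, 0)])],
        ).validate()
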