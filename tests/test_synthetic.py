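"""Generator invariants: determinism, edit-replay, densities, read placement."""

import numpy as np
import pytest

from reseqlens.formats import read_fasta, write_fasta, write_gene_models
from reseqlens.simulate import (
    ContigSimSpec,
    GenomeSpec,
    GenomeSizingError,
    ReadSimConfig,
    TruthVariant,
    TruthVariantSet,
    VariantSpec,
    generate_reference,
    plant_variants,
    simulate_alignments,
    simulate_contigs,
)


def _replay_oracle(reference, records):
    """Independent edit replay: apply records right-to-left with string slicing."""
    donor = {}
    for chrom, seq in reference.items():
        s = seq
        for r in sorted(
            (r for r in records if r.chromosome == chrom),
            key=lambda r: -r.position,
        ):
            if r.type == "SNP":
                s = s[: r.position] + r.alt + s[r.position + 1 :]
            elif r.type == "insertion":
                s = s[: r.position + 1] + r.alt[1:] + s[r.position + 1 :]
            else:
                s = s[: r.position + 1] + s[r.position + len(r.ref) :]
        donor[chrom] = s
    return donor


def test_degenerate_reference():
    """One 1,000 bp chromosome, no genes: a single record, no gene models."""
    ref = generate_reference(
        GenomeSpec(
            chromosome_lengths=[1000], unanchored_lengths=[], gene_count=0,
            repeat_segment_count=0, novel_insertion_spec=[], seed=0,
        )
    )
    assert list(ref.sequences) == ["chr01"]
    assert len(ref.sequences["chr01"]) == 1000
    assert ref.genes == []


def test_gene_placement_and_cds_phasing():
    ref = generate_reference(
        GenomeSpec(
            chromosome_lengths=[20_000, 20_000], unanchored_lengths=[],
            gene_count=10, repeat_segment_count=0, novel_insertion_spec=[],
            seed=3,
        )
    )
    assert len(ref.genes) == 10
    for g in ref.genes:
        g.validate()
        for t in g.transcripts:
            assert t.cds_length() % 3 == 0


def test_gene_count_infeasible():
    with pytest.raises(GenomeSizingError):
        generate_reference(
            GenomeSpec(
                chromosome_lengths=[2000], unanchored_lengths=[], gene_count=50,
                repeat_segment_count=0, novel_insertion_spec=[], seed=0,
            )
        )


def test_reference_determinism(tmp_path):
    spec = dict(
        chromosome_lengths=[20_000], unanchored_lengths=[5_000], gene_count=6,
        repeat_segment_count=1, seed=17,
    )
    paths = []
    for run in range(2):
        ref = generate_reference(GenomeSpec(**spec))
        fa = tmp_path / f"ref{run}.fa"
        gff = tmp_path / f"ref{run}.gff3"
        write_fasta(ref.sequences, str(fa))
        write_gene_models(ref.genes, str(gff))
        paths.append((fa.read_bytes(), gff.read_bytes()))
    assert paths[0] == paths[1]


def test_repeats_are_exact_duplications():
    ref = generate_reference(
        GenomeSpec(
            chromosome_lengths=[30_000, 30_000], unanchored_lengths=[],
            gene_count=8, repeat_segment_count=2, seed=4,
        )
    )
    assert len(ref.repeats) == 4  # two copies per segment
    for k in range(2):
        (c1, s1, e1), (c2, s2, e2) = ref.repeats[2 * k], ref.repeats[2 * k + 1]
        assert ref.sequences[c1][s1:e1] == ref.sequences[c2][s2:e2]


def test_plant_zero_rates_identity():
    ref = {"chr01": "ACGT" * 2500}
    donor, truth = plant_variants(
        ref, VariantSpec(snp_per_mb=0, insertion_per_mb=0, deletion_per_mb=0, seed=0)
    )
    assert donor == ref and len(truth) == 0


def test_edit_replay_oracle():
    """Replaying the truth set reproduces the donor byte-for-byte."""
    rng = np.random.default_rng(8)
    ref = {"chr01": "".join(rng.choice(list("ACGT"), size=50_000))}
    donor, truth = plant_variants(
        ref, VariantSpec(snp_per_mb=800, insertion_per_mb=100, deletion_per_mb=100, seed=9)
    )
    assert _replay_oracle(ref, truth.records) == donor
    for r in truth:
        if r.type == "SNP":
            assert r.alt != r.ref
        assert ref["chr01"][r.position : r.position + len(r.ref)] == r.ref


def test_planted_window_densities_within_poisson_bounds():
    ref = generate_reference(
        GenomeSpec(
            chromosome_lengths=[1_000_000], unanchored_lengths=[], gene_count=0,
            repeat_segment_count=0, novel_insertion_spec=[], seed=1,
        )
    )
    rate = 400.0
    _, truth = plant_variants(ref.sequences, VariantSpec(snp_per_mb=rate, seed=2))
    hist = np.zeros(10)
    for r in truth.by_type("SNP"):
        hist[r.position // 100_000] += 1
    expected = rate / 10  # per 100 kb window
    sigma = np.sqrt(expected)
    assert (np.abs(hist - expected) <= 3 * sigma + 1).all()


def test_truth_tsv_roundtrip(tmp_path):
    recs = [
        TruthVariant("chr01", 5, "A", "T", "SNP"),
        TruthVariant("chr01", 9, "C", "CGG", "insertion", novel=True),
    ]
    path = tmp_path / "truth.tsv"
    TruthVariantSet(recs).write_tsv(str(path))
    assert TruthVariantSet.read_tsv(str(path)).records == sorted(
        recs, key=lambda r: (r.chromosome, r.position)
    )


def test_zero_depth_no_reads():
    ref = {"chr01": "ACGT" * 100}
    donor, truth = plant_variants(ref, VariantSpec(snp_per_mb=0, insertion_per_mb=0, deletion_per_mb=0))
    aln, unmapped = simulate_alignments(
        donor, ref, truth, ReadSimConfig(read_length=36, target_depth=0, seed=0)
    )
    assert aln == [] and unmapped == []


def test_simulated_depth_matches_target():
    """At error 0 and 20x on 10 kb, brute-force mean depth is within 3 SE."""
    rng = np.random.default_rng(12)
    ref = {"chr01": "".join(rng.choice(list("ACGT"), size=10_000))}
    donor, truth = plant_variants(ref, VariantSpec(snp_per_mb=100, seed=13))
    aln, _ = simulate_alignments(
        donor, ref, truth, ReadSimConfig(read_length=50, target_depth=20, seed=14)
    )
    depth = np.zeros(10_000)
    for r in aln:
        depth[r.start : r.end] += 1
    se = depth.std() / np.sqrt(len(depth) / 50)  # ~independent per read length
    assert abs(depth.mean() - 20) < 3 * se + 0.5


def test_novel_insertion_reads_unmapped():
    """Reads from inside a novel insertion go to FASTQ and share no 31-mer
    with the reference."""
    rng = np.random.default_rng(20)
    ref = {"chr01": "".join(rng.choice(list("ACGT"), size=20_000))}
    donor, truth = plant_variants(
        ref,
        VariantSpec(snp_per_mb=0, insertion_per_mb=0, deletion_per_mb=0, seed=21),
        novel_insertion_spec=[(2000, 1)],
    )
    aln, unmapped = simulate_alignments(
        donor, ref, truth, ReadSimConfig(read_length=74, target_depth=15, seed=22)
    )
    assert len(unmapped) > 0
    ref_kmers = {ref["chr01"][i : i + 31] for i in range(len(ref["chr01"]) - 30)}
    novel = truth.records[0]
    ins_start = novel.position + 1
    ins_seq = novel.alt[1:]
    # fully-inside reads: no 31-mer shared with the reference
    inside = [s for _, s, _ in unmapped if s in ins_seq]
    assert inside, "expected reads sampled wholly inside the insertion"
    for seq in inside:
        assert all(seq[i : i + 31] not in ref_kmers for i in range(len(seq) - 30))
    # and no SAM read claims the insertion's bases as reference-consuming
    sam_ids = {r.read_id for r in aln}
    assert not any(rid in sam_ids for rid, _, _ in unmapped)


def test_repeat_reads_flagged_multimapped():
    ref = generate_reference(
        GenomeSpec(
            chromosome_lengths=[30_000], unanchored_lengths=[], gene_count=4,
            repeat_segment_count=1, repeat_length=500, novel_insertion_spec=[],
            seed=30,
        )
    )
    donor, truth = plant_variants(
        ref.sequences, VariantSpec(snp_per_mb=0, insertion_per_mb=0, deletion_per_mb=0)
    )
    aln, _ = simulate_alignments(
        donor, ref.sequences, truth,
        ReadSimConfig(read_length=74, target_depth=20, seed=31),
        repeats=ref.repeats,
    )
    multi = [r for r in aln if r.uniqueness == "multiple"]
    assert multi
    for r in multi:
        assert any(
            s <= r.start and r.end <= e for c, s, e in ref.repeats if c == r.chromosome
        )


def test_uncovered_regions_divert_reads():
    rng = np.random.default_rng(40)
    ref = {"chr01": "".join(rng.choice(list("ACGT"), size=20_000))}
    donor, truth = plant_variants(
        ref, VariantSpec(snp_per_mb=0, insertion_per_mb=0, deletion_per_mb=0)
    )
    aln, unmapped = simulate_alignments(
        donor, ref, truth,
        ReadSimConfig(read_length=74, target_depth=20, seed=41),
        uncovered_regions=[("chr01", 5000, 8000)],
    )
    depth = np.zeros(20_000)
    for r in aln:
        depth[r.start : r.end] += 1
    assert depth[5100:7900].sum() == 0
    assert len(unmapped) > 0


def test_paired_mode_emits_complete_pairs():
    ref = {"chr01": "ACGT" * 5000}
    donor, truth = plant_variants(ref, VariantSpec(snp_per_mb=100, seed=1))
    aln, _ = simulate_alignments(
        donor, ref, truth,
        ReadSimConfig(read_length=50, target_depth=10, paired=True, seed=2),
    )
    from collections import Counter

    pairs = Counter(r.read_id.split("/")[0] for r in aln)
    assert all(v == 2 for v in pairs.values())
    assert sum(r.is_reverse for r in aln) == len(aln) // 2
    depth = np.zeros(20_000)
    for r in aln:
        depth[r.start : r.end] += 1
    assert abs(depth.mean() - 10) < 0.5


def test_contig_simulation_classes_and_determinism(small_reference):
    spec = ContigSimSpec(seed=50)
    contigs1, truth1 = simulate_contigs(small_reference, spec)
    contigs2, _ = simulate_contigs(small_reference, ContigSimSpec(seed=50))
    assert contigs1 == contigs2
    chrom_seqs = {
        c: small_reference.sequences[c] for c in small_reference.chromosome_names
    }
    for cid, info in truth1.items():
        seq = contigs1[cid]
        if info["class"] == "unique":
            # exhaustive substring search: exactly one chromosomal locus
            occurrences = sum(s.count(seq) for s in chrom_seqs.values())
            assert occurrences == 1
        elif info["class"] == "novel":
            assert all(seq not in s for s in small_reference.sequences.values())
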