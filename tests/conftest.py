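import numpy as np
import pytest

from reseqlens.formats import AlignedRead
from reseqlens.simulate import (
    GenomeSpec,
    ReadSimConfig,
    VariantSpec,
    generate_reference,
    plant_variants,
    simulate_alignments,
)


def make_read(
    chrom: str,
    start: int,
    sequence: str,
    cigar: str = None,
    quality: int = 35,
    read_id: str = "r",
    uniqueness: str = "unique",
    qualities=None,
) -> AlignedRead:
    """Construct an aligned read with uniform (or explicit) base qualities."""
    quals = (
        np.asarray(qualities, dtype=np.uint8)
        if qualities is not None
        else np.full(len(sequence), quality, dtype=np.uint8)
    )
    return AlignedRead(
        read_id=read_id,
        chromosome=chrom,
        start=start,
        cigar=cigar or f"{len(sequence)}M",
        sequence=sequence,
        base_qualities=quals,
        uniqueness=uniqueness,
    )


@pytest.fixture(scope="session")
def small_reference():
    """A 2-chromosome 60 kb reference with genes, repeats and a scaffold."""
    spec = GenomeSpec(
        chromosome_lengths=[60_000, 60_000],
        unanchored_lengths=[20_000],
        gene_count=24,
        repeat_segment_count=2,
        novel_insertion_spec=[(2000, 1)],
        seed=11,
    )
    return generate_reference(spec)


@pytest.fixture(scope="session")
def called_study():
    """One simulated error-free sample: reference, truth, alignments."""
    spec = GenomeSpec(
        chromosome_lengths=[80_000],
        unanchored_lengths=[],
        gene_count=10,
        repeat_segment_count=0,
        novel_insertion_spec=[],
        seed=21,
    )
    ref = generate_reference(spec)
    donor, truth = plant_variants(
        ref.sequences, VariantSpec(snp_per_mb=400.0, seed=22)
    )
    alignments, unmapped = simulate_alignments(
        donor,
        ref.sequences,
        truth,
        ReadSimConfig(read_length=74, target_depth=30.0, seed=23),
    )
    return ref, truth, alignments, unmapped
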