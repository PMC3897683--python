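"""End-to-end orchestration of a synthetic resequencing study.

``run_all`` drives every stage with one seed: generate a reference with
gene models, plant per-sample variants, simulate reads, call and annotate
variants, compare per-megabase densities across samples, and run the
unmapped-read contig rescue. Outputs are TSV tables (mapping summary,
gene-coverage bins, per-chromosome counts, annotation classes, contig
classes, newly mapped counts), VCFs, BEDs and a JSON run manifest that
echoes every threshold and input checksum. Partition identities are
asserted before any table is written; a violation is a hard error naming
the table.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from reseqlens import __version__
from reseqlens.annotate import (
    GeneIndex,
    annotate_variant,
    count_classes,
    summarize_annotation_counts,
    AnnotationSummary,
)
from reseqlens.calling import (
    FilterConfig,
    call_variants_from_alignments,
    validate_against_truth,
    write_rejected_log,
    write_vcf,
)
from reseqlens.coverage import (
    bin_genes_by_coverage,
    cds_coverage,
    coverage_summary,
    realized_depth,
    saturation_curve,
)
from reseqlens.density import (
    chromosome_table,
    density_floor_report,
    fold_difference_regions,
    regions_to_bed,
    shared_high_density_regions,
    window_counts,
    write_window_table,
)
from reseqlens.formats import (
    depth_track,
    write_bed,
    write_fasta,
    write_fastq,
    write_gene_models,
    write_sam,
)
from reseqlens.rescue import (
    classification_counts,
    classify_contigs,
    contig_stats,
    depth_zero_regions,
    find_newly_mapped,
    trim_and_filter_reads,
)
from reseqlens.seedalign import ReferenceIndex, align_contigs
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


@dataclass
class RunConfig:
    """Configuration for a full synthetic run (documented key-value schema).

    ``sample_snp_per_mb`` gives one SNP density per sample; cross-sample
    stages need at least two samples. ``hotspot_windows`` are (chromosome,
    window index) pairs planted above ``high_density_threshold`` in every
    sample; ``uncovered_segment_count`` reference segments per sample are
    excluded from read mapping to exercise the rescue stage.
    """

    out_dir: str = "reseqlens_run"
    seed: int = 0
    chromosome_lengths: List[int] = field(default_factory=lambda: [400_000, 400_000])
    unanchored_lengths: List[int] = field(default_factory=lambda: [60_000])
    gene_count: int = 150
    sample_snp_per_mb: Dict[str, float] = field(
        default_factory=lambda: {"sampleA": 300.0, "sampleB": 250.0}
    )
    insertion_per_mb: float = 40.0
    deletion_per_mb: float = 45.0
    novel_insertion_spec: Optional[List[Tuple[int, int]]] = None  # None -> genome default
    hotspot_windows: List[Tuple[str, int]] = field(default_factory=list)
    hotspot_snp_per_mb: float = 700.0
    uncovered_segment_count: int = 2
    uncovered_segment_length: int = 3000
    read_length: int = 74
    target_depth: float = 25.0
    base_error_rate: float = 0.002
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    saturation_depths: List[float] = field(default_factory=lambda: [5.0, 10.0, 20.0])
    window_size: int = 100_000
    high_density_threshold: int = 50
    fold_threshold: float = 5.0
    min_window_count: int = 50
    density_floor: int = 50
    e_value_max: float = 1e-10
    min_unique_fraction: float = 0.8
    min_zero_run: int = 100
    trim_length: int = 50
    trim_min_quality: int = 20

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "filter_config" in raw:
            raw["filter_config"] = FilterConfig(**raw["filter_config"])
        if "hotspot_windows" in raw:
            raw["hotspot_windows"] = [tuple(x) for x in raw["hotspot_windows"]]
        return cls(**raw)


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def make_summary_tables(
    out_dir: str,
    bin_tables: Dict[str, List],
    annotation_counts: pd.DataFrame,
    indel_annotation_counts: Optional[pd.DataFrame],
    chrom_table: pd.DataFrame,
    contig_class_counts: Dict[str, Dict[str, int]],
    newly_mapped: Dict[str, Tuple[int, int]],
    total_genes: int,
) -> AnnotationSummary:
    """Assert partition identities, then write the analogue tables.

    Raises ``ValueError`` naming the offending table on any violation:
    gene-coverage bins must sum to the gene count, annotation classes must
    nest exactly (intergenic + genic = total; intron + UTRs + CDS = genic;
    for SNPs synonymous + nonsynonymous = CDS), contig classes must
    partition the contig set, and chromosome-table totals must equal the
    per-chromosome sums.
    """
    for sample, bins in bin_tables.items():
        if sum(b.gene_count for b in bins) != total_genes:
            raise ValueError(
                f"gene-coverage bin table ({sample}): bins sum to "
                f"{sum(b.gene_count for b in bins)}, expected {total_genes}"
            )
    pd.DataFrame(
        {s: {b.label: b.gene_count for b in bins} for s, bins in bin_tables.items()}
    ).to_csv(os.path.join(out_dir, "gene_coverage_bins.tsv"), sep="\t")

    for sample in annotation_counts.columns:
        col = annotation_counts[sample]
        if col["synonymous"] + col["nonsynonymous"] != col["CDS"]:
            raise ValueError(
                f"annotation table ({sample}): synonymous + nonsynonymous != CDS SNPs"
            )
    summary = summarize_annotation_counts(annotation_counts)  # checks nesting
    annotation_counts.to_csv(os.path.join(out_dir, "snp_annotation_classes.tsv"), sep="\t")
    if indel_annotation_counts is not None:
        summarize_annotation_counts(indel_annotation_counts)
        indel_annotation_counts.to_csv(
            os.path.join(out_dir, "indel_annotation_classes.tsv"), sep="\t"
        )

    for sample in chrom_table.columns:
        for vtype in ("SNP", "insertion", "deletion"):
            block = chrom_table[sample].loc[vtype]
            if block.drop("Total").sum() != block["Total"]:
                raise ValueError(
                    f"chromosome table ({sample}, {vtype}): total mismatch"
                )
    chrom_table.to_csv(os.path.join(out_dir, "chromosome_counts.tsv"), sep="\t")

    rows = {}
    for sample, counts in contig_class_counts.items():
        parts = counts["unique"] + counts["multi"] + counts["unanchored"] + counts["no_hit"]
        if parts != counts["total"]:
            raise ValueError(f"contig class table ({sample}): classes do not partition")
        rows[sample] = counts
    pd.DataFrame(rows).T.to_csv(os.path.join(out_dir, "contig_classes.tsv"), sep="\t")

    pd.DataFrame(
        {s: {"newly_mapped_contigs": nm, "newly_covered_genes": ng}
         for s, (nm, ng) in newly_mapped.items()}
    ).T.to_csv(os.path.join(out_dir, "newly_mapped.tsv"), sep="\t")
    return summary


def run_all(config: RunConfig) -> Dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    samples = list(config.sample_snp_per_mb)
    if len(samples) < 2:
        raise ValueError("cross-sample stages need at least 2 samples")
    os.makedirs(config.out_dir, exist_ok=True)

    gspec = GenomeSpec(
        chromosome_lengths=list(config.chromosome_lengths),
        unanchored_lengths=list(config.unanchored_lengths),
        gene_count=config.gene_count,
        seed=config.seed,
    )
    reference = generate_reference(gspec)
    chrom_lengths = reference.chromosome_lengths()
    ref_fa = os.path.join(config.out_dir, "reference.fa")
    ref_gff = os.path.join(config.out_dir, "genes.gff3")
    write_fasta(reference.sequences, ref_fa)
    write_gene_models(reference.genes, ref_gff)
    index = GeneIndex(reference.genes)

    # uncovered segments: per sample, gene-containing reference intervals
    # whose reads will fail to map
    gene_spans = [(g.chromosome, *g.span) for g in reference.genes]
    manifest: Dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "min_depth": config.filter_config.min_depth,
            "min_base_quality": config.filter_config.min_base_quality,
            "snp_call_rate": config.filter_config.snp_call_rate,
            "indel_call_rate": config.filter_config.indel_call_rate,
            "high_density_threshold": config.high_density_threshold,
            "fold_threshold": config.fold_threshold,
            "density_floor": config.density_floor,
            "e_value_max": config.e_value_max,
            "min_unique_fraction": config.min_unique_fraction,
            "min_zero_run": config.min_zero_run,
            "window_size": config.window_size,
            "read_length": config.read_length,
            "target_depth": config.target_depth,
            "base_error_rate": config.base_error_rate,
            "trim_length": config.trim_length,
            "trim_min_quality": config.trim_min_quality,
        },
        "inputs": {},
        "samples": {},
    }
    manifest["inputs"]["reference.fa"] = _checksum(ref_fa)
    manifest["inputs"]["genes.gff3"] = _checksum(ref_gff)

    per_sample_calls: Dict[str, List] = {}
    bin_tables: Dict[str, List] = {}
    snp_ann_counts: Dict[str, Dict[str, int]] = {}
    indel_ann_counts: Dict[str, Dict[str, int]] = {}
    contig_class_counts: Dict[str, Dict[str, int]] = {}
    newly_mapped_counts: Dict[str, Tuple[int, int]] = {}
    wcounts = []
    ref_index = ReferenceIndex(reference.sequences)

    for si, sample in enumerate(samples):
        sdir = os.path.join(config.out_dir, sample)
        os.makedirs(sdir, exist_ok=True)
        sseed = (config.seed * 9973 + 7919 * (si + 1)) % (2**31)
        vspec = VariantSpec(
            snp_per_mb=config.sample_snp_per_mb[sample],
            insertion_per_mb=config.insertion_per_mb,
            deletion_per_mb=config.deletion_per_mb,
            snp_per_mb_windows={
                (c, w): config.hotspot_snp_per_mb for c, w in config.hotspot_windows
            },
            window_size=config.window_size,
            seed=sseed,
        )
        novel_spec = (
            config.novel_insertion_spec
            if config.novel_insertion_spec is not None
            else gspec.novel_insertion_spec
        )
        donor, truth = plant_variants(
            reference.sequences, vspec, novel_insertion_spec=novel_spec
        )
        truth.write_tsv(os.path.join(sdir, "truth.tsv"))

        srng = np.random.default_rng(sseed + 1)
        uncovered: List[Tuple[str, int, int]] = []
        if config.uncovered_segment_count and gene_spans:
            picks = srng.choice(
                len(gene_spans), size=config.uncovered_segment_count, replace=False
            )
            for pi in picks:
                c, gs, ge = gene_spans[int(pi)]
                mid = (gs + ge) // 2
                half = config.uncovered_segment_length // 2
                lo = max(0, mid - half)
                hi = min(chrom_lengths[c], mid + half)
                uncovered.append((c, lo, hi))
        cfg = ReadSimConfig(
            read_length=config.read_length,
            target_depth=config.target_depth,
            base_error_rate=config.base_error_rate,
            seed=sseed + 2,
        )
        alignments, unmapped = simulate_alignments(
            donor, reference.sequences, truth, cfg,
            repeats=reference.repeats, uncovered_regions=uncovered,
        )
        write_sam(alignments, chrom_lengths, os.path.join(sdir, "alignments.sam"))
        write_fastq(unmapped, os.path.join(sdir, "unmapped.fastq"))

        track = depth_track(alignments, chrom_lengths)
        cov = coverage_summary(track, chromosomes=reference.chromosome_names)
        fractions = {g.gene_id: cds_coverage(track, g) for g in reference.genes}
        bin_tables[sample] = bin_genes_by_coverage(fractions)

        calls, rejected = call_variants_from_alignments(
            alignments, reference.sequences, config.filter_config
        )
        write_vcf(calls, chrom_lengths, sample, os.path.join(sdir, "calls.vcf"))
        write_rejected_log(rejected, os.path.join(sdir, "rejected.tsv"))
        validation = validate_against_truth(calls, truth, reference.sequences)
        per_sample_calls[sample] = calls

        annotations = [
            annotate_variant(c, index, reference.sequences) for c in calls
        ]
        snp_ann_counts[sample] = count_classes(
            [a for a in annotations if a.variant.type == "SNP"]
        )
        indel_ann_counts[sample] = count_classes(
            [a for a in annotations if a.variant.type != "SNP"]
        )

        chrom_name_set = set(reference.chromosome_names)
        wcounts.append(
            window_counts(
                [c for c in calls
                 if c.type == "SNP" and c.chromosome in chrom_name_set],
                {c: chrom_lengths[c] for c in reference.chromosome_names},
                config.window_size,
                sample,
            )
        )
        write_window_table(wcounts[-1], os.path.join(sdir, "snp_windows.tsv"))

        # rescue: trim/QC unmapped reads, simulate an assembly over the
        # uncovered segments plus background classes, align and classify
        kept, pass_rate = trim_and_filter_reads(
            [(r, s, q) for r, s, q in unmapped],
            config.trim_length,
            config.trim_min_quality,
        )
        zero = depth_zero_regions(track, config.min_zero_run)
        cspec = ContigSimSpec(
            from_intervals=[
                (c, s, e) for c, s, e in uncovered
            ],
            seed=sseed + 3,
        )
        contigs, _ = simulate_contigs(reference, cspec)
        write_fasta(contigs, os.path.join(sdir, "contigs.fa"))
        stats = contig_stats(contigs)
        contig_alns = align_contigs(
            contigs, reference.sequences, config.e_value_max, index=ref_index
        )
        reports = classify_contigs(
            contig_alns,
            {cid: len(s) for cid, s in contigs.items()},
            reference.chromosome_names,
            reference.unanchored_names,
        )
        contig_class_counts[sample] = classification_counts(reports)
        nm_contigs, nm_genes = find_newly_mapped(
            reports, contig_alns, zero, reference.genes, config.min_unique_fraction
        )
        newly_mapped_counts[sample] = (len(nm_contigs), len(nm_genes))
        write_bed(zero, os.path.join(sdir, "depth_zero.bed"))

        manifest["samples"][sample] = {
            "seed": sseed,
            "n_truth": len(truth),
            "n_calls": len(calls),
            "precision": validation.precision,
            "recall": validation.recall,
            "mapped_nucleotides": cov.mapped_nucleotides,
            "genome_coverage_ge5_pct": round(cov.genome_coverage_ge5, 3),
            "average_depth": round(cov.average_depth, 2),
            "unmapped_reads": len(unmapped),
            "unmapped_pass_rate": round(pass_rate, 4),
            "contig_n50": stats.n50,
            "newly_mapped_contigs": len(nm_contigs),
            "newly_covered_genes": len(nm_genes),
        }

    # saturation curve on the first sample
    first = samples[0]
    first_sam = os.path.join(config.out_dir, first, "alignments.sam")
    from reseqlens.formats import read_sam

    aln0 = read_sam(first_sam)
    genome_len = sum(chrom_lengths.values())
    depths = [d for d in config.saturation_depths
              if d <= realized_depth(aln0, genome_len)]
    curve = saturation_curve(
        aln0, reference.genes, depths, chrom_lengths, seed=config.seed
    )
    with open(os.path.join(config.out_dir, "saturation_curve.tsv"), "w") as fh:
        fh.write("#depth\tgenes_cds90\n")
        for d in sorted(curve):
            fh.write(f"{d}\t{curve[d]}\n")
    manifest["saturation_curve"] = {str(d): int(n) for d, n in sorted(curve.items())}

    # cross-sample density stages
    shared = shared_high_density_regions(wcounts, config.high_density_threshold)
    write_bed(regions_to_bed(shared), os.path.join(config.out_dir, "shared_high_density.bed"))
    folds = fold_difference_regions(
        wcounts[0], wcounts[1], config.fold_threshold, config.min_window_count
    )
    write_bed(regions_to_bed(folds), os.path.join(config.out_dir, "fold_difference.bed"))
    floor_report = density_floor_report(wcounts, config.density_floor)
    manifest["density"] = {
        "shared_high_density_regions": len(shared),
        "fold_difference_regions": len(folds),
        "windows_below_floor_any": len(floor_report.below_floor_any),
        "windows_below_floor_all": len(floor_report.below_floor_all),
    }

    chrom_tbl = chromosome_table(per_sample_calls, reference.chromosome_names)
    summary = make_summary_tables(
        config.out_dir,
        bin_tables,
        pd.DataFrame(snp_ann_counts).reindex(AnnotationSummary.ROWS),
        pd.DataFrame(indel_ann_counts).reindex(AnnotationSummary.ROWS),
        chrom_tbl,
        contig_class_counts,
        newly_mapped_counts,
        total_genes=len(reference.genes),
    )
    manifest["annotation_mean_sd"] = {
        k: [round(v[0], 3), round(v[1], 3)] for k, v in summary.mean_sd.items()
    }

    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
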