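"""Assignment of aligned reads to per-gene exon/intron features.

Each retained read is assigned to at most one (gene, feature-class) pair:
overlap base-counts are accumulated per (gene, class) over all aligned
blocks, a read touching more than one gene is ambiguous, and otherwise the
class with the larger overlap wins (ties go to exon, so 1-bp boundary
jitter never inflates the intron signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .catalog import FeatureCatalog

EXON = "exon"
INTRON = "intron"


@dataclass
class AlignmentRecord:
    """A single aligned read reduced to what counting needs."""

    read_id: str
    chrom: str
    strand: str  # '+' or '-'
    blocks: list[tuple[int, int]]  # sorted, non-overlapping, 0-based half-open
    mapq: int = 255
    hit_count: int | None = None  # NH tag when present


@dataclass
class CountingConfig:
    """Counting behaviour.

    strandedness : {'reverse', 'forward', 'unstranded'}
        'reverse' (dUTP-style libraries): a read counts for genes on the
        opposite strand. Unstranded catalog features match any read.
    unique_only : bool
        Discard reads with hit_count > 1 (or, when the aligner reports no
        hit count, mapq below ``mapq_min``).
    """

    strandedness: str = "reverse"
    unique_only: bool = True
    mapq_min: int = 20

    def __post_init__(self) -> None:
        if self.strandedness not in ("reverse", "forward", "unstranded"):
            raise ValueError(f"unknown strandedness {self.strandedness!r}")


@dataclass
class CountingSummary:
    """Per-sample read dispositions; the six categories sum to ``total``."""

    total: int = 0
    discarded_non_unique: int = 0
    discarded_low_mapq: int = 0
    assigned_exon: int = 0
    assigned_intron: int = 0
    ambiguous_multi_gene: int = 0
    unassigned_no_feature: int = 0
    missing_chromosomes: set = field(default_factory=set)

    def check(self) -> None:
        parts = (
            self.discarded_non_unique
            + self.discarded_low_mapq
            + self.assigned_exon
            + self.assigned_intron
            + self.ambiguous_multi_gene
            + self.unassigned_no_feature
        )
        if parts != self.total:
            raise AssertionError(
                f"disposition counts {parts} != total records {self.total}"
            )


def _strand_compatible(read_strand: str, feature_strand: str, mode: str) -> bool:
    if mode == "unstranded" or feature_strand == ".":
        return True
    if mode == "forward":
        return read_strand == feature_strand
    return read_strand != feature_strand  # reverse


def build_feature_index(catalog: FeatureCatalog) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees with (gene_id, class, strand) payloads."""
    trees: dict[str, IntervalTree] = {}
    for cls, segmap in ((EXON, catalog.exon_segments), (INTRON, catalog.intron_segments)):
        for gid, segs in segmap.items():
            for iv in segs:
                trees.setdefault(iv.chrom, IntervalTree()).addi(
                    iv.start, iv.end, (gid, cls, iv.strand)
                )
    return trees


def resolve_read_class(
    overlaps: dict[tuple[str, str], int],
) -> tuple[str, str | None, str | None]:
    """Turn per-(gene, class) overlap base-counts into a disposition.

    Returns ``(disposition, gene_id, feature_class)`` where disposition is
    one of 'assigned_exon', 'assigned_intron', 'ambiguous_multi_gene',
    'unassigned_no_feature'.
    """
    overlaps = {k: v for k, v in overlaps.items() if v > 0}
    genes = {gid for gid, _cls in overlaps}
    if not genes:
        return "unassigned_no_feature", None, None
    if len(genes) > 1:
        return "ambiguous_multi_gene", None, None
    gid = genes.pop()
    exon_bp = overlaps.get((gid, EXON), 0)
    intron_bp = overlaps.get((gid, INTRON), 0)
    cls = EXON if exon_bp >= intron_bp else INTRON
    return f"assigned_{cls}", gid, cls


def count_sample(
    alignments: Iterable[AlignmentRecord],
    catalog: FeatureCatalog,
    config: CountingConfig | None = None,
    index: dict[str, IntervalTree] | None = None,
) -> tuple[dict[str, int], dict[str, int], CountingSummary]:
    """Count one sample's alignments into per-gene exon/intron tallies."""
    config = config or CountingConfig()
    trees = index if index is not None else build_feature_index(catalog)
    exon_counts: dict[str, int] = {}
    intron_counts: dict[str, int] = {}
    summary = CountingSummary()

    for rec in alignments:
        summary.total += 1
        if config.unique_only:
            if rec.hit_count is not None:
                if rec.hit_count > 1:
                    summary.discarded_non_unique += 1
                    continue
            elif rec.mapq < config.mapq_min:
                summary.discarded_low_mapq += 1
                continue
        tree = trees.get(rec.chrom)
        if tree is None:
            if rec.chrom not in summary.missing_chromosomes and rec.chrom:
                summary.missing_chromosomes.add(rec.chrom)
            summary.unassigned_no_feature += 1
            continue
        overlaps: dict[tuple[str, str], int] = {}
        for bs, be in rec.blocks:
            for hit in tree.overlap(bs, be):
                gid, cls, fstrand = hit.data
                if not _strand_compatible(rec.strand, fstrand, config.strandedness):
                    continue
                bp = min(be, hit.end) - max(bs, hit.begin)
                if bp > 0:
                    overlaps[(gid, cls)] = overlaps.get((gid, cls), 0) + bp
        disposition, gid, cls = resolve_read_class(overlaps)
        setattr(summary, disposition, getattr(summary, disposition) + 1)
        if cls == EXON:
            exon_counts[gid] = exon_counts.get(gid, 0) + 1
        elif cls == INTRON:
            intron_counts[gid] = intron_counts.get(gid, 0) + 1

    summary.check()
    return exon_counts, intron_counts, summary


def iter_sam(path_or_text: str) -> Iterator[AlignmentRecord]:
    """Yield AlignmentRecords from a SAM/BAM file path via pysam.

    Unmapped, secondary and supplementary records are yielded with empty
    block lists so they land in ``unassigned_no_feature`` (secondary and
    supplementary alignments never represent an extra sequenced read).
    """
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(path_or_text, check_sq=False) as sam:
            for read in sam:
                if read.is_secondary or read.is_supplementary:
                    continue
                if read.is_unmapped:
                    yield AlignmentRecord(read.query_name, "", "+", [], 0, None)
                    continue
                nh = read.get_tag("NH") if read.has_tag("NH") else None
                yield AlignmentRecord(
                    read_id=read.query_name,
                    chrom=read.reference_name,
                    strand="-" if read.is_reverse else "+",
                    blocks=[(int(s), int(e)) for s, e in read.get_blocks()],
                    mapq=read.mapping_quality,
                    hit_count=int(nh) if nh is not None else None,
                )
    finally:
        pysam.set_verbosity(save)


def count_reads(
    sample_alignments: dict[str, Iterable[AlignmentRecord]],
    catalog: FeatureCatalog,
    config: CountingConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, CountingSummary]]:
    """Count reads for several samples against one catalog.

    Parameters
    ----------
    sample_alignments : mapping sample_id -> iterable of AlignmentRecord
        Use :func:`iter_sam` to stream from SAM/BAM files.

    Returns
    -------
    (exon_table, intron_table, summaries)
        Count tables are gene × sample integer DataFrames covering every
        catalog gene (zeros where nothing was assigned).
    """
    config = config or CountingConfig()
    index = build_feature_index(catalog)
    genes = catalog.gene_ids
    samples = list(sample_alignments)
    exon_tab = pd.DataFrame(0, index=genes, columns=samples, dtype=int)
    intron_tab = pd.DataFrame(0, index=genes, columns=samples, dtype=int)
    summaries: dict[str, CountingSummary] = {}
    for sid, alns in sample_alignments.items():
        ec, ic, summary = count_sample(alns, catalog, config, index=index)
        for gid, n in ec.items():
            exon_tab.loc[gid, sid] = n
        for gid, n in ic.items():
            intron_tab.loc[gid, sid] = n
        summaries[sid] = summary
    exon_tab.index.name = "gene_id"
    intron_tab.index.name = "gene_id"
    return exon_tab, intron_tab, summaries


def write_counts(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t")


def read_counts(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_summaries(summaries: dict[str, CountingSummary], path: str) -> None:
    rows = []
    for sid, s in summaries.items():
        rows.append(
            {
                "sample_id": sid,
                "total": s.total,
                "discarded_non_unique": s.discarded_non_unique,
                "discarded_low_mapq": s.discarded_low_mapq,
                "assigned_exon": s.assigned_exon,
                "assigned_intron": s.assigned_intron,
                "ambiguous_multi_gene": s.ambiguous_multi_gene,
                "unassigned_no_feature": s.unassigned_no_feature,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
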