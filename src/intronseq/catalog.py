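"""Gene-model parsing and construction of disjoint exon/intron catalogs.

The intron-signal analysis needs, for every gene, a set of exon segments
(the union of all isoforms' exons) and a set of intron segments (gene span
minus that union).  Because intron-mapping reads are the evidence for
nascent transcription, an intronic base must never be exonic anywhere else
in the genome: after the per-gene flattening, every intron segment is
purged of any region that overlaps ANY gene's exon segment.  Exon segments
take precedence and are never trimmed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils

from .intervals import GenomicInterval, merge_spans, subtract_spans, total_length

logger = logging.getLogger(__name__)

_TRANSCRIPT_TYPES = {"mRNA", "transcript"}


class GFF3ParseError(ValueError):
    """Raised when a GFF3 line cannot be interpreted."""


class OrphanFeatureError(ValueError):
    """Raised when an exon carries no Parent attribute."""


@dataclass
class TranscriptModel:
    """One isoform: an ordered list of exon intervals on a single strand."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        chroms = {e.chrom for e in self.exons}
        if len(chroms) > 1:
            raise ValueError(
                f"transcript {self.transcript_id} spans chromosomes {chroms}"
            )


@dataclass
class GeneModel:
    """A gene with its isoforms and the flattened (union) exon structure."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel]

    @property
    def span(self) -> GenomicInterval:
        start = min(e.start for t in self.transcripts for e in t.exons)
        end = max(e.end for t in self.transcripts for e in t.exons)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def exon_union(self) -> list[tuple[int, int]]:
        return merge_spans(
            (e.start, e.end) for t in self.transcripts for e in t.exons
        )

    @property
    def exon_count(self) -> int:
        return len(self.exon_union)


@dataclass
class FeatureCatalog:
    """Genome-wide disjoint exon and intron segments, keyed by gene.

    Invariants (enforced by :func:`build_feature_catalog`):

    * per-gene segment lists are sorted, merged and non-adjacent;
    * no base is covered by both an exon segment and an intron segment,
      across all genes (exon precedence);
    * intron segments lie within their gene's span;
    * single-exon genes have no intron segments.
    """

    exon_segments: dict[str, list[GenomicInterval]]
    intron_segments: dict[str, list[GenomicInterval]]
    exon_counts: dict[str, int]
    provenance: str = ""

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.exon_segments)

    def gene_strand(self, gene_id: str) -> str:
        segs = self.exon_segments.get(gene_id) or self.intron_segments.get(gene_id)
        return segs[0].strand if segs else "."

    def gene_chrom(self, gene_id: str) -> str:
        segs = self.exon_segments.get(gene_id) or self.intron_segments.get(gene_id)
        return segs[0].chrom if segs else ""


def _validate_gff3_line(line: str, lineno: int) -> None:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 9:
        raise GFF3ParseError(
            f"line {lineno}: expected 9 tab-separated columns, got {len(fields)}"
        )
    attrs = fields[8]
    for part in attrs.rstrip(";").split(";"):
        part = part.strip()
        if part and "=" not in part:
            raise GFF3ParseError(
                f"line {lineno}: malformed attribute {part!r} (missing '=')"
            )


def _parse_attrs(attrs: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attrs.rstrip(";").split(";"):
        part = part.strip()
        if part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def parse_gene_models(source: str) -> list[GeneModel]:
    """Parse gene/transcript/exon models from GFF3 text or a file path.

    GFF3's 1-based closed coordinates are converted to the internal 0-based
    half-open convention here and nowhere else.  Exons lacking a ``Parent``
    attribute raise :class:`OrphanFeatureError`; exons whose parent
    transcript is absent from the file are reported via the module logger
    and skipped.

    Parameters
    ----------
    source : str
        GFF3 text (contains a newline) or a path to a GFF3 file.

    Returns
    -------
    list of GeneModel, sorted by gene id.
    """
    if "\n" in source or source.lstrip().startswith("##gff"):
        text = source
    else:
        with open(source) as fh:
            text = fh.read()

    # Pre-validate so errors carry line numbers; gffutils then resolves the
    # gene/transcript hierarchy.
    rows: list[tuple[int, list[str]]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        _validate_gff3_line(line, lineno)
        rows.append((lineno, line.split("\t")))

    try:
        db = gffutils.create_db(
            text,
            dbfn=":memory:",
            from_string=True,
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # pragma: no cover - gffutils wraps many causes
        raise GFF3ParseError(f"gffutils failed to build feature store: {exc}") from exc

    gene_strand: dict[str, str] = {}
    gene_chrom: dict[str, str] = {}
    for g in db.features_of_type("gene"):
        gene_strand[g.id] = g.strand if g.strand in ("+", "-") else "."
        gene_chrom[g.id] = g.seqid

    tx_gene: dict[str, str] = {}
    tx_order: list[str] = []
    for ttype in sorted(_TRANSCRIPT_TYPES):
        for t in db.features_of_type(ttype):
            parents = t.attributes.get("Parent", [])
            if not parents:
                logger.warning("transcript %s has no Parent gene; skipped", t.id)
                continue
            tx_gene[t.id] = parents[0]
            tx_order.append(t.id)

    tx_exons: dict[str, list[GenomicInterval]] = {t: [] for t in tx_gene}
    unknown_parents: set[str] = set()
    for lineno, fields in rows:
        if fields[2] != "exon":
            continue
        attrs = _parse_attrs(fields[8])
        if "Parent" not in attrs:
            raise OrphanFeatureError(f"line {lineno}: exon has no Parent attribute")
        chrom, strand = fields[0], fields[6]
        start1, end1 = int(fields[3]), int(fields[4])
        iv = GenomicInterval(chrom, start1 - 1, end1,
                             strand if strand in ("+", "-") else ".")
        for parent in attrs["Parent"].split(","):
            if parent in tx_exons:
                tx_exons[parent].append(iv)
            else:
                unknown_parents.add(parent)
    if unknown_parents:
        logger.warning(
            "exons referenced %d unknown parent(s): %s",
            len(unknown_parents), ", ".join(sorted(unknown_parents)[:10]),
        )

    genes: dict[str, GeneModel] = {}
    for tid in tx_order:
        gid = tx_gene[tid]
        exons = tx_exons[tid]
        if not exons:
            logger.warning("transcript %s has no exons; skipped", tid)
            continue
        model = TranscriptModel(tid, gid, exons)
        if gid not in genes:
            genes[gid] = GeneModel(
                gene_id=gid,
                chrom=gene_chrom.get(gid, exons[0].chrom),
                strand=gene_strand.get(gid, exons[0].strand),
                transcripts=[],
            )
        genes[gid].transcripts.append(model)

    return [genes[g] for g in sorted(genes)]


def build_feature_catalog(
    genes: list[GeneModel],
    strand_aware: bool = False,
    min_segment_length: int = 1,
    provenance: str = "",
) -> FeatureCatalog:
    """Flatten gene models into globally disjoint exon/intron segments.

    Per gene, exon segments are the merged union of all isoform exons and
    intron segments are the gene span minus that union (so an exon skipped
    by one isoform is still exonic).  Then genome-wide, every intron region
    overlapping any gene's exon segment is trimmed away, so that no base is
    simultaneously exonic and intronic anywhere.  With ``strand_aware`` the
    purge only considers exons on the same strand as the intron's gene.

    Segments shorter than ``min_segment_length`` are dropped after purging.
    """
    per_gene_exons: dict[str, list[tuple[int, int]]] = {}
    per_gene_introns: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    exon_counts: dict[str, int] = {}

    for gene in genes:
        union = gene.exon_union
        span = gene.span
        per_gene_exons[gene.gene_id] = union
        per_gene_introns[gene.gene_id] = subtract_spans(
            [(span.start, span.end)], union
        )
        meta[gene.gene_id] = (gene.chrom, gene.strand)
        exon_counts[gene.gene_id] = len(union)

    # Genome-wide exon mask per chromosome (optionally per strand).
    def _mask_key(chrom: str, strand: str) -> tuple:
        return (chrom, strand) if strand_aware else (chrom,)

    exon_mask: dict[tuple, list[tuple[int, int]]] = {}
    for gid, spans in per_gene_exons.items():
        chrom, strand = meta[gid]
        key = _mask_key(chrom, strand)
        exon_mask.setdefault(key, []).extend(spans)
    exon_mask = {k: merge_spans(v) for k, v in exon_mask.items()}

    exon_segments: dict[str, list[GenomicInterval]] = {}
    intron_segments: dict[str, list[GenomicInterval]] = {}
    for gid in per_gene_exons:
        chrom, strand = meta[gid]
        exon_segments[gid] = [
            GenomicInterval(chrom, s, e, strand)
            for s, e in per_gene_exons[gid]
            if e - s >= min_segment_length
        ]
        purged = subtract_spans(
            per_gene_introns[gid], exon_mask.get(_mask_key(chrom, strand), [])
        )
        intron_segments[gid] = [
            GenomicInterval(chrom, s, e, strand)
            for s, e in purged
            if e - s >= min_segment_length
        ]

    return FeatureCatalog(
        exon_segments=exon_segments,
        intron_segments=intron_segments,
        exon_counts=exon_counts,
        provenance=provenance,
    )


def write_catalog(catalog: FeatureCatalog, out_prefix: str) -> tuple[str, str]:
    """Write the catalog as 6-column BED plus a per-gene TSV sidecar.

    BED names encode ``gene_id|exon`` / ``gene_id|intron``; the sidecar
    carries gene_id, exon_count and total exon/intron bp.  Returns the two
    paths written.
    """
    bed_path = f"{out_prefix}.catalog.bed"
    tsv_path = f"{out_prefix}.catalog_genes.tsv"
    with open(bed_path, "w") as bed:
        for gid in catalog.gene_ids:
            for cls, segs in (
                ("exon", catalog.exon_segments[gid]),
                ("intron", catalog.intron_segments.get(gid, [])),
            ):
                for iv in segs:
                    bed.write(
                        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{gid}|{cls}\t0\t"
                        f"{iv.strand if iv.strand != '.' else '.'}\n"
                    )
    with open(tsv_path, "w") as tsv:
        tsv.write("gene_id\texon_count\ttotal_exon_bp\ttotal_intron_bp\n")
        for gid in catalog.gene_ids:
            ebp = total_length((iv.start, iv.end) for iv in catalog.exon_segments[gid])
            ibp = total_length(
                (iv.start, iv.end) for iv in catalog.intron_segments.get(gid, [])
            )
            tsv.write(f"{gid}\t{catalog.exon_counts[gid]}\t{ebp}\t{ibp}\n")
    return bed_path, tsv_path


def read_catalog(prefix: str) -> FeatureCatalog:
    """Read a catalog written by :func:`write_catalog`."""
    exon_segments: dict[str, list[GenomicInterval]] = {}
    intron_segments: dict[str, list[GenomicInterval]] = {}
    with open(f"{prefix}.catalog.bed") as bed:
        for line in bed:
            chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")
            gid, cls = name.rsplit("|", 1)
            iv = GenomicInterval(chrom, int(start), int(end), strand)
            target = exon_segments if cls == "exon" else intron_segments
            target.setdefault(gid, []).append(iv)
    exon_counts: dict[str, int] = {}
    with open(f"{prefix}.catalog_genes.tsv") as tsv:
        next(tsv)
        for line in tsv:
            gid, n, _ebp, _ibp = line.rstrip("\n").split("\t")
            exon_counts[gid] = int(n)
            exon_segments.setdefault(gid, [])
            intron_segments.setdefault(gid, [])
    for gid in exon_segments:
        intron_segments.setdefault(gid, [])
    return FeatureCatalog(exon_segments, intron_segments, exon_counts,
                          provenance=f"read from {prefix}")
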