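"""Catalog construction: coordinate conventions, flattening, global purge."""

import logging

import pytest

import intronseq as iq
from intronseq.catalog import GFF3ParseError, OrphanFeatureError

GFF_ONE_GENE = """##gff-version 3
chr1\tsrc\tgene\t100\t500\t.\t+\t.\tID=g1
chr1\tsrc\tmRNA\t100\t500\t.\t+\t.\tID=g1.t1;Parent=g1
chr1\tsrc\texon\t100\t200\t.\t+\t.\tID=e1;Parent=g1.t1
chr1\tsrc\texon\t400\t500\t.\t+\t.\tID=e2;Parent=g1.t1
"""

GFF_TWO_ISOFORMS = """##gff-version 3
chr1\tsrc\tgene\t100\t900\t.\t+\t.\tID=g1
chr1\tsrc\tmRNA\t100\t900\t.\t+\t.\tID=g1.t1;Parent=g1
chr1\tsrc\texon\t100\t200\t.\t+\t.\tParent=g1.t1
chr1\tsrc\texon\t301\t350\t.\t+\t.\tParent=g1.t1
chr1\tsrc\texon\t700\t900\t.\t+\t.\tParent=g1.t1
chr1\tsrc\tmRNA\t100\t900\t.\t+\t.\tID=g1.t2;Parent=g1
chr1\tsrc\texon\t100\t200\t.\t+\t.\tParent=g1.t2
chr1\tsrc\texon\t700\t900\t.\t+\t.\tParent=g1.t2
"""

GFF_NESTED = """##gff-version 3
chr1\tsrc\tgene\t100\t500\t.\t+\t.\tID=gA
chr1\tsrc\tmRNA\t100\t500\t.\t+\t.\tID=gA.t1;Parent=gA
chr1\tsrc\texon\t100\t200\t.\t+\t.\tParent=gA.t1
chr1\tsrc\texon\t400\t500\t.\t+\t.\tParent=gA.t1
chr1\tsrc\tgene\t251\t300\t.\t-\t.\tID=gB
chr1\tsrc\tmRNA\t251\t300\t.\t-\t.\tID=gB.t1;Parent=gB
chr1\tsrc\texon\t251\t300\t.\t-\t.\tParent=gB.t1
"""


def spans(segs):
    return [(iv.start, iv.end) for iv in segs]


def test_gff3_coordinates_convert_to_half_open():
    genes = iq.parse_gene_models(GFF_ONE_GENE)
    assert len(genes) == 1
    g = genes[0]
    assert (g.span.start, g.span.end) == (99, 500)
    assert g.exon_union == [(99, 200), (399, 500)]
    catalog = iq.build_feature_catalog(genes)
    assert spans(catalog.intron_segments["g1"]) == [(200, 399)]


def test_two_isoforms_make_one_gene_two_transcripts():
    genes = iq.parse_gene_models(GFF_TWO_ISOFORMS)
    assert len(genes) == 1
    assert len(genes[0].transcripts) == 2
    # the exon skipped by isoform t2 stays exonic (union), never intronic
    catalog = iq.build_feature_catalog(genes)
    assert (300, 350) in spans(catalog.exon_segments["g1"])
    for s, e in spans(catalog.intron_segments["g1"]):
        assert not (s < 350 and 300 < e)


def test_nested_gene_splits_host_intron():
    catalog = iq.build_feature_catalog(iq.parse_gene_models(GFF_NESTED))
    assert spans(catalog.intron_segments["gA"]) == [(200, 250), (300, 399)]
    assert catalog.intron_segments["gB"] == []
    assert catalog.exon_counts["gB"] == 1


def test_stranded_purge_keeps_opposite_strand_intron():
    catalog = iq.build_feature_catalog(
        iq.parse_gene_models(GFF_NESTED), strand_aware=True
    )
    # gB is on the minus strand, so gA's intron survives intact
    assert spans(catalog.intron_segments["gA"]) == [(200, 399)]


def test_malformed_attribute_reports_line_number():
    bad = GFF_ONE_GENE.replace("ID=e2;Parent=g1.t1", "broken attribute")
    with pytest.raises(GFF3ParseError, match="line 5"):
        iq.parse_gene_models(bad)


def test_exon_without_parent_is_an_error():
    bad = GFF_ONE_GENE.replace("ID=e2;Parent=g1.t1", "ID=e2")
    with pytest.raises(OrphanFeatureError):
        iq.parse_gene_models(bad)


def test_unknown_parent_is_reported_not_fatal(caplog):
    extra = GFF_ONE_GENE + "chr1\tsrc\texon\t600\t650\t.\t+\t.\tParent=ghost\n"
    with caplog.at_level(logging.WARNING, logger="intronseq.catalog"):
        genes = iq.parse_gene_models(extra)
    assert len(genes) == 1
    assert any("unknown parent" in rec.message for rec in caplog.records)


def test_simulated_gene_count_round_trips(small_config, small_dataset):
    assert len(small_dataset["genes"]) == small_config.n_genes


def per_base_label(genes, strand_aware=False):
    """Brute-force oracle: label every base exon/intron per gene, then purge
    intron bases that are exonic for ANY gene (optionally same-strand)."""
    exon_bases, intron_bases = {}, {}
    global_exon = set()
    for g in genes:
        ebases = {
            (g.chrom, b) for s, e in g.exon_union for b in range(s, e)
        }
        exon_bases[g.gene_id] = ebases
        span = g.span
        intron_bases[g.gene_id] = {
            (g.chrom, b) for b in range(span.start, span.end)
        } - ebases
        key = {(c, b, g.strand) for c, b in ebases} if strand_aware else ebases
        global_exon |= key
    for g in genes:
        if strand_aware:
            purge = {
                (c, b) for c, b, s in global_exon if s == g.strand
            }
        else:
            purge = global_exon
        intron_bases[g.gene_id] -= purge
    return exon_bases, intron_bases


def catalog_bases(segmap):
    return {
        gid: {(iv.chrom, b) for iv in segs for b in range(iv.start, iv.end)}
        for gid, segs in segmap.items()
    }


@pytest.mark.parametrize("strand_aware", [False, True])
def test_catalog_equals_per_base_oracle_on_random_genomes(strand_aware):
    for seed in range(20):
        cfg = iq.SimulationConfig(
            n_genes=12, seed=seed, exon_len_range=(20, 80),
            intron_len_range=(30, 200), gap_range=(40, 200),
            genes_per_chrom=6, nesting_rate=0.4, isoform_rate=0.4,
        )
        gff3, _ = iq.simulate_annotation(cfg)
        genes = iq.parse_gene_models(gff3)
        catalog = iq.build_feature_catalog(genes, strand_aware=strand_aware)
        oracle_ex, oracle_in = per_base_label(genes, strand_aware)
        assert catalog_bases(catalog.exon_segments) == oracle_ex
        assert catalog_bases(catalog.intron_segments) == oracle_in


def test_catalog_invariants_and_idempotence(small_dataset):
    catalog = small_dataset["catalog"]
    for gid in catalog.gene_ids:
        segs = catalog.exon_segments[gid] + catalog.intron_segments[gid]
        ordered = sorted(spans(catalog.exon_segments[gid]))
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            assert e1 < s2  # merged, non-adjacent
        if catalog.exon_counts[gid] == 1:
            assert catalog.intron_segments[gid] == []
        span = (
            min(iv.start for iv in segs),
            max(iv.end for iv in segs),
        )
        for iv in catalog.intron_segments[gid]:
            assert span[0] <= iv.start and iv.end <= span[1]
    # rebuilding from the catalog's own exon segments reproduces it
    models = [
        iq.GeneModel(
            gene_id=gid,
            chrom=catalog.gene_chrom(gid),
            strand=catalog.gene_strand(gid),
            transcripts=[
                iq.TranscriptModel(f"{gid}.t1", gid, list(catalog.exon_segments[gid]))
            ],
        )
        for gid in catalog.gene_ids
    ]
    rebuilt = iq.build_feature_catalog(models)
    assert catalog_bases(rebuilt.exon_segments) == catalog_bases(catalog.exon_segments)
    assert catalog_bases(rebuilt.intron_segments) == catalog_bases(
        catalog.intron_segments
    )


def test_catalog_round_trips_through_bed(tmp_path, small_dataset):
    catalog = small_dataset["catalog"]
    prefix = str(tmp_path / "cat")
    iq.write_catalog(catalog, prefix)
    loaded = iq.read_catalog(prefix)
    assert loaded.exon_counts == catalog.exon_counts
    assert catalog_bases(loaded.exon_segments) == catalog_bases(catalog.exon_segments)
    assert catalog_bases(loaded.intron_segments) == catalog_bases(
        catalog.intron_segments
    )


def test_empty_input_gives_empty_catalog():
    catalog = iq.build_feature_catalog([])
    assert catalog.gene_ids == []
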