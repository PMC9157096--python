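"""Read-to-feature assignment: majority rule, conservation, strand modes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import intronseq as iq
from intronseq.counting import EXON, INTRON, build_feature_index, count_sample


@pytest.fixture(scope="module")
def toy_catalog():
    gff = """##gff-version 3
chr1\tsrc\tgene\t101\t1000\t.\t+\t.\tID=G
chr1\tsrc\tmRNA\t101\t1000\t.\t+\t.\tID=G.t1;Parent=G
chr1\tsrc\texon\t101\t300\t.\t+\t.\tParent=G.t1
chr1\tsrc\texon\t701\t1000\t.\t+\t.\tParent=G.t1
chr1\tsrc\tgene\t2001\t2500\t.\t-\t.\tID=H
chr1\tsrc\tmRNA\t2001\t2500\t.\t-\t.\tID=H.t1;Parent=H
chr1\tsrc\texon\t2001\t2500\t.\t-\t.\tParent=H.t1
"""
    return iq.build_feature_catalog(iq.parse_gene_models(gff))


def read(chrom, blocks, strand="-", mapq=60, nh=1, name="r"):
    return iq.AlignmentRecord(name, chrom, strand, blocks, mapq, nh)


def run(catalog, reads, **cfg):
    return count_sample(reads, catalog, iq.CountingConfig(**cfg))


def test_read_inside_intron_counts_for_intron(toy_catalog):
    # G is '+', library is reverse-stranded, so a '-' read counts for G
    ec, ic, s = run(toy_catalog, [read("chr1", [(400, 500)])])
    assert ic == {"G": 1} and ec == {}
    assert s.assigned_intron == 1


def test_majority_overlap_and_exon_tie_break(toy_catalog):
    # 80 bp on exon, 20 bp on intron -> exon
    ec, ic, _ = run(toy_catalog, [read("chr1", [(220, 320)])])
    assert ec == {"G": 1} and ic == {}
    # 50/50 split -> exon by tie-break
    ec, ic, _ = run(toy_catalog, [read("chr1", [(250, 350)])])
    assert ec == {"G": 1} and ic == {}
    # 20 bp on exon, 80 bp on intron -> intron
    ec, ic, _ = run(toy_catalog, [read("chr1", [(280, 380)])])
    assert ic == {"G": 1} and ec == {}


def test_junction_read_blocks_sum_per_class(toy_catalog):
    # gapped read: both blocks exonic -> exon, one count only
    ec, ic, s = run(
        toy_catalog, [read("chr1", [(150, 250), (750, 850)], name="gapped")]
    )
    assert ec == {"G": 1} and s.assigned_exon == 1


def test_read_touching_two_genes_is_ambiguous():
    gff = """##gff-version 3
chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=A
chr1\tsrc\tmRNA\t101\t200\t.\t+\t.\tID=A.t1;Parent=A
chr1\tsrc\texon\t101\t200\t.\t+\t.\tParent=A.t1
chr1\tsrc\tgene\t151\t400\t.\t+\t.\tID=B
chr1\tsrc\tmRNA\t151\t400\t.\t+\t.\tID=B.t1;Parent=B
chr1\tsrc\texon\t151\t400\t.\t+\t.\tParent=B.t1
"""
    catalog = iq.build_feature_catalog(iq.parse_gene_models(gff))
    ec, ic, s = run(catalog, [read("chr1", [(140, 240)])])
    assert s.ambiguous_multi_gene == 1 and ec == {} and ic == {}


def test_strandedness_modes(toy_catalog):
    r_plus = read("chr1", [(400, 500)], strand="+")
    for mode, expect in (("reverse", 0), ("forward", 1), ("unstranded", 1)):
        _, ic, _ = run(toy_catalog, [r_plus], strandedness=mode)
        assert ic.get("G", 0) == expect, mode


def test_strand_flip_leaves_counts_unchanged(toy_catalog):
    reads = [
        read("chr1", [(400, 500)], strand="-"),
        read("chr1", [(150, 250)], strand="-"),
        read("chr1", [(2100, 2200)], strand="+"),
    ]
    flipped = [
        iq.AlignmentRecord(r.read_id, r.chrom, "+" if r.strand == "-" else "-",
                           r.blocks, r.mapq, r.hit_count)
        for r in reads
    ]
    ec1, ic1, _ = run(toy_catalog, reads, strandedness="reverse")
    ec2, ic2, _ = run(toy_catalog, flipped, strandedness="forward")
    assert ec1 == ec2 and ic1 == ic2


def test_unique_filters(toy_catalog):
    reads = [
        read("chr1", [(400, 500)], nh=3, name="multi"),
        iq.AlignmentRecord("lowq", "chr1", "-", [(400, 500)], mapq=5, hit_count=None),
        read("chr1", [(400, 500)], name="good"),
    ]
    _, ic, s = run(toy_catalog, reads)
    assert s.discarded_non_unique == 1
    assert s.discarded_low_mapq == 1
    assert ic == {"G": 1}
    # with the filter off everything is assigned
    _, ic, s = run(toy_catalog, reads, unique_only=False)
    assert ic == {"G": 3} and s.discarded_non_unique == 0


def test_missing_chromosome_reported_once(toy_catalog):
    reads = [read("chrX", [(10, 50)], name=f"r{i}") for i in range(3)]
    _, _, s = run(toy_catalog, reads)
    assert s.unassigned_no_feature == 3
    assert s.missing_chromosomes == {"chrX"}


@settings(deadline=None, derandomize=True, max_examples=200)
@given(
    blocks=st.lists(
        st.tuples(st.integers(0, 2600), st.integers(1, 120)).map(
            lambda t: (t[0], t[0] + t[1])
        ),
        min_size=1,
        max_size=3,
    )
)
def test_resolution_matches_per_base_oracle(toy_catalog, blocks):
    """Random block sets: interval-tree overlap accounting must equal an
    exhaustive per-base count."""
    blocks = sorted(blocks)
    merged = []
    for s, e in blocks:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
        else:
            merged.append((s, e))
    r = read("chr1", merged)
    # oracle: count bases per (gene, class) by brute force, reverse-stranded
    base_overlaps = {}
    for gid in toy_catalog.gene_ids:
        gstrand = toy_catalog.gene_strand(gid)
        if gstrand == r.strand:  # reverse-stranded: must be antisense
            continue
        for cls, segs in (
            (EXON, toy_catalog.exon_segments[gid]),
            (INTRON, toy_catalog.intron_segments[gid]),
        ):
            bp = sum(
                max(0, min(be, iv.end) - max(bs, iv.start))
                for bs, be in merged
                for iv in segs
            )
            if bp:
                base_overlaps[(gid, cls)] = bp
    expected = iq.resolve_read_class(base_overlaps)
    ec, ic, s = run(toy_catalog, [r])
    disposition = expected[0]
    assert getattr(s, disposition) == 1
    s.check()


def test_count_reads_builds_full_tables(toy_catalog):
    samples = {
        "s1": [read("chr1", [(400, 500)], name="a")],
        "s2": [read("chr1", [(150, 250)], name="b"),
               read("chr1", [(2100, 2200)], strand="+", name="c")],
    }
    exon_tab, intron_tab, summaries = iq.count_reads(samples, toy_catalog)
    assert set(exon_tab.index) == set(toy_catalog.gene_ids)
    assert intron_tab.loc["G", "s1"] == 1
    assert exon_tab.loc["G", "s2"] == 1
    assert exon_tab.loc["H", "s2"] == 1
    assert [s.total for s in summaries.values()] == [1, 2]


def test_counting_is_deterministic_and_conserves(small_config, small_dataset, tmp_path):
    catalog = small_dataset["catalog"]
    sam_text, truth = iq.simulate_alignments(
        small_config, catalog, small_dataset["truth"]
    )
    sam_path = tmp_path / "reads.sam"
    sam_path.write_text(sam_text)
    exon_tab, intron_tab, summaries = iq.count_reads(
        {"all": iq.iter_sam(str(sam_path))}, catalog
    )
    s = summaries["all"]
    s.check()
    # simulator placement record is the counting oracle
    pl = truth.placements
    for cls, table in (("exon", exon_tab), ("intron", intron_tab)):
        expected = (
            pl[pl.feature_class == cls].groupby("gene_id").n_reads.sum()
        )
        observed = table["all"][table["all"] > 0]
        assert observed.sort_index().equals(expected.sort_index().astype(int))
    # rerunning is bit-identical
    exon2, intron2, _ = iq.count_reads({"all": iq.iter_sam(str(sam_path))}, catalog)
    assert exon_tab.equals(exon2) and intron_tab.equals(intron2)
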