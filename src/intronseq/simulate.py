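"""Synthetic genomes, counts, alignments and auxiliary tables with truth.

The generator embodies the generative assumptions of the intron-signal
analysis: per gene g and condition c there is a transcription rate
``tau_gc`` and an mRNA stability ``s_gc``; intron (nascent) abundance is
proportional to ``tau`` alone while exon (mature) abundance is
proportional to ``tau * s``.  A transcriptional effect multiplies ``tau``
by ``2**lfc`` in the up tissue and therefore moves intron and exon counts
jointly; a post-transcriptional effect multiplies ``s`` only and moves
exon counts alone.  Counts are negative-binomial with a shared dispersion.

Every generator output is byte-for-byte deterministic under a fixed seed;
each stage draws from its own seed stream so the stages can be rerun
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .catalog import FeatureCatalog
from .intervals import merge_spans, subtract_spans

NULL = "null"
TRANS = "transcriptional"
POST = "post_transcriptional"


@dataclass
class SimulationConfig:
    """All knobs of the generative model, with the study's default design:
    two conditions × 3 replicates, |log2 fold-change| 2, NB dispersion
    0.05, exon mean 500 and intron:exon abundance ratio 0.1 (the nascent
    fraction is scarce relative to mature mRNA)."""

    n_genes: int = 2000
    seed: int = 0

    # gene structure
    single_exon_prob: float = 0.15
    max_exons: int = 20
    exon_len_range: tuple[int, int] = (80, 300)
    intron_len_range: tuple[int, int] = (100, 1000)
    gap_range: tuple[int, int] = (200, 2000)
    genes_per_chrom: int = 100
    nesting_rate: float = 0.05
    isoform_rate: float = 0.2

    # expression / effects
    frac_transcriptional: float = 0.10   # per tissue
    frac_post_transcriptional: float = 0.05  # per tissue
    lfc: float = 2.0
    dispersion: float = 0.05
    exon_mean: float = 500.0
    intron_exon_ratio: float = 0.1
    n_replicates: int = 3
    sample_depths: tuple[float, ...] | None = None  # len = 2 * n_replicates

    # alignment emission
    read_length: int = 100
    alignment_depth: float = 0.05

    # auxiliary tables
    enhancer_genes_per_tissue: int = 60
    enhancer_odds: float = 9.0
    n_tfs: int = 5
    targets_per_tf: int = 150
    target_odds: float = 6.0
    n_go_terms: int = 25
    go_terms_per_gene: float = 2.0
    spike_term: str = "GO:7777777"
    spike_term_size: int = 40
    tf_go_term: str = "GO:0003700"
    subgenome_probs: tuple[float, float, float] = (0.49, 0.30, 0.21)

    def __post_init__(self) -> None:
        total = 2 * (self.frac_transcriptional + self.frac_post_transcriptional)
        if total > 1:
            raise ValueError("DE fractions exceed the gene pool")
        if self.sample_depths is not None and len(self.sample_depths) != 2 * self.n_replicates:
            raise ValueError("sample_depths must cover both conditions' replicates")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


@dataclass
class GroundTruth:
    """The simulator's record of what it generated."""

    genes: pd.DataFrame  # gene_id, chrom, strand, exon_count, true_class, true_tissue, true_lfc
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    placements: pd.DataFrame | None = None  # sample_id, gene_id, feature_class, n_reads
    tf_ids: list[str] = field(default_factory=list)


def make_design(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for cond in ("A", "B"):
        for r in range(1, config.n_replicates + 1):
            rows.append({"sample_id": f"{cond}_rep{r}", "condition": cond,
                         "replicate": r})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# annotation


def _draw_gene_structure(
    rng: np.random.Generator, cfg: SimulationConfig
) -> tuple[list[int], list[int]]:
    """Exon and intron lengths for one gene (exon count per the configured
    distribution: single-exon with prob ``single_exon_prob``, else uniform
    2..max_exons)."""
    if rng.random() < cfg.single_exon_prob:
        n_exons = 1
    else:
        n_exons = int(rng.integers(2, cfg.max_exons + 1))
    exon_lens = rng.integers(*cfg.exon_len_range, size=n_exons,
                             endpoint=True).tolist()
    intron_lens = rng.integers(*cfg.intron_len_range, size=max(0, n_exons - 1),
                               endpoint=True).tolist()
    return exon_lens, intron_lens


def simulate_annotation(config: SimulationConfig) -> tuple[str, GroundTruth]:
    """Emit a GFF3 genome with single-exon, nested and multi-isoform genes.

    Returns the GFF3 text and a truth skeleton (classes are assigned later
    by :func:`simulate_counts`).
    """
    rng = config.rng(1)
    lines = ["##gff-version 3"]
    records: list[dict] = []
    chrom_lengths: dict[str, int] = {}

    cursor = 0
    chrom_idx = 1
    chrom = f"chr{chrom_idx}"
    # introns of the previous gene on this chromosome, for nesting
    host_introns: list[tuple[int, int]] = []

    for i in range(config.n_genes):
        gid = f"gene{i + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"

        if (i + 1) % config.genes_per_chrom == 1 and i > 0:
            chrom_lengths[chrom] = cursor + 500
            chrom_idx += 1
            chrom = f"chr{chrom_idx}"
            cursor = 0
            host_introns = []

        exon_lens, intron_lens = _draw_gene_structure(rng, config)
        gene_span = sum(exon_lens) + sum(intron_lens)

        nested = False
        if host_introns and rng.random() < config.nesting_rate:
            fitting = [
                iv for iv in host_introns if iv[1] - iv[0] >= gene_span + 40
            ]
            if fitting:
                hs, _he = fitting[int(rng.integers(len(fitting)))]
                start = hs + 20
                nested = True
        if not nested:
            start = cursor + int(rng.integers(*config.gap_range, endpoint=True))

        exons: list[tuple[int, int]] = []
        pos = start
        for k, el in enumerate(exon_lens):
            exons.append((pos, pos + el))
            pos += el
            if k < len(intron_lens):
                pos += intron_lens[k]
        end = exons[-1][1]

        isoforms = [exons]
        if len(exons) >= 3 and rng.random() < config.isoform_rate:
            skip = int(rng.integers(1, len(exons) - 1))
            isoforms.append([e for j, e in enumerate(exons) if j != skip])

        lines.append(
            f"{chrom}\tsim\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\tID={gid}"
        )
        for t, iso in enumerate(isoforms, start=1):
            tid = f"{gid}.t{t}"
            lines.append(
                f"{chrom}\tsim\tmRNA\t{iso[0][0] + 1}\t{iso[-1][1]}\t.\t{strand}\t.\t"
                f"ID={tid};Parent={gid}"
            )
            for k, (es, ee) in enumerate(iso, start=1):
                lines.append(
                    f"{chrom}\tsim\texon\t{es + 1}\t{ee}\t.\t{strand}\t.\t"
                    f"ID={tid}.e{k};Parent={tid}"
                )

        records.append(
            {
                "gene_id": gid,
                "chrom": chrom,
                "strand": strand,
                "exon_count": len(merge_spans(exons)),
                "true_class": NULL,
                "true_tissue": "",
                "true_lfc": 0.0,
            }
        )
        if not nested:
            cursor = end
            host_introns.extend(subtract_spans([(start, end)], exons))

    chrom_lengths[chrom] = cursor + 500
    columns = [
        "gene_id", "chrom", "strand", "exon_count",
        "true_class", "true_tissue", "true_lfc",
    ]
    genes_df = pd.DataFrame(records, columns=columns).set_index(
        "gene_id", drop=False
    )
    truth = GroundTruth(genes=genes_df, chrom_lengths=chrom_lengths)
    return "\n".join(lines) + "\n", truth


# ---------------------------------------------------------------------------
# counts


def assign_classes(config: SimulationConfig, truth: GroundTruth) -> GroundTruth:
    """Label genes with their true regulatory class, tissue and effect size.

    Idempotent under a fixed seed: if classes were already assigned the
    same assignment is recomputed.
    """
    rng = config.rng(2)
    genes = truth.genes.copy()
    n = len(genes)
    n_t = int(round(config.frac_transcriptional * n))
    n_p = int(round(config.frac_post_transcriptional * n))
    order = rng.permutation(n)
    blocks = [
        (TRANS, "A", order[:n_t]),
        (TRANS, "B", order[n_t : 2 * n_t]),
        (POST, "A", order[2 * n_t : 2 * n_t + n_p]),
        (POST, "B", order[2 * n_t + n_p : 2 * n_t + 2 * n_p]),
    ]
    genes["true_class"] = NULL
    genes["true_tissue"] = ""
    genes["true_lfc"] = 0.0
    for cls, tissue, idx in blocks:
        genes.iloc[idx, genes.columns.get_loc("true_class")] = cls
        genes.iloc[idx, genes.columns.get_loc("true_tissue")] = tissue
        genes.iloc[idx, genes.columns.get_loc("true_lfc")] = config.lfc
    truth.genes = genes
    return truth


def _expected_means(
    config: SimulationConfig,
    truth: GroundTruth,
    has_intron: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene expected exon and intron means for each condition.

    Means are per-gene rate totals: the transcription rate tau absorbs
    feature length, so the baseline exon mean is ``exon_mean`` and the
    baseline intron mean is ``exon_mean * intron_exon_ratio`` wherever the
    gene has intron territory.
    """
    genes = truth.genes
    tau = pd.DataFrame(1.0, index=genes.index, columns=["A", "B"])
    stab = pd.DataFrame(1.0, index=genes.index, columns=["A", "B"])
    for gid, row in genes.iterrows():
        if row["true_class"] == TRANS:
            tau.loc[gid, row["true_tissue"]] = 2.0 ** row["true_lfc"]
        elif row["true_class"] == POST:
            stab.loc[gid, row["true_tissue"]] = 2.0 ** row["true_lfc"]
    exon_mu = config.exon_mean * tau * stab
    intron_mu = (config.exon_mean * config.intron_exon_ratio * tau).mul(
        has_intron.astype(float), axis=0
    )
    return exon_mu, intron_mu


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if alpha <= 1e-12:
        out[pos] = rng.poisson(mean[pos])
        return out
    size = 1.0 / alpha
    p = size / (size + mean[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def simulate_counts(
    config: SimulationConfig,
    catalog: FeatureCatalog | None,
    truth: GroundTruth,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw NB exon and intron count tables for the configured design.

    When a catalog is supplied, a gene's intron signal is emitted only if
    it retained intron territory after the genome-wide purge; otherwise
    any multi-exon gene is assumed to have introns.
    """
    truth = assign_classes(config, truth)
    rng = config.rng(3)
    genes = truth.genes
    if catalog is not None:
        has_intron = pd.Series(
            {g: bool(catalog.intron_segments.get(g)) for g in genes.index}
        )
    else:
        has_intron = genes["exon_count"] > 1
    exon_mu, intron_mu = _expected_means(config, truth, has_intron)

    design = make_design(config)
    depths = (
        np.asarray(config.sample_depths, dtype=float)
        if config.sample_depths is not None
        else np.ones(len(design))
    )
    exon_cols, intron_cols = {}, {}
    for j, row in design.iterrows():
        cond = row["condition"]
        exon_cols[row["sample_id"]] = _nb_draw(
            rng, exon_mu[cond].to_numpy() * depths[j], config.dispersion
        )
        intron_cols[row["sample_id"]] = _nb_draw(
            rng, intron_mu[cond].to_numpy() * depths[j], config.dispersion
        )
    exon_tab = pd.DataFrame(exon_cols, index=genes.index)
    intron_tab = pd.DataFrame(intron_cols, index=genes.index)
    exon_tab.index.name = "gene_id"
    intron_tab.index.name = "gene_id"
    return exon_tab, intron_tab, truth


# ---------------------------------------------------------------------------
# alignments


def _private_spans(
    catalog: FeatureCatalog,
) -> dict[tuple[str, str], list[tuple[int, int]]]:
    """Per (gene, class): segment regions not overlapped by any other
    gene's segments of either class (unambiguous read territory)."""
    by_chrom: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for segmap in (catalog.exon_segments, catalog.intron_segments):
        for gid, segs in segmap.items():
            for iv in segs:
                by_chrom.setdefault(iv.chrom, {}).setdefault(gid, []).append(
                    (iv.start, iv.end)
                )
    out: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for cls, segmap in (("exon", catalog.exon_segments), ("intron", catalog.intron_segments)):
        for gid, segs in segmap.items():
            if not segs:
                continue
            chrom = segs[0].chrom
            others: list[tuple[int, int]] = []
            for other_gid, spans in by_chrom.get(chrom, {}).items():
                if other_gid != gid:
                    others.extend(spans)
            spans = [(iv.start, iv.end) for iv in segs]
            out[(gid, cls)] = subtract_spans(spans, others)
    return out


def simulate_alignments(
    config: SimulationConfig,
    catalog: FeatureCatalog,
    truth: GroundTruth,
) -> tuple[str, GroundTruth]:
    """Emit single-end reverse-stranded reads as SAM text.

    Reads are placed entirely within regions attributable to exactly one
    (gene, feature-class), so counting the emitted SAM reproduces the
    placement record exactly.  Read depth follows the count model scaled
    by ``alignment_depth``.
    """
    truth = assign_classes(config, truth)
    rng = config.rng(4)
    genes = truth.genes
    has_intron = pd.Series(
        {g: bool(catalog.intron_segments.get(g)) for g in genes.index}
    )
    exon_mu, intron_mu = _expected_means(config, truth, has_intron)
    private = _private_spans(catalog)
    design = make_design(config)

    header = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom in sorted(truth.chrom_lengths):
        header.append(f"@SQ\tSN:{chrom}\tLN:{truth.chrom_lengths[chrom]}")
    records: list[str] = []
    placements: list[dict] = []
    read_no = 0

    for _, srow in design.iterrows():
        sid, cond = srow["sample_id"], srow["condition"]
        for gid in genes.index:
            strand = genes.loc[gid, "strand"]
            flag = 16 if strand == "+" else 0  # reverse-stranded library
            chrom = genes.loc[gid, "chrom"]
            for cls, mu in (("exon", exon_mu), ("intron", intron_mu)):
                mean = mu.loc[gid, cond] * config.alignment_depth
                if mean <= 0:
                    continue
                n_reads = int(_nb_draw(rng, np.array([mean]), config.dispersion)[0])
                spans = [
                    (s, e) for s, e in private.get((gid, cls), []) if e - s >= 20
                ]
                if n_reads == 0 or not spans:
                    continue
                weights = np.array([e - s for s, e in spans], dtype=float)
                weights /= weights.sum()
                placed = 0
                for _ in range(n_reads):
                    s, e = spans[int(rng.choice(len(spans), p=weights))]
                    length = min(config.read_length, e - s)
                    start = int(rng.integers(s, e - length + 1))
                    read_no += 1
                    records.append(
                        "\t".join(
                            [
                                f"read{read_no:08d}",
                                str(flag),
                                chrom,
                                str(start + 1),
                                "60",
                                f"{length}M",
                                "*", "0", "0",
                                "A" * length,
                                "*",
                                "NH:i:1",
                            ]
                        )
                    )
                    placed += 1
                if placed:
                    placements.append(
                        {
                            "sample_id": sid,
                            "gene_id": gid,
                            "feature_class": cls,
                            "n_reads": placed,
                        }
                    )

    truth.placements = pd.DataFrame(
        placements, columns=["sample_id", "gene_id", "feature_class", "n_reads"]
    )
    return "\n".join(header + records) + "\n", truth


# ---------------------------------------------------------------------------
# auxiliary tables


def _weighted_sample(
    rng: np.random.Generator, pool: list[str], weights: np.ndarray, k: int
) -> list[str]:
    k = min(k, len(pool))
    probs = weights / weights.sum()
    idx = rng.choice(len(pool), size=k, replace=False, p=probs)
    return [pool[i] for i in sorted(idx)]


def simulate_auxiliary(
    config: SimulationConfig, truth: GroundTruth
) -> dict[str, pd.DataFrame]:
    """Enhancer lists, TF network, subgenome map and GO map, each enriched
    for the true classes so downstream joins have signal to find.

    Returns a dict with keys 'enhancers', 'network', 'subgenomes', 'go_map'.
    TF gene ids are recorded in ``truth.tf_ids``.
    """
    rng = config.rng(5)
    genes = truth.genes
    if len(genes) == 0:
        empty = {
            "enhancers": pd.DataFrame(columns=["gene_id", "tissue"]),
            "network": pd.DataFrame(columns=["tf_id", "target_id"]),
            "subgenomes": pd.DataFrame(columns=["gene_id", "subgenome"]),
            "go_map": pd.DataFrame(columns=["gene_id", "term_id"]),
        }
        return empty
    all_ids = list(genes.index)
    multiexon = genes["exon_count"] > 1

    # enhancer-linked genes, preferentially truly transcriptional per tissue
    enh_rows = []
    for tissue in ("A", "B"):
        is_target = (
            (genes["true_class"] == TRANS) & (genes["true_tissue"] == tissue)
        ) & multiexon
        weights = np.where(is_target.to_numpy(), config.enhancer_odds, 1.0)
        for g in _weighted_sample(
            rng, all_ids, weights, config.enhancer_genes_per_tissue
        ):
            enh_rows.append({"gene_id": g, "tissue": tissue})
    enhancers = pd.DataFrame(enh_rows, columns=["gene_id", "tissue"])

    # TF network: TFs from true transcriptional genes; targets lean DE
    trans_pool = list(genes.index[(genes["true_class"] == TRANS) & multiexon])
    tf_ids = (
        _weighted_sample(rng, trans_pool, np.ones(len(trans_pool)), config.n_tfs)
        if trans_pool
        else []
    )
    is_de = (genes["true_class"] != NULL).to_numpy()
    net_rows = []
    for tf in tf_ids:
        weights = np.where(is_de, config.target_odds, 1.0)
        for tgt in _weighted_sample(rng, all_ids, weights, config.targets_per_tf):
            if tgt != tf:
                net_rows.append({"tf_id": tf, "target_id": tgt})
    network = pd.DataFrame(net_rows, columns=["tf_id", "target_id"]).drop_duplicates()
    truth.tf_ids = tf_ids

    # subgenome labels (two homeologous subgenomes + unassigned)
    labels = np.array(["maize1", "maize2", "none"])
    draw = rng.choice(3, size=len(all_ids), p=np.asarray(config.subgenome_probs))
    subgenomes = pd.DataFrame(
        {"gene_id": all_ids, "subgenome": labels[draw]}
    )
    subgenomes = subgenomes[subgenomes["subgenome"] != "none"].reset_index(drop=True)

    # GO map: background terms + a spiked term on true transcriptional genes
    go_rows = []
    n_terms = max(config.n_go_terms, 1)
    for g in all_ids:
        k = rng.poisson(config.go_terms_per_gene)
        for t in rng.choice(n_terms, size=min(k, n_terms), replace=False):
            go_rows.append({"gene_id": g, "term_id": f"GO:{t + 1:07d}"})
    spike_pool = trans_pool if trans_pool else all_ids
    for g in _weighted_sample(
        rng, spike_pool, np.ones(len(spike_pool)), config.spike_term_size
    ):
        go_rows.append({"gene_id": g, "term_id": config.spike_term})
    tf_term_genes = list(tf_ids) + _weighted_sample(
        rng, all_ids, np.ones(len(all_ids)), 10
    )
    for g in dict.fromkeys(tf_term_genes):
        go_rows.append({"gene_id": g, "term_id": config.tf_go_term})
    go_map = pd.DataFrame(go_rows, columns=["gene_id", "term_id"]).drop_duplicates()

    return {
        "enhancers": enhancers,
        "network": network,
        "subgenomes": subgenomes,
        "go_map": go_map,
    }
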