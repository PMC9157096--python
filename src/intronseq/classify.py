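"""Calling the regulatory level of differentially expressed genes.

Intron-mapping reads in a total-RNA library report nascent (unspliced)
transcripts, so a differential intron signal marks a transcriptional
change while an exon-only signal marks a change in mature-mRNA abundance,
i.e. post-transcriptional regulation.  Single-exon genes have no introns
and an exon-only signal there is inconclusive.

A gene is "significant for tissue A" in a table when it was tested,
p_adjusted < padj_max and log2_fc > lfc_min_abs (tissue B: < -lfc_min_abs);
the inequalities are strict.  The evidence per tissue is the set of tables
(intron, exon) in which the gene is significant for that tissue:

* intron in the evidence (intron_only or both)  -> transcriptional
* exon_only, gene has >= 2 exons                -> post_transcriptional_multiexon
* exon_only, single-exon gene                   -> inconclusive_single_exon

A gene significant for different tissues in the two tables receives one
call per tissue, each flagged as a conflict.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .catalog import FeatureCatalog

TRANSCRIPTIONAL = "transcriptional"
POST_TRANSCRIPTIONAL = "post_transcriptional_multiexon"
INCONCLUSIVE = "inconclusive_single_exon"
CATEGORIES = (TRANSCRIPTIONAL, POST_TRANSCRIPTIONAL, INCONCLUSIVE)


@dataclass
class ClassificationThresholds:
    """Significance cut-offs applied to each differential table."""

    padj_max: float = 0.05
    lfc_min_abs: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.padj_max <= 1:
            raise ValueError("padj_max must lie in (0, 1]")
        if self.lfc_min_abs <= 0:
            raise ValueError("lfc_min_abs must be positive")


def _significant_tissue(row: pd.Series, thr: ClassificationThresholds) -> str | None:
    """Which tissue (if any) a DE record supports: 'A', 'B', or None."""
    if not row["tested"] or pd.isna(row["p_adjusted"]):
        return None
    if row["p_adjusted"] >= thr.padj_max:
        return None
    if row["log2_fc"] > thr.lfc_min_abs:
        return "A"
    if row["log2_fc"] < -thr.lfc_min_abs:
        return "B"
    return None


def classify_genes(
    intron_table: pd.DataFrame,
    exon_table: pd.DataFrame,
    catalog: FeatureCatalog | dict[str, int],
    thresholds: ClassificationThresholds | None = None,
) -> pd.DataFrame:
    """Classify every differentially expressed gene by regulatory level.

    Parameters
    ----------
    intron_table, exon_table : DataFrame
        Differential tables indexed by gene_id with columns log2_fc,
        p_adjusted, tested (as produced by :mod:`intronseq.diffexp`).
    catalog : FeatureCatalog or mapping gene_id -> exon_count
        Source of per-gene exon counts.
    thresholds : ClassificationThresholds, optional

    Returns
    -------
    DataFrame with one row per (gene, tissue) call: columns gene_id,
    tissue ('A' or 'B'), category, evidence, exon_count, conflict_flag.
    """
    thr = thresholds or ClassificationThresholds()
    exon_counts = (
        catalog.exon_counts if isinstance(catalog, FeatureCatalog) else dict(catalog)
    )
    de_genes = set(intron_table.index) | set(exon_table.index)
    missing = sorted(g for g in de_genes if g not in exon_counts)
    if missing:
        raise KeyError(
            f"{len(missing)} gene(s) in DE tables absent from catalog: {missing[:10]}"
        )

    calls: list[dict] = []
    for gid in sorted(de_genes):
        by_tissue: dict[str, set[str]] = {}
        for cls, table in (("intron", intron_table), ("exon", exon_table)):
            if gid not in table.index:
                continue
            tissue = _significant_tissue(table.loc[gid], thr)
            if tissue is not None:
                by_tissue.setdefault(tissue, set()).add(cls)
        if not by_tissue:
            continue
        conflict = len(by_tissue) > 1
        for tissue, tables in sorted(by_tissue.items()):
            if "intron" in tables:
                evidence = "both" if "exon" in tables else "intron_only"
                category = TRANSCRIPTIONAL
            else:
                evidence = "exon_only"
                category = (
                    INCONCLUSIVE if exon_counts[gid] == 1 else POST_TRANSCRIPTIONAL
                )
            calls.append(
                {
                    "gene_id": gid,
                    "tissue": tissue,
                    "category": category,
                    "evidence": evidence,
                    "exon_count": exon_counts[gid],
                    "conflict_flag": conflict,
                }
            )
    return pd.DataFrame(
        calls,
        columns=[
            "gene_id", "tissue", "category", "evidence", "exon_count", "conflict_flag",
        ],
    )


def summarize_categories(calls: pd.DataFrame) -> pd.DataFrame:
    """Tabulate calls per tissue × category with row totals.

    Returns a DataFrame indexed by category with columns for each tissue,
    'total', and one extra row 'unique_genes' giving the deduplicated gene
    count (multi-category genes counted once) plus a 'multi_category_genes'
    row.
    """
    tissues = sorted(calls["tissue"].unique()) if len(calls) else ["A", "B"]
    rows = {}
    for cat in CATEGORIES:
        sub = calls[calls["category"] == cat]
        rows[cat] = {t: int((sub["tissue"] == t).sum()) for t in tissues}
        rows[cat]["total"] = int(len(sub))
    n_unique = calls["gene_id"].nunique() if len(calls) else 0
    n_multi = (
        int((calls.groupby("gene_id").size() > 1).sum()) if len(calls) else 0
    )
    summary = pd.DataFrame(rows).T
    summary.index.name = "category"
    summary.loc["unique_genes"] = {t: 0 for t in tissues} | {"total": n_unique}
    summary.loc["multi_category_genes"] = {t: 0 for t in tissues} | {"total": n_multi}
    return summary.astype(int)


def write_calls(calls: pd.DataFrame, path: str) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
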