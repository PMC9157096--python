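"""Joining regulatory calls with auxiliary gene annotations.

These operations quantify how the transcriptional / post-transcriptional
partition aligns with independent annotations: tissue-specific
enhancer-linked gene lists, TF→target network edges, subgenome (homeolog)
assignments, named-TF target lists, and GO term enrichment (one-sided
Fisher with Benjamini–Yekutieli control, the combination agriGO-style
tools use).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import FeatureCatalog
from .classify import POST_TRANSCRIPTIONAL, TRANSCRIPTIONAL


@dataclass(frozen=True)
class OverlapSummary:
    """A numerator/denominator pair with its printed-style percentage."""

    numerator: int
    denominator: int
    decimals: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.numerator <= max(self.denominator, 0):
            raise ValueError(
                f"invalid overlap {self.numerator}/{self.denominator}"
            )

    @property
    def percentage(self) -> float | None:
        """100*num/den rounded to the configured precision; None when the
        denominator is zero (undefined, never reported as 0%)."""
        if self.denominator == 0:
            return None
        return round(100.0 * self.numerator / self.denominator, self.decimals)


def _class_members(calls: pd.DataFrame, tissue: str, category: str) -> set[str]:
    sub = calls[(calls["tissue"] == tissue) & (calls["category"] == category)]
    return set(sub["gene_id"])


def enhancer_overlap(
    calls: pd.DataFrame,
    enhancers: pd.DataFrame,
    catalog: FeatureCatalog | dict[str, int],
) -> dict[tuple[str, str], OverlapSummary]:
    """Overlap of tissue-specific enhancer-linked genes with the two classes.

    ``enhancers`` has columns gene_id, tissue.  Single-exon genes are
    removed first (they cannot carry intron evidence).  Per tissue, the
    denominator is the number of enhancer-linked genes recovered in either
    class for that tissue; the numerators split it by class.
    """
    exon_counts = (
        catalog.exon_counts if isinstance(catalog, FeatureCatalog) else dict(catalog)
    )
    out: dict[tuple[str, str], OverlapSummary] = {}
    for tissue in sorted(enhancers["tissue"].unique()):
        linked = {
            g
            for g in enhancers.loc[enhancers["tissue"] == tissue, "gene_id"]
            if exon_counts.get(g, 2) > 1
        }
        trans = _class_members(calls, tissue, TRANSCRIPTIONAL) & linked
        post = _class_members(calls, tissue, POST_TRANSCRIPTIONAL) & linked
        den = len(trans | post)
        out[(tissue, TRANSCRIPTIONAL)] = OverlapSummary(len(trans), den)
        out[(tissue, POST_TRANSCRIPTIONAL)] = OverlapSummary(len(post), den)
    return out


def tf_target_coverage(
    calls: pd.DataFrame,
    network: pd.DataFrame,
    tf_genes: set[str],
) -> dict[tuple[str, str], OverlapSummary]:
    """Fraction of each class covered by targets of that tissue's active TFs.

    ``network`` has columns tf_id, target_id.  Per tissue, the active TF
    set is the transcriptional calls that are annotated TFs; the target
    pool is the union of their network targets; each class's summary is
    (class members in the pool) / (class size in the tissue).
    """
    edges = network.groupby("tf_id")["target_id"].apply(set).to_dict()
    out: dict[tuple[str, str], OverlapSummary] = {}
    for tissue in sorted(calls["tissue"].unique()):
        active_tfs = _class_members(calls, tissue, TRANSCRIPTIONAL) & tf_genes
        pool: set[str] = set()
        for tf in active_tfs:
            pool |= edges.get(tf, set())
        for category in (TRANSCRIPTIONAL, POST_TRANSCRIPTIONAL):
            members = _class_members(calls, tissue, category)
            out[(tissue, category)] = OverlapSummary(
                len(members & pool), len(members)
            )
    return out


def subgenome_breakdown(
    calls: pd.DataFrame,
    subgenomes: pd.DataFrame,
    labels: tuple[str, ...] = ("maize1", "maize2"),
) -> dict[tuple[str, str, str], OverlapSummary]:
    """Subgenome composition of each tissue × category class.

    ``subgenomes`` has columns gene_id, subgenome; genes absent from it
    fall in the 'none' bucket.  Percentages use 2 decimals and the three
    buckets partition each class exactly.
    """
    label_of = dict(zip(subgenomes["gene_id"], subgenomes["subgenome"]))
    out: dict[tuple[str, str, str], OverlapSummary] = {}
    for tissue in sorted(calls["tissue"].unique()):
        for category in (TRANSCRIPTIONAL, POST_TRANSCRIPTIONAL):
            members = _class_members(calls, tissue, category)
            den = len(members)
            remaining = set(members)
            for label in labels:
                hits = {g for g in members if label_of.get(g) == label}
                remaining -= hits
                out[(tissue, category, label)] = OverlapSummary(
                    len(hits), den, decimals=2
                )
            out[(tissue, category, "none")] = OverlapSummary(
                len(remaining), den, decimals=2
            )
    return out


def grn_target_summary(
    tf_targets: dict[str, set[str]],
    calls: pd.DataFrame,
) -> pd.DataFrame:
    """Per named TF: how its network targets split across the two classes.

    The differentially expressed targets are those called transcriptional
    or multi-exon post-transcriptional (in any tissue); percentages are
    over that DE total and are None when a TF has no DE targets.
    """
    trans_all = set(calls.loc[calls["category"] == TRANSCRIPTIONAL, "gene_id"])
    post_all = set(calls.loc[calls["category"] == POST_TRANSCRIPTIONAL, "gene_id"])
    rows = []
    for tf, targets in tf_targets.items():
        t_hits = targets & trans_all
        p_hits = (targets & post_all) - t_hits
        de_total = len(t_hits) + len(p_hits)
        t_sum = OverlapSummary(len(t_hits), de_total)
        p_sum = OverlapSummary(len(p_hits), de_total)
        rows.append(
            {
                "tf_id": tf,
                "n_targets": len(targets),
                "n_transcriptional": len(t_hits),
                "n_post_transcriptional": len(p_hits),
                "n_de_targets": de_total,
                "pct_transcriptional": t_sum.percentage,
                "pct_post_transcriptional": p_sum.percentage,
            }
        )
    return pd.DataFrame(rows)


def benjamini_yekutieli(p_values: np.ndarray) -> np.ndarray:
    """BY step-up adjusted p-values (valid under arbitrary dependence)."""
    return multipletests(p_values, method="fdr_by")[1]


def term_enrichment(
    study: set[str],
    background: set[str],
    go_map: pd.DataFrame,
    alpha: float = 0.01,
    min_entries: int = 10,
) -> pd.DataFrame:
    """One-sided Fisher term enrichment with Benjamini–Yekutieli control.

    ``go_map`` has columns gene_id, term_id.  Terms with fewer than
    ``min_entries`` annotated background genes are excluded before testing.
    The p-value for a term with m background hits and k study hits is the
    hypergeometric upper tail P[X >= k] drawing K = |study| from
    N = |background|.

    Raises if the study set is not contained in the background.
    """
    stray = study - background
    if stray:
        raise ValueError(
            f"{len(stray)} study gene(s) absent from background: {sorted(stray)[:10]}"
        )
    go_map = go_map[go_map["gene_id"].isin(background)]
    n_bg = len(background)
    n_study = len(study)
    rows = []
    for term, genes in go_map.groupby("term_id")["gene_id"]:
        annotated = set(genes)
        m = len(annotated)
        if m < min_entries:
            continue
        k = len(annotated & study)
        p = float(stats.hypergeom.sf(k - 1, n_bg, m, n_study))
        rows.append({"term_id": term, "k": k, "K": n_study, "m": m, "N": n_bg,
                     "p_value": min(p, 1.0)})
    result = pd.DataFrame(
        rows, columns=["term_id", "k", "K", "m", "N", "p_value"]
    )
    if len(result):
        result["fdr"] = benjamini_yekutieli(result["p_value"].to_numpy())
        result["significant"] = result["fdr"] < alpha
        result = result.sort_values("p_value", kind="stable").reset_index(drop=True)
    else:
        result["fdr"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return result


def load_synonyms(path: str) -> dict[str, str]:
    """Two-column TSV (old_id, new_id) mapping annotation versions."""
    table = pd.read_csv(path, sep="\t", header=None, names=["old", "new"])
    return dict(zip(table["old"], table["new"]))


def apply_synonyms(genes: pd.Series, synonyms: dict[str, str]) -> pd.Series:
    return genes.map(lambda g: synonyms.get(g, g))


def overlap_table(
    summaries: dict, decimals_note: str = ""
) -> pd.DataFrame:
    """Flatten a summary dict (tuple keys) into a tidy DataFrame."""
    rows = []
    for key, s in summaries.items():
        row = {f"key_{i}": k for i, k in enumerate(key)}
        row |= {
            "numerator": s.numerator,
            "denominator": s.denominator,
            "percentage": s.percentage,
        }
        rows.append(row)
    return pd.DataFrame(rows)
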