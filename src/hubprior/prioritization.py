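"""Combine the two hub-selection routes and evaluate the prioritized list.

Step 1 (differential co-expression) and Step 2 (semantic similarity) each
yield a candidate hub set; the prioritized list is their union with
provenance flags.  The list is then evaluated by overlap with a reference
disease-gene set, by a tissue-specificity filter against target tissues,
and by GO term over-representation (one-sided hypergeometric test with
ancestor propagation and Benjamini–Hochberg correction — an in-repo
replacement for web-service enrichment tools).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import AnnotationMap, GeneSet, GoDag, TissueTable

__all__ = [
    "PrioritizedList",
    "TissueFilterResult",
    "combine_hubs",
    "reference_overlap",
    "tissue_filter",
    "go_enrichment",
]


@dataclass
class PrioritizedList:
    """Union of the Step-1 and Step-2 hub sets with provenance."""

    table: pd.DataFrame  # index gene_id; columns provenance, avg_pcc,
    #                      median_semsim, reference_hit, tissue_pass
    reference_hits: frozenset[str] = frozenset()
    tissue_expressed: frozenset[str] = frozenset()

    @property
    def genes(self) -> GeneSet:
        return GeneSet("prioritized", frozenset(self.table.index))

    def __len__(self) -> int:
        return len(self.table)


def combine_hubs(
    netvar_sel: GeneSet,
    semsim_sel: GeneSet,
    avg_pcc: Mapping[str, float] | None = None,
    median_semsim: Mapping[str, float] | None = None,
) -> PrioritizedList:
    """Set union with provenance flags (netvar / semsim / both).

    Deterministic ordering: provenance "both" first, then decreasing
    |AvgPCC| (genes without a score last), then gene id.
    """
    avg_pcc = dict(avg_pcc or {})
    median_semsim = dict(median_semsim or {})
    rows = []
    for gene in sorted(set(netvar_sel.genes) | set(semsim_sel.genes)):
        in_a, in_b = gene in netvar_sel, gene in semsim_sel
        provenance = "both" if (in_a and in_b) else ("netvar" if in_a else "semsim")
        rows.append(
            {
                "gene_id": gene,
                "provenance": provenance,
                "avg_pcc": avg_pcc.get(gene, np.nan),
                "median_semsim": median_semsim.get(gene, np.nan),
                "reference_hit": False,
                "tissue_pass": False,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "provenance", "avg_pcc", "median_semsim",
            "reference_hit", "tissue_pass",
        ],
    ).set_index("gene_id")
    if len(table):
        order = sorted(
            table.index,
            key=lambda g: (
                table.at[g, "provenance"] != "both",
                -abs(table.at[g, "avg_pcc"])
                if np.isfinite(table.at[g, "avg_pcc"])
                else np.inf,
                g,
            ),
        )
        table = table.loc[order]
    return PrioritizedList(table)


def reference_overlap(prioritized: PrioritizedList, reference: GeneSet) -> GeneSet:
    """Intersection of the prioritized list with a reference disease-gene set."""
    hits = frozenset(prioritized.table.index) & reference.genes
    prioritized.table["reference_hit"] = [
        g in hits for g in prioritized.table.index
    ]
    prioritized.reference_hits = hits
    return GeneSet("reference_hits", hits)


@dataclass
class TissueFilterResult:
    """Outcome of the tissue-specificity filter."""

    passed: GeneSet
    housekeeping: GeneSet  # list members that are housekeeping genes
    unmeasured: frozenset[str]
    fold: float
    targets: tuple[str, ...]


def tissue_filter(
    prioritized: PrioritizedList,
    tissues: TissueTable,
    targets: Iterable[str],
    housekeeping: GeneSet,
    fold: float = 1.5,
) -> TissueFilterResult:
    """Keep genes enriched in a target tissue relative to their own median.

    A gene passes when, in at least one target tissue, its expression is at
    least *fold* times its median across all tissues.  Housekeeping genes
    are reported separately and never counted as tissue-specific; genes
    missing from the table are flagged unmeasured.
    """
    if fold <= 0:
        raise ValueError("fold must be > 0")
    targets = tuple(targets)
    missing_cols = set(targets) - set(tissues.tissues)
    if missing_cols:
        raise ValueError(f"unknown target tissue(s): {sorted(missing_cols)}")
    passed, hk, unmeasured = set(), set(), set()
    for gene in prioritized.table.index:
        if gene not in tissues.values.index:
            unmeasured.add(gene)
            continue
        row = tissues.values.loc[gene]
        med = float(row.median())
        hits_target = any(row[t] >= fold * med for t in targets)
        if gene in housekeeping:
            hk.add(gene)
        elif hits_target:
            passed.add(gene)
    prioritized.table["tissue_pass"] = [
        g in passed for g in prioritized.table.index
    ]
    prioritized.tissue_expressed = frozenset(passed)
    return TissueFilterResult(
        passed=GeneSet("tissue_specific", frozenset(passed)),
        housekeeping=GeneSet("housekeeping_members", frozenset(hk)),
        unmeasured=frozenset(unmeasured),
        fold=fold,
        targets=targets,
    )


def _propagated_annotations(
    ann: AnnotationMap, dag: GoDag, genes: Iterable[str]
) -> dict[str, set[str]]:
    """Term → genes, with each annotation propagated to all ancestors."""
    closures: dict[str, set[str]] = {}
    term_genes: dict[str, set[str]] = {}
    for gene in genes:
        for term in ann.terms_for(gene):
            if term not in dag:
                continue
            if term not in closures:
                closures[term] = dag.ancestor_closure(term)
            for t in closures[term]:
                term_genes.setdefault(t, set()).add(gene)
    return term_genes


def go_enrichment(
    gene_list: GeneSet,
    background: GeneSet,
    ann: AnnotationMap,
    dag: GoDag,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per GO term.

    Annotations are propagated to ancestor terms; for each term with K >= 1
    background annotations, p = P(X >= k) for X hypergeometric(N, K, n)
    where N is the background size, n the list size and k the number of
    list genes annotated.  Benjamini–Hochberg adjusted p-values are added
    and rows with adjusted_p <= alpha flagged.
    """
    if not gene_list.genes <= background.genes:
        raise ValueError("gene list must be a subset of the background")
    cols = [
        "term_id", "list_count", "list_size", "background_count",
        "background_size", "p_value", "adjusted_p", "enriched",
    ]
    if len(gene_list) == 0:
        return pd.DataFrame(columns=cols)
    term_genes = _propagated_annotations(ann, dag, background.genes)
    N, n = len(background), len(gene_list)
    rows = []
    for term in sorted(term_genes):
        K = len(term_genes[term])
        k = len(term_genes[term] & gene_list.genes)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, n, K, N, min(p, 1.0)))
    df = pd.DataFrame(
        rows,
        columns=[
            "term_id", "list_count", "list_size", "background_count",
            "background_size", "p_value",
        ],
    )
    _, adj, _, _ = multipletests(df["p_value"], method="fdr_bh")
    df["adjusted_p"] = adj
    df["enriched"] = df["adjusted_p"] <= alpha
    return df.sort_values(["p_value", "term_id"]).reset_index(drop=True)
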