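"""Wang's ontology-based semantic similarity and median-similarity hub selection.

For a term A, every ancestor t (including A itself) contributes
S_A(t) to A's semantics: S_A(A) = 1 and, walking rootward,
S_A(t) = max over children c of t on paths toward A of w_rel * S_A(c),
with relation weights w_is_a = 0.8 and w_part_of = 0.6 by default.  The
similarity of two terms is the weight of their shared ancestry relative to
their total semantic values:

    S_GO(A, B) = sum_{t in T_A ∩ T_B} (S_A(t) + S_B(t)) / (sv(A) + sv(B))

Gene-level similarity averages S_GO over annotation-term pairs (full cross
product by default; best-match average available), and a hub is selected
when the median similarity to its annotated interactors strictly exceeds
the threshold (0.5 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import AnnotationMap, GeneSet, GoDag
from .network_topology import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "TermSemanticProfile",
    "SemSimResult",
    "semantic_profile",
    "term_similarity",
    "gene_similarity",
    "prioritize_by_semsim",
]


@dataclass(frozen=True)
class TermSemanticProfile:
    """S-values of a term's ancestor closure and their sum sv(A)."""

    term: str
    s_values: dict[str, float]  # t -> S_A(t) for every t in T_A
    sv: float


def semantic_profile(dag: GoDag, term: str) -> TermSemanticProfile:
    """Wang S-value profile of *term* over its ancestor closure."""
    closure = dag.ancestor_closure(term)  # KeyError for unknown terms
    sub = dag.graph.subgraph(closure)
    s: dict[str, float] = {term: 1.0}
    # child->parent edges: topological order visits children before parents
    for node in nx.topological_sort(sub):
        if node not in s:
            continue
        for _, parent, data in sub.out_edges(node, data=True):
            w = dag.weights[data["relation"]]
            cand = w * s[node]
            if cand > s.get(parent, 0.0):
                s[parent] = cand
    return TermSemanticProfile(term, s, float(sum(s.values())))


def term_similarity(
    dag: GoDag,
    a: str,
    b: str,
    _cache: dict[str, TermSemanticProfile] | None = None,
) -> float:
    """S_GO(A, B): shared-ancestor semantic weight over total semantic value.

    Terms with disjoint ancestor closures (different roots) get similarity 0
    with a warning.
    """
    if _cache is None:
        _cache = {}
    for t in (a, b):
        if t not in _cache:
            _cache[t] = semantic_profile(dag, t)
    pa, pb = _cache[a], _cache[b]
    shared = pa.s_values.keys() & pb.s_values.keys()
    if not shared:
        logger.warning("terms %s and %s share no ancestors; similarity 0", a, b)
        return 0.0
    num = sum(pa.s_values[t] + pb.s_values[t] for t in shared)
    return num / (pa.sv + pb.sv)


def gene_similarity(
    dag: GoDag,
    ann: AnnotationMap,
    g1: str,
    g2: str,
    combine: str = "all_pairs_avg",
    _cache: dict[str, TermSemanticProfile] | None = None,
) -> float:
    """Similarity of two annotated genes from their term-set similarities.

    ``all_pairs_avg`` (default) is the mean of S_GO over the full cross
    product of the two term sets; ``best_match_avg`` averages each term's
    best match in the other set (symmetrised).
    """
    t1, t2 = sorted(ann.terms_for(g1)), sorted(ann.terms_for(g2))
    if not t1 or not t2:
        raise ValueError(f"gene {g1 if not t1 else g2!r} has no annotation")
    if combine not in ("all_pairs_avg", "best_match_avg"):
        raise ValueError("combine must be 'all_pairs_avg' or 'best_match_avg'")
    if _cache is None:
        _cache = {}
    sims = np.array(
        [[term_similarity(dag, a, b, _cache) for b in t2] for a in t1]
    )
    if combine == "all_pairs_avg":
        return float(sims.mean())
    return float(
        (sims.max(axis=1).sum() + sims.max(axis=0).sum()) / (len(t1) + len(t2))
    )


@dataclass
class SemSimResult:
    """Per-hub interactor similarities, their median and the selection flag."""

    table: pd.DataFrame  # index hub_id; n_scored_interactors,
    #                      median_similarity, selected
    similarities: dict[str, dict[str, float]]
    threshold: float
    combine: str
    excluded: dict[str, str]

    def selected_hubs(self) -> GeneSet:
        sel = self.table.index[self.table["selected"]]
        return GeneSet("semsim_hubs", frozenset(sel))


def prioritize_by_semsim(
    dag: GoDag,
    ann: AnnotationMap,
    net: InteractionNetwork,
    hubs: list[str] | GeneSet,
    threshold: float = 0.5,
    combine: str = "all_pairs_avg",
) -> SemSimResult:
    """Select hubs whose median similarity to annotated interactors exceeds
    the threshold (strictly).

    Unannotated interactors are skipped; a hub is excluded (never selected)
    when it is unannotated or has no annotated interactor.  The median of an
    even number of values is the mean of the two central ones.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    cache: dict[str, TermSemanticProfile] = {}
    pair_cache: dict[frozenset[str], float] = {}
    rows = []
    sims_by_hub: dict[str, dict[str, float]] = {}
    excluded: dict[str, str] = {}
    for hub in sorted(set(hubs if isinstance(hubs, GeneSet) else hubs)):
        if hub not in net:
            excluded[hub] = "absent from network"
            continue
        if hub not in ann:
            excluded[hub] = "hub unannotated"
            continue
        sims: dict[str, float] = {}
        for partner in sorted(net.neighbors(hub)):
            if partner not in ann:
                continue
            key = frozenset((hub, partner))
            if key not in pair_cache:
                pair_cache[key] = gene_similarity(
                    dag, ann, hub, partner, combine=combine, _cache=cache
                )
            sims[partner] = pair_cache[key]
        if not sims:
            excluded[hub] = "no annotated interactor"
            continue
        med = float(np.median(list(sims.values())))
        sims_by_hub[hub] = sims
        rows.append((hub, len(sims), med, med > threshold))
    table = pd.DataFrame(
        rows,
        columns=["hub_id", "n_scored_interactors", "median_similarity", "selected"],
    ).set_index("hub_id")
    return SemSimResult(
        table,
        similarities=sims_by_hub,
        threshold=threshold,
        combine=combine,
        excluded=excluded,
    )
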