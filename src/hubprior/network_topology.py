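"""Disease-specific network construction and hub/bottleneck detection.

The disease network is the induced subgraph of the interaction network on
the differentially expressed genes (isolated nodes dropped).  Two
topological rules select hubs:

* degree hubs: nodes whose degree strictly exceeds AVG + 2*Std, with AVG
  the mean degree over the disease network and Std the sample standard
  deviation;
* bottlenecks: nodes in the top half (configurable quantile) of the
  *positive* normalized betweenness-centrality distribution — leaves and
  other zero-betweenness nodes are never bottlenecks.

The hub set is the union of the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import GeneSet, RawEdgeList

__all__ = [
    "InteractionNetwork",
    "HubTable",
    "build_disease_network",
    "degree_cutoff_from_degrees",
    "degree_hub_cutoff",
    "betweenness",
    "select_hubs",
]

#: the pipeline's network container: an undirected simple graph
InteractionNetwork = nx.Graph


@dataclass
class HubTable:
    """Per-node topology metrics and hub flags plus global network summary."""

    table: pd.DataFrame  # index node; degree, betweenness_norm, is_degree_hub,
    #                      is_bottleneck, is_hub
    degree_cutoff: float
    bottleneck_threshold: float
    summary: dict

    def hubs(self) -> GeneSet:
        return GeneSet("hubs", frozenset(self.table.index[self.table["is_hub"]]))

    def degree_hubs(self) -> GeneSet:
        return GeneSet(
            "degree_hubs", frozenset(self.table.index[self.table["is_degree_hub"]])
        )

    def bottlenecks(self) -> GeneSet:
        return GeneSet(
            "bottlenecks", frozenset(self.table.index[self.table["is_bottleneck"]])
        )


def network_from_edges(raw: RawEdgeList) -> InteractionNetwork:
    """Simple undirected graph over all edge-list pairs."""
    g = nx.Graph()
    g.add_edges_from(raw.pairs())
    return g


def build_disease_network(raw: RawEdgeList, de_genes: GeneSet) -> InteractionNetwork:
    """Induced subgraph on the DE genes; isolated nodes removed.

    Both endpoints of an edge must be differentially expressed for the edge
    to survive.  An empty result is valid (a warning case, not an error).
    """
    full = network_from_edges(raw)
    keep = set(de_genes.genes) & set(full.nodes)
    sub = nx.Graph(full.subgraph(keep))
    sub.remove_nodes_from(list(nx.isolates(sub)))
    return sub


def degree_cutoff_from_degrees(degrees) -> float:
    """AVG + 2*Std over a degree sequence (sample standard deviation)."""
    degrees = np.asarray(degrees, dtype=float)
    if degrees.size < 2:
        raise ValueError("degree cutoff needs at least 2 nodes")
    return float(degrees.mean() + 2.0 * degrees.std(ddof=1))


def degree_hub_cutoff(net: InteractionNetwork) -> float:
    """Degree cut-off AVG + 2*Std (sample standard deviation, ddof=1).

    Degree hubs are the nodes with degree strictly greater than this value;
    on a regular graph Std = 0 and no node qualifies.
    """
    return degree_cutoff_from_degrees([d for _, d in net.degree()])


def betweenness(net: InteractionNetwork) -> dict[str, float]:
    """Normalized betweenness centrality.

    C_b(n) = sum over unordered pairs s != n != t of theta_st(n)/theta_st,
    divided by (N-1)(N-2)/2; node pairs in different components contribute
    no paths.
    """
    return nx.betweenness_centrality(net, normalized=True)


def select_hubs(
    net: InteractionNetwork, bottleneck_quantile: float = 0.5
) -> HubTable:
    """Flag degree hubs and bottlenecks; hubs are the union of the two.

    A node is a bottleneck when its betweenness is positive and at least the
    (1 - q) quantile of the positive betweenness values (q = 0.5 keeps the
    top half, i.e. values >= the median of the nonzero mass; exact ties at
    the threshold are kept).
    """
    if not 0.0 < bottleneck_quantile < 1.0:
        raise ValueError("bottleneck_quantile must be in (0, 1)")
    nodes = sorted(net.nodes)
    deg = np.array([net.degree(n) for n in nodes], dtype=float)
    btw_map = betweenness(net)
    btw = np.array([btw_map[n] for n in nodes], dtype=float)

    cutoff = degree_hub_cutoff(net) if len(nodes) >= 2 else np.inf
    is_degree_hub = deg > cutoff

    positive = btw[btw > 0]
    if positive.size:
        threshold = float(np.quantile(positive, 1.0 - bottleneck_quantile))
    else:
        threshold = np.inf
    is_bottleneck = (btw > 0) & (btw >= threshold)

    table = pd.DataFrame(
        {
            "degree": deg.astype(int),
            "betweenness_norm": btw,
            "is_degree_hub": is_degree_hub,
            "is_bottleneck": is_bottleneck,
            "is_hub": is_degree_hub | is_bottleneck,
        },
        index=pd.Index(nodes, name="gene_id"),
    )
    summary = {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "avg_degree": float(deg.mean()) if len(nodes) else 0.0,
        "degree_std": float(deg.std(ddof=1)) if len(nodes) >= 2 else 0.0,
        "clustering_coefficient": float(nx.average_clustering(net))
        if len(nodes)
        else 0.0,
        "mean_betweenness": float(btw.mean()) if len(nodes) else 0.0,
    }
    return HubTable(
        table,
        degree_cutoff=float(cutoff),
        bottleneck_threshold=float(threshold) if np.isfinite(threshold) else np.nan,
        summary=summary,
    )
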