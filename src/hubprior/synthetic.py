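"""Statistically controlled synthetic inputs for the whole pipeline.

The generator emulates the *structure* the pipeline is built to detect,
without any download: a scale-free interaction network (preferential
attachment), two-group expression in which a few planted hubs are
co-expressed with their interactors in the control group but decorrelated
in the disease group (the differential co-expression signal), a toy
ontology DAG with coherent annotations for the planted neighbourhoods, a
tissue table in which planted genes are brain-enriched, and reference /
housekeeping gene lists.

Correlations are planted by linear mixing: an interactor profile is
``r * hub + sqrt(1 - r^2) * noise``, which has population correlation
exactly ``r`` with the hub.  A positive mean shift applied to planted hubs
*and* their interactors in disease samples makes the planted
neighbourhoods positively differentially expressed (so a positive-direction
DE selection retains them) while leaving hub-interactor expression
differences unchanged; the classification signal therefore comes from the
decorrelation, not the shift.

Everything is a deterministic function of the fixture seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io_formats as io
from .io_formats import (
    AnnotationMap,
    ExpressionMatrix,
    GeneSet,
    GoDag,
    RawEdgeList,
    SampleGroups,
    TissueTable,
)

__all__ = [
    "FixtureSpec",
    "Fixture",
    "generate_network",
    "generate_expression",
    "generate_ontology",
    "generate_tissue_table",
    "generate_fixture",
    "write_fixture",
]

BRAIN_TISSUES = ("whole brain", "prefrontal cortex")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study.

    Defaults are the package's standard conditions: a 300-gene network grown
    with attachment m=2, 20 disease + 20 control samples, 6 planted hubs
    whose neighbourhoods are correlated at r=0.8 in controls and r=0.0 in
    disease, with a +1.0 disease-group mean shift on planted neighbourhoods.
    """

    n_genes: int = 300
    n_samples_per_group: int = 20
    attachment: int = 2
    n_planted_hubs: int = 6
    planted_min_degree: int = 12
    r_control: float = 0.8
    r_disease: float = 0.0
    class_shift: float = 1.0
    ontology_depth: int = 3
    ontology_branching: int = 3
    terms_per_gene: int = 2
    annotation_coherence: float = 0.9
    n_tissues: int = 10
    n_housekeeping: int = 30
    n_reference_decoys: int = 20
    baseline: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if self.n_planted_hubs > self.n_genes:
            raise ValueError("more planted hubs than genes")
        if not (abs(self.r_control) < 1 and abs(self.r_disease) < 1):
            raise ValueError("|r| must be < 1")
        for name in ("n_samples_per_group", "attachment", "n_planted_hubs",
                     "ontology_depth", "ontology_branching", "terms_per_gene",
                     "n_tissues"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Fixture:
    """A complete synthetic input bundle plus the planted ground truth."""

    expression: ExpressionMatrix
    groups: SampleGroups
    edges: RawEdgeList
    dag: GoDag
    annotations: AnnotationMap
    tissues: TissueTable
    reference: GeneSet
    housekeeping: GeneSet
    planted: GeneSet
    planted_neighbours: dict[str, list[str]] = field(default_factory=dict)


def _rng(spec: FixtureSpec, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((spec.seed, stage)))


def _gene_id(i: int) -> str:
    return f"G{i:04d}"


def _plant_network(
    spec: FixtureSpec,
) -> tuple[RawEdgeList, list[str], dict[str, list[str]]]:
    """Grow the scale-free graph and carve out the planted hub neighbourhoods.

    Hubs are chosen greedily in degree-descending order subject to pairwise
    *disjoint closed neighbourhoods*, so every network interactor of a
    planted hub carries that hub's planted correlation undiluted (no
    hub-hub edges, no shared interactors).  Because disjointness quickly
    exhausts high-degree candidates in a preferential-attachment graph,
    each chosen hub is then wired to additional unclaimed nodes until it
    reaches the minimum planted degree, keeping every planted hub
    detectable by the degree / betweenness hub rules.
    """
    rng = _rng(spec, 1)
    graph = nx.barabasi_albert_graph(
        spec.n_genes, spec.attachment, seed=int(rng.integers(2**31))
    )
    by_degree = sorted(graph.degree(), key=lambda kv: (-kv[1], kv[0]))
    median_degree = float(np.median([d for _, d in by_degree]))
    target = min(
        spec.planted_min_degree, max(spec.n_genes // (2 * spec.n_planted_hubs), 2)
    )
    planted: list[int] = []
    claimed: set[int] = set()
    for node, degree in by_degree:
        if len(planted) == spec.n_planted_hubs:
            break
        # a low-degree candidate is fine when the top-up wiring below will
        # still lift it above the median
        if degree <= median_degree and target <= median_degree:
            continue
        closed = {node} | set(graph.neighbors(node))
        if closed & claimed:
            continue
        planted.append(node)
        claimed |= closed
    if len(planted) < spec.n_planted_hubs:
        raise ValueError(
            f"could only place {len(planted)} of {spec.n_planted_hubs} planted "
            "hubs with disjoint neighbourhoods; reduce n_planted_hubs or grow "
            "the network"
        )
    # top up planted degrees with unclaimed nodes (claiming them)
    for hub in planted:
        free = sorted(set(graph.nodes) - claimed - {hub})
        while graph.degree(hub) < target and free:
            pick = free.pop(int(rng.integers(len(free))))
            graph.add_edge(hub, pick)
            claimed.add(pick)

    rows = []
    for a, b in sorted(graph.edges()):
        ga, gb = sorted((_gene_id(a), _gene_id(b)))
        evidence = int(rng.integers(2, 6))
        source = "literature" if rng.random() < 0.5 else "screen"
        rows.append((ga, gb, evidence, source))
    df = (
        pd.DataFrame(rows, columns=list(RawEdgeList.COLUMNS))
        .sort_values(["gene_a", "gene_b"])
        .reset_index(drop=True)
    )
    edges = RawEdgeList(df)
    planted_ids = sorted(_gene_id(n) for n in planted)
    neighbours = {
        _gene_id(n): sorted(_gene_id(m) for m in graph.neighbors(n))
        for n in planted
    }
    return edges, planted_ids, neighbours


def generate_network(spec: FixtureSpec) -> RawEdgeList:
    """Scale-free edge list by preferential attachment with planted hubs.

    Growth with attachment m yields m * (n - m) edges before hub top-up
    wiring.  Evidence counts are drawn at or above the standard filter
    threshold so every generated edge survives reading; sources mix
    literature and screen.
    """
    edges, _, _ = _plant_network(spec)
    return edges


def _assign_neighbourhoods(
    spec: FixtureSpec, net: nx.Graph
) -> tuple[list[str], dict[str, list[str]]]:
    """Planted hubs and interactors for an arbitrary (foreign) graph:
    greedy disjoint closed neighbourhoods in degree-descending order."""
    by_degree = sorted(net.degree(), key=lambda kv: (-kv[1], kv[0]))
    planted: list[str] = []
    taken: set[str] = set()
    neighbours: dict[str, list[str]] = {}
    for gene, _ in by_degree:
        if len(planted) == spec.n_planted_hubs:
            break
        closed = {gene} | set(net.neighbors(gene))
        if closed & taken:
            continue
        planted.append(gene)
        taken |= closed
        neighbours[gene] = sorted(net.neighbors(gene))
    return sorted(planted), neighbours


def generate_expression(
    spec: FixtureSpec, edges: RawEdgeList
) -> tuple[ExpressionMatrix, SampleGroups, GeneSet, dict[str, list[str]]]:
    """Two-group expression with planted differential co-expression.

    Planted hubs are the top-degree network nodes.  Their interactors track
    the hub profile at r_control in control samples and r_disease in
    disease samples; all other genes are independent noise.  The class
    shift is added to disease columns of planted hubs and their interactors,
    and a positive log-scale baseline to everything.
    """
    rng = _rng(spec, 2)
    own_edges, own_planted, own_neighbours = _plant_network(spec)
    if set(map(frozenset, own_edges.pairs())) == set(map(frozenset, edges.pairs())):
        planted, neighbours = own_planted, own_neighbours
    else:  # foreign edge list: derive neighbourhoods greedily
        net = nx.Graph()
        net.add_edges_from(edges.pairs())
        planted, neighbours = _assign_neighbourhoods(spec, net)

    n_pg = spec.n_samples_per_group
    n_s = 2 * n_pg
    genes = sorted(_gene_id(i) for i in range(spec.n_genes))
    samples = [f"D{i + 1:02d}" for i in range(n_pg)] + [
        f"C{i + 1:02d}" for i in range(n_pg)
    ]
    d_cols = np.arange(n_pg)
    c_cols = np.arange(n_pg, n_s)

    X = pd.DataFrame(
        rng.standard_normal((spec.n_genes, n_s)), index=genes, columns=samples
    )
    for hub in planted:
        h = rng.standard_normal(n_s)
        X.loc[hub] = h
        for partner in neighbours[hub]:
            eps = rng.standard_normal(n_s)
            x = np.empty(n_s)
            for cols, r in ((d_cols, spec.r_disease), (c_cols, spec.r_control)):
                x[cols] = r * h[cols] + math.sqrt(1.0 - r * r) * eps[cols]
            X.loc[partner] = x
        shifted = [hub] + neighbours[hub]
        X.loc[shifted, X.columns[d_cols]] += spec.class_shift
    X += spec.baseline

    groups = SampleGroups(
        {s: ("disease" if s.startswith("D") else "control") for s in samples}
    )
    return (
        ExpressionMatrix(X),
        groups,
        GeneSet("planted_hubs", frozenset(planted)),
        neighbours,
    )


def _term_id(i: int) -> str:
    return f"SYN:{i:07d}"


def generate_ontology(
    spec: FixtureSpec,
    planted: GeneSet,
    neighbours: dict[str, list[str]],
    genes: list[str],
) -> tuple[GoDag, AnnotationMap]:
    """Toy ontology tree (plus ~10% extra DAG edges) and annotations.

    The tree has the configured depth and branching (1 + b + b^2 + ... + b^d
    terms).  Each planted neighbourhood is annotated coherently within one
    depth-2 subtree (so within-neighbourhood term pairs share deep
    ancestry); background genes draw terms uniformly.  Extra is_a edges
    always point to strictly shallower terms, preserving acyclicity.
    """
    rng = _rng(spec, 3)
    dag = nx.DiGraph()
    depth_of: dict[str, int] = {}
    counter = 0

    def new_term(depth: int) -> str:
        nonlocal counter
        term = _term_id(counter)
        counter += 1
        dag.add_node(
            term, name=f"synthetic process {counter}", namespace="biological_process"
        )
        depth_of[term] = depth
        return term

    root = new_term(0)
    levels: list[list[str]] = [[root]]
    for depth in range(1, spec.ontology_depth + 1):
        level = []
        for parent in levels[-1]:
            for _ in range(spec.ontology_branching):
                child = new_term(depth)
                relation = "is_a" if rng.random() < 0.85 else "part_of"
                dag.add_edge(child, parent, relation=relation)
                level.append(child)
        levels.append(level)

    # ~10% extra is_a edges toward strictly shallower non-parent terms
    terms = list(dag.nodes)
    n_extra = max(1, len(terms) // 10)
    added = 0
    while added < n_extra:
        child = terms[int(rng.integers(len(terms)))]
        if depth_of[child] < 2:
            continue
        shallow = [t for t in terms if depth_of[t] < depth_of[child]]
        parent = shallow[int(rng.integers(len(shallow)))]
        if dag.has_edge(child, parent):
            continue
        dag.add_edge(child, parent, relation="is_a")
        added += 1

    godag = GoDag(dag)

    # coherent pools: one depth-2 subtree (the node and its descendants)
    depth2 = levels[2] if spec.ontology_depth >= 2 else levels[-1]
    pools: list[list[str]] = []
    for node in depth2:
        pool = [node]
        frontier = [node]
        while frontier:
            nxt = []
            for t in frontier:
                kids = [c for c, p in dag.in_edges(t) if depth_of[c] > depth_of[t]]
                nxt.extend(kids)
            pool.extend(nxt)
            frontier = nxt
        pools.append(sorted(set(pool)))

    non_root = sorted(t for t in terms if t != root)
    mapping: dict[str, frozenset[str]] = {}
    planted_order = sorted(planted.genes)
    coherent_members: dict[str, list[str]] = {}
    fully_coherent: set[str] = set()
    for k, hub in enumerate(planted_order):
        pool = pools[k % len(pools)]
        # the hub's own annotation defines its neighbourhood's function and
        # is always drawn from the pool; interactors are coherent with the
        # configured probability
        fully_coherent.add(hub)
        for gene in [hub] + neighbours.get(hub, []):
            coherent_members[gene] = pool

    for gene in sorted(genes):
        pool = coherent_members.get(gene)
        p_coherent = (
            1.0 if gene in fully_coherent else spec.annotation_coherence
        )
        chosen: set[str] = set()
        while len(chosen) < spec.terms_per_gene:
            if pool is not None and rng.random() < p_coherent:
                chosen.add(pool[int(rng.integers(len(pool)))])
            else:
                chosen.add(non_root[int(rng.integers(len(non_root)))])
        mapping[gene] = frozenset(chosen)
    return godag, AnnotationMap(mapping)


def generate_tissue_table(
    spec: FixtureSpec, planted: GeneSet, genes: list[str]
) -> tuple[TissueTable, GeneSet, GeneSet]:
    """Tissue table plus housekeeping and reference gene lists.

    Planted genes are raised in the two brain tissues to ~4x their
    cross-tissue median; housekeeping genes are uniformly high everywhere
    (max/median well under the default 1.5 fold threshold); the reference
    set is half the planted hubs plus random decoys.
    """
    rng = _rng(spec, 4)
    tissue_names = list(BRAIN_TISSUES) + [
        f"tissue_{i:02d}" for i in range(3, spec.n_tissues + 1)
    ]
    genes = sorted(genes)
    values = pd.DataFrame(
        rng.uniform(5.0, 15.0, size=(len(genes), len(tissue_names))),
        index=genes,
        columns=tissue_names,
    )

    non_planted = [g for g in genes if g not in planted]
    hk = sorted(
        rng.choice(non_planted, size=min(spec.n_housekeeping, len(non_planted)),
                   replace=False)
    )
    for gene in hk:
        level = rng.uniform(8.0, 12.0)
        values.loc[gene] = level * (1.0 + rng.uniform(-0.1, 0.1, len(tissue_names)))
    for gene in sorted(planted.genes):
        med = float(values.loc[gene].median())
        values.loc[gene, list(BRAIN_TISSUES)] = med * 4.0

    planted_sorted = sorted(planted.genes)
    n_ref_planted = math.ceil(len(planted_sorted) / 2)
    decoy_pool = [g for g in non_planted if g not in set(hk)]
    decoys = sorted(
        rng.choice(decoy_pool, size=min(spec.n_reference_decoys, len(decoy_pool)),
                   replace=False)
    )
    reference = GeneSet(
        "reference", frozenset(planted_sorted[:n_ref_planted]) | frozenset(decoys)
    )
    return (
        TissueTable(values),
        GeneSet("housekeeping", frozenset(hk)),
        reference,
    )


def generate_fixture(spec: FixtureSpec | None = None, seed: int | None = None) -> Fixture:
    """Generate the complete input bundle for one seed."""
    if spec is None:
        spec = FixtureSpec()
    if seed is not None:
        spec = FixtureSpec(**{**spec.__dict__, "seed": seed})
    edges = generate_network(spec)
    expr, groups, planted, neighbours = generate_expression(spec, edges)
    dag, ann = generate_ontology(spec, planted, neighbours, expr.gene_ids)
    tissues, housekeeping, reference = generate_tissue_table(
        spec, planted, expr.gene_ids
    )
    return Fixture(
        expression=expr,
        groups=groups,
        edges=edges,
        dag=dag,
        annotations=ann,
        tissues=tissues,
        reference=reference,
        housekeeping=housekeeping,
        planted=planted,
        planted_neighbours=neighbours,
    )


def generate_null_hub_fixture(
    n_hubs: int = 200,
    n_interactors: int = 4,
    n_samples_per_group: int = 20,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SampleGroups, nx.Graph, GeneSet]:
    """Hubs with no differential co-expression: the calibration null.

    Disjoint star neighbourhoods over i.i.d. normal expression — group
    labels carry no signal, so two-sided permutation p-values should be
    approximately uniform.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 91)))
    per_star = 1 + n_interactors
    genes = [_gene_id(i) for i in range(n_hubs * per_star)]
    net = nx.Graph()
    hubs = []
    for h in range(n_hubs):
        hub = genes[h * per_star]
        hubs.append(hub)
        for j in range(1, per_star):
            net.add_edge(hub, genes[h * per_star + j])
    n_s = 2 * n_samples_per_group
    samples = [f"D{i + 1:02d}" for i in range(n_samples_per_group)] + [
        f"C{i + 1:02d}" for i in range(n_samples_per_group)
    ]
    expr = ExpressionMatrix(
        pd.DataFrame(
            rng.standard_normal((len(genes), n_s)) + 8.0,
            index=sorted(genes),
            columns=samples,
        )
    )
    groups = SampleGroups(
        {s: ("disease" if s.startswith("D") else "control") for s in samples}
    )
    return expr, groups, net, GeneSet("null_hubs", frozenset(hubs))


def generate_coherence_fixture(
    n_hubs: int = 30,
    n_planted: int = 10,
    n_interactors: int = 8,
    seed: int = 0,
) -> tuple[GoDag, AnnotationMap, nx.Graph, GeneSet, GeneSet]:
    """Star hubs with separated annotation-similarity distributions.

    The planted hubs and their interactors are annotated fully coherently
    within per-hub ontology subtrees; the remaining hubs draw terms
    uniformly, so only the planted hubs reach high median hub-interactor
    similarity.
    """
    per_star = 1 + n_interactors
    genes = [_gene_id(i) for i in range(n_hubs * per_star)]
    net = nx.Graph()
    hubs, neighbours = [], {}
    for h in range(n_hubs):
        hub = genes[h * per_star]
        partners = genes[h * per_star + 1 : (h + 1) * per_star]
        hubs.append(hub)
        neighbours[hub] = partners
        for p in partners:
            net.add_edge(hub, p)
    planted = GeneSet("planted_coherent", frozenset(hubs[:n_planted]))
    spec = FixtureSpec(
        n_genes=max(len(genes), 10), annotation_coherence=1.0, seed=seed
    )
    dag, ann = generate_ontology(
        spec, planted, {h: neighbours[h] for h in planted.genes}, genes
    )
    return dag, ann, net, GeneSet("hubs", frozenset(hubs)), planted


#: canonical fixture file names, used by both the writer and the pipeline
FIXTURE_FILES = {
    "expression": "expression.tsv",
    "groups": "groups.tsv",
    "interactions": "interactions.tsv",
    "obo": "ontology.obo",
    "gaf": "annotations.gaf",
    "tissues": "tissues.tsv",
    "reference": "reference_genes.txt",
    "housekeeping": "housekeeping_genes.txt",
}


def write_fixture(fixture: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Write every fixture file in its standard plain-text format."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / v for k, v in FIXTURE_FILES.items()}
    io.write_expression(fixture.expression, paths["expression"])
    io.write_groups(fixture.groups, paths["groups"])
    io.write_interactions(fixture.edges, paths["interactions"])
    io.write_obo(fixture.dag, paths["obo"])
    io.write_annotations(fixture.annotations, paths["gaf"])
    io.write_tissue_table(fixture.tissues, paths["tissues"])
    io.write_gene_set(fixture.reference, paths["reference"])
    io.write_gene_set(fixture.housekeeping, paths["housekeeping"])
    truth = outdir / "ground_truth.tsv"
    with open(truth, "w") as fh:
        fh.write("gene_id\trole\n")
        for hub in sorted(fixture.planted.genes):
            fh.write(f"{hub}\tplanted_hub\n")
    paths["ground_truth"] = truth
    return paths
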