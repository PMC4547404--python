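"""Readers, writers and in-memory domain types for every file the pipeline touches.

All downstream stages operate on the validated objects defined here:
expression matrices with two-group sample labels, evidence-annotated
interaction edge lists, a GO-style ontology DAG with typed (``is_a`` /
``part_of``) edges, gene→term annotation maps, tissue expression tables and
plain gene sets.

Formats are deliberately plain text: TSV for matrices and edge lists (a 2- or
3-column SIF dialect is also accepted for interactions), OBO 1.2 for the
ontology, GAF 2.x for annotations, and newline-delimited lists for gene sets.
Identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

DISEASE = "disease"
CONTROL = "control"

#: default semantic-contribution weights for ontology edge relations
DEFAULT_RELATION_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes × samples real-valued expression matrix.

    Values are taken as given (assumed already normalized / log scale).
    Gene and sample identifiers must be unique and every value finite.
    """

    values: pd.DataFrame  # index: gene ids, columns: sample ids

    def __post_init__(self) -> None:
        if self.values.size == 0:
            raise FormatError("expression matrix is empty")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r} in expression matrix")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r} in expression matrix")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression matrix contains non-numeric values")
        if not np.isfinite(arr).all():
            gi, si = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                f"non-finite expression value at gene {self.values.index[gi]!r}, "
                f"sample {self.values.columns[si]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.values.shape == other.values.shape
            and self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.allclose(self.values.to_numpy(), other.values.to_numpy())
        )


@dataclass(frozen=True)
class SampleGroups:
    """Two-group (disease / control) labelling of samples."""

    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - {DISEASE, CONTROL}
        if bad:
            raise FormatError(f"unknown group label(s): {sorted(bad)}")
        if not self.disease_samples or not self.control_samples:
            raise FormatError("both disease and control groups must be non-empty")

    @property
    def disease_samples(self) -> list[str]:
        return [s for s, g in self.labels.items() if g == DISEASE]

    @property
    def control_samples(self) -> list[str]:
        return [s for s, g in self.labels.items() if g == CONTROL]

    def validate_against(self, expr: ExpressionMatrix) -> None:
        """Require every sample of *expr* to be labelled."""
        missing = [s for s in expr.sample_ids if s not in self.labels]
        if missing:
            raise FormatError(f"sample {missing[0]!r} has no group label")

    def swapped(self) -> "SampleGroups":
        """Return the labelling with disease and control exchanged."""
        flip = {DISEASE: CONTROL, CONTROL: DISEASE}
        return SampleGroups({s: flip[g] for s, g in self.labels.items()})


@dataclass
class RawEdgeList:
    """Undirected interaction records with per-edge evidence counts.

    ``edges`` columns: gene_a, gene_b, evidence_count, source. Pairs are
    unordered and unique; self-loops are forbidden.
    """

    edges: pd.DataFrame

    COLUMNS = ("gene_a", "gene_b", "evidence_count", "source")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.edges.columns)
        if missing:
            raise FormatError(f"edge list missing columns {sorted(missing)}")
        if (self.edges["gene_a"] == self.edges["gene_b"]).any():
            raise FormatError("edge list contains a self-loop")
        if (self.edges["evidence_count"].to_numpy() < 0).any():
            raise FormatError("negative evidence count")

    def __len__(self) -> int:
        return len(self.edges)

    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.edges["gene_a"], self.edges["gene_b"]))


@dataclass
class GoDag:
    """Ontology DAG: directed edges child → parent, typed is_a / part_of.

    Each relation carries a semantic-contribution weight in (0, 1) used by
    the Wang similarity recursion.
    """

    graph: nx.DiGraph  # edge attr "relation"
    weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RELATION_WEIGHTS)
    )

    def __post_init__(self) -> None:
        for rel, w in self.weights.items():
            if not 0.0 < w < 1.0:
                raise FormatError(f"relation weight {rel}={w} outside (0,1)")
        if not nx.is_directed_acyclic_graph(self.graph):
            cyc = nx.find_cycle(self.graph)
            raise FormatError(f"ontology contains a cycle through {cyc[0][0]!r}")

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def ancestor_closure(self, term: str) -> set[str]:
        """All ancestors of *term* including the term itself (the set T_A)."""
        if term not in self.graph:
            raise KeyError(f"unknown ontology term {term!r}")
        return {term} | nx.descendants(self.graph, term)  # edges point rootward

    def parents(self, term: str) -> list[tuple[str, str]]:
        """(parent, relation) pairs of *term*."""
        return [
            (p, d["relation"]) for _, p, d in self.graph.out_edges(term, data=True)
        ]

    def namespace(self, term: str) -> str | None:
        return self.graph.nodes[term].get("namespace")


@dataclass
class AnnotationMap:
    """Mapping gene id → set of ontology term ids (single namespace)."""

    mapping: dict[str, frozenset[str]]

    def terms_for(self, gene: str) -> frozenset[str]:
        return self.mapping.get(gene, frozenset())

    def annotated_genes(self) -> set[str]:
        return {g for g, ts in self.mapping.items() if ts}

    def __contains__(self, gene: str) -> bool:
        return bool(self.mapping.get(gene))


@dataclass
class TissueTable:
    """Gene × tissue expression levels (non-negative, finite)."""

    values: pd.DataFrame  # index: gene ids, columns: tissue names

    def __post_init__(self) -> None:
        if self.values.columns.has_duplicates:
            raise FormatError("duplicate tissue name")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise FormatError("non-finite tissue expression value")
        if (arr < 0).any():
            gi, ti = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative tissue expression for gene "
                f"{self.values.index[gi]!r} in {self.values.columns[ti]!r}"
            )

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers."""

    name: str
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __iter__(self):
        return iter(sorted(self.genes))


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def read_expression(
    path_matrix: str | Path, path_groups: str | Path
) -> tuple[ExpressionMatrix, SampleGroups]:
    """Read a genes × samples TSV plus a two-column sample→group file.

    Rows whose gene id occurs more than once (multiple probes for one gene)
    are collapsed by the arithmetic mean. The resulting gene order is sorted,
    so the outcome is independent of input row order.
    """
    df = pd.read_csv(path_matrix, sep="\t", index_col=0)
    if df.size == 0:
        raise FormatError(f"{path_matrix}: empty expression matrix")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            gene = df.index[(bad | df[col].isna()).to_numpy()][0]
            raise FormatError(
                f"{path_matrix}: non-numeric or missing value at gene "
                f"{gene!r}, sample {col!r}"
            )
        df[col] = coerced
    df.index = df.index.astype(str)
    collapsed = df.groupby(level=0).mean().sort_index()
    expr = ExpressionMatrix(collapsed.astype(float))
    groups = read_groups(path_groups)
    groups.validate_against(expr)
    return expr, groups


def read_groups(path: str | Path) -> SampleGroups:
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            sample, label = parts[0], parts[1].lower()
            if lineno == 1 and label not in (DISEASE, CONTROL):
                continue  # header row
            labels[sample] = label
    return SampleGroups(labels)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.rename_axis("gene_id").to_csv(path, sep="\t")


def write_groups(groups: SampleGroups, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, label in groups.labels.items():
            fh.write(f"{sample}\t{label}\n")


# ---------------------------------------------------------------------------
# Interactions
# ---------------------------------------------------------------------------


def _merge_duplicate_pairs(rows: pd.DataFrame) -> pd.DataFrame:
    """Merge duplicate unordered pairs.

    Evidence counts from the same source are summed; across different
    sources the maximum is kept and the merged record is tagged "both".
    """
    a = rows[["gene_a", "gene_b"]].min(axis=1)
    b = rows[["gene_a", "gene_b"]].max(axis=1)
    rows = rows.assign(gene_a=a, gene_b=b)
    per_source = (
        rows.groupby(["gene_a", "gene_b", "source"], as_index=False)[
            "evidence_count"
        ].sum()
    )

    def _combine(grp: pd.DataFrame) -> pd.Series:
        if len(grp) == 1:
            return grp.iloc[0][["evidence_count", "source"]]
        return pd.Series(
            {"evidence_count": grp["evidence_count"].max(), "source": "both"}
        )

    merged = (
        per_source.groupby(["gene_a", "gene_b"])
        .apply(_combine, include_groups=False)
        .reset_index()
    )
    return merged[["gene_a", "gene_b", "evidence_count", "source"]]


def read_interactions(path: str | Path, min_evidence: int = 2) -> RawEdgeList:
    """Read an interaction edge list and apply the evidence filter.

    TSV dialect: columns gene_a, gene_b, evidence_count, source (header
    optional).  SIF dialect (2 or 3 whitespace-separated columns) carries no
    evidence; such rows get evidence_count=1 and source "sif".

    Self-loops are dropped, duplicate unordered pairs merged, and pairs from
    the "literature" source with fewer than *min_evidence* pieces of evidence
    removed.  Pairs from interaction screens (or any non-literature source)
    are kept regardless, mirroring how systematic Y2H screen pairs enter the
    network unfiltered.
    """
    if min_evidence < 0:
        raise ValueError("min_evidence must be >= 0")
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if lineno == 1 and parts[0].lower() in ("gene_a", "genea", "source"):
                continue  # header
            if len(parts) == 4:
                ga, gb, ev, src = parts
                try:
                    evidence = int(ev)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: evidence_count {ev!r} is not an integer"
                    ) from exc
                if evidence < 0:
                    raise FormatError(f"{path}:{lineno}: negative evidence count")
            elif len(parts) == 3:  # SIF: nodeA relation nodeB
                ga, _, gb = parts
                evidence, src = 1, "sif"
            elif len(parts) == 2:  # SIF 2-column dialect
                ga, gb = parts
                evidence, src = 1, "sif"
            else:
                raise FormatError(
                    f"{path}:{lineno}: expected 2, 3 or 4 columns, got {len(parts)}"
                )
            if ga == gb:
                continue  # self-loop
            records.append((ga, gb, evidence, src))
    df = pd.DataFrame(records, columns=list(RawEdgeList.COLUMNS))
    if len(df):
        df = _merge_duplicate_pairs(df)
        keep = (df["source"] != "literature") | (df["evidence_count"] >= min_evidence)
        df = df[keep].reset_index(drop=True)
    df = df.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
    return RawEdgeList(df)


def write_interactions(raw: RawEdgeList, path: str | Path) -> None:
    raw.edges.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Ontology (OBO 1.2) and annotations (GAF 2.x)
# ---------------------------------------------------------------------------


def read_obo(
    path: str | Path, weights: Mapping[str, float] | None = None
) -> GoDag:
    """Parse an OBO 1.2 ontology into a typed child→parent DAG.

    Obsolete terms are skipped and only ``is_a`` and ``part_of`` edges are
    retained.  Acyclicity is verified.
    """
    multigraph = obonet.read_obo(path)  # skips obsolete terms
    dag = nx.DiGraph()
    for node, data in multigraph.nodes(data=True):
        dag.add_node(
            node, name=data.get("name", ""), namespace=data.get("namespace", "")
        )
    for child, parent, key in multigraph.edges(keys=True):
        if key in ("is_a", "part_of"):
            dag.add_edge(child, parent, relation=key)
    return GoDag(dag, dict(weights or DEFAULT_RELATION_WEIGHTS))


def write_obo(dag: GoDag, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: hubprior_synthetic\n")
        for term in sorted(dag.graph.nodes):
            data = dag.graph.nodes[term]
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {data.get('name', term)}\n")
            if data.get("namespace"):
                fh.write(f"namespace: {data['namespace']}\n")
            for parent, rel in sorted(dag.parents(term)):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")


_ASPECTS = {"P", "F", "C"}


def read_annotations(
    path: str | Path, namespace: str = "P", dag: GoDag | None = None
) -> AnnotationMap:
    """Read a GAF 2.x annotation file restricted to one namespace (P/F/C).

    Rows with a NOT qualifier are dropped.  When *dag* is given, annotations
    to terms absent from it are dropped with a logged count.
    """
    if namespace not in _ASPECTS:
        raise ValueError(f"namespace must be one of {sorted(_ASPECTS)}")
    mapping: dict[str, set[str]] = {}
    unknown = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            gene, qualifier, term, aspect = cols[1], cols[3], cols[4], cols[8]
            if "NOT" in qualifier.split("|"):
                continue
            if aspect != namespace:
                continue
            if dag is not None and term not in dag:
                unknown += 1
                continue
            mapping.setdefault(gene, set()).add(term)
    if unknown:
        logger.warning("dropped %d annotations to unknown terms", unknown)
    return AnnotationMap({g: frozenset(ts) for g, ts in mapping.items()})


_ASPECT_OF_NAMESPACE = {
    "biological_process": "P",
    "molecular_function": "F",
    "cellular_component": "C",
}


def write_annotations(
    ann: AnnotationMap, path: str | Path, aspect: str = "P"
) -> None:
    """Write an AnnotationMap as a minimal GAF 2.2 file."""
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for gene in sorted(ann.mapping):
            for term in sorted(ann.mapping[gene]):
                cols = [
                    "HUBPRIOR", gene, gene, "involved_in", term, "SYN:0000001",
                    "IEA", "", aspect, gene, "", "protein", "taxon:9606",
                    "20160101", "HUBPRIOR", "", "",
                ]
                fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Tissue table and gene sets
# ---------------------------------------------------------------------------


def read_tissue_table(path: str | Path) -> TissueTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    try:
        return TissueTable(df.astype(float))
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric tissue value") from exc


def write_tissue_table(table: TissueTable, path: str | Path) -> None:
    table.values.rename_axis("gene_id").to_csv(path, sep="\t")


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a newline-delimited gene list; duplicates are deduplicated."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return GeneSet(name or Path(path).stem, frozenset(genes))


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(gene_set.genes):
            fh.write(gene + "\n")


def make_gene_set(name: str, genes: Iterable[str]) -> GeneSet:
    return GeneSet(name, frozenset(genes))
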