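"""Wang S-value recursion, term/gene similarity, median-based hub selection."""

import itertools

import networkx as nx
import numpy as np
import pytest

from hubprior.io_formats import AnnotationMap, GoDag
from hubprior.semantic_similarity import (
    gene_similarity,
    prioritize_by_semsim,
    semantic_profile,
    term_similarity,
)
from hubprior.synthetic import generate_coherence_fixture


def dag_from_edges(edge_list, weights=None):
    g = nx.DiGraph()
    nodes = {n for e in edge_list for n in e[:2]}
    g.add_nodes_from(nodes, namespace="biological_process")
    for child, parent, *rel in edge_list:
        g.add_edge(child, parent, relation=rel[0] if rel else "is_a")
    return GoDag(g, weights or {"is_a": 0.8, "part_of": 0.6})


@pytest.fixture
def chain():
    # A is_a P is_a R
    return dag_from_edges([("A", "P"), ("P", "R")])


@pytest.fixture
def siblings():
    return dag_from_edges([("A", "R"), ("B", "R")])


class TestSemanticProfile:
    def test_root_only(self):
        g = nx.DiGraph()
        g.add_node("R", namespace="biological_process")
        prof = semantic_profile(GoDag(g), "R")
        assert prof.s_values == {"R": 1.0}
        assert prof.sv == 1.0

    def test_chain_hand_recursion(self, chain):
        prof = semantic_profile(chain, "A")
        assert prof.s_values["A"] == 1.0
        assert prof.s_values["P"] == pytest.approx(0.8, abs=1e-9)
        assert prof.s_values["R"] == pytest.approx(0.64, abs=1e-9)
        assert prof.sv == pytest.approx(2.44, abs=1e-9)

    def test_diamond_takes_max_over_paths(self):
        dag = dag_from_edges([("A", "P1"), ("A", "P2"), ("P1", "R"), ("P2", "R")])
        prof = semantic_profile(dag, "A")
        assert prof.s_values["R"] == pytest.approx(0.64, abs=1e-9)

    def test_part_of_weight_applies(self):
        dag = dag_from_edges([("A", "R", "part_of")])
        assert semantic_profile(dag, "A").s_values["R"] == pytest.approx(0.6)

    def test_unknown_term_raises(self, chain):
        with pytest.raises(KeyError):
            semantic_profile(chain, "nope")

    def test_profile_strictly_decreases_along_chain(self):
        dag = dag_from_edges([(f"t{i}", f"t{i + 1}") for i in range(6)])
        prof = semantic_profile(dag, "t0")
        vals = [prof.s_values[f"t{i}"] for i in range(7)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_path_product_oracle_on_random_dags(self, seed):
        """S_A(t) equals max over A->t paths of the product of edge weights."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 21))
        edges = []
        for child in range(1, n):
            parents = rng.choice(child, size=min(child, 1 + int(rng.integers(2))),
                                 replace=False)
            for p in parents:
                rel = "is_a" if rng.random() < 0.7 else "part_of"
                edges.append((f"t{child}", f"t{p}", rel))
        dag = dag_from_edges(edges)
        term = f"t{n - 1}"
        prof = semantic_profile(dag, term)
        w = dag.weights
        for t in prof.s_values:
            if t == term:
                assert prof.s_values[t] == 1.0
                continue
            best = 0.0
            for path in nx.all_simple_paths(dag.graph, term, t):
                prod = 1.0
                for u, v in zip(path, path[1:]):
                    prod *= w[dag.graph.edges[u, v]["relation"]]
                best = max(best, prod)
            assert prof.s_values[t] == pytest.approx(best, abs=1e-12)


class TestTermSimilarity:
    def test_self_similarity_is_one(self, chain):
        for t in ("A", "P", "R"):
            assert term_similarity(chain, t, t) == pytest.approx(1.0, abs=1e-12)

    def test_siblings_hand_value(self, siblings):
        assert term_similarity(siblings, "A", "B") == pytest.approx(
            (0.8 + 0.8) / (1.8 + 1.8), abs=1e-9
        )

    def test_term_vs_parent_hand_value(self, chain):
        expected = (0.8 + 1 + 0.64 + 0.8) / (2.44 + 1.8)
        assert term_similarity(chain, "A", "P") == pytest.approx(expected, abs=1e-9)

    def test_symmetric(self, chain):
        assert term_similarity(chain, "A", "R") == term_similarity(chain, "R", "A")

    def test_disjoint_roots_give_zero(self):
        dag = dag_from_edges([("A", "R1"), ("B", "R2")])
        assert term_similarity(dag, "A", "B") == 0.0


class TestGeneSimilarity:
    def test_identical_singleton_annotations(self, siblings):
        ann = AnnotationMap({"g1": frozenset({"A"}), "g2": frozenset({"A"})})
        assert gene_similarity(siblings, ann, "g1", "g2") == pytest.approx(1.0)

    def test_all_pairs_average_hand_value(self, siblings):
        ann = AnnotationMap({"g1": frozenset({"A"}), "g2": frozenset({"A", "B"})})
        sim_ab = (0.8 + 0.8) / 3.6
        expected = (1.0 + sim_ab) / 2
        assert gene_similarity(siblings, ann, "g1", "g2") == pytest.approx(
            expected, abs=1e-9
        )

    def test_best_match_average_differs_from_all_pairs(self, siblings):
        ann = AnnotationMap({"g1": frozenset({"A"}), "g2": frozenset({"A", "B"})})
        bma = gene_similarity(siblings, ann, "g1", "g2", combine="best_match_avg")
        # row max = 1; column maxes = 1 and sim(A,B)
        expected = (1.0 + 1.0 + (0.8 + 0.8) / 3.6) / 3
        assert bma == pytest.approx(expected, abs=1e-9)

    def test_symmetry_on_random_annotation_sets(self):
        rng = np.random.default_rng(2)
        dag = dag_from_edges(
            [(f"t{i}", f"t{int(rng.integers(i))}") for i in range(1, 15)]
        )
        terms = sorted(dag.terms)
        for _ in range(20):
            s1 = frozenset(rng.choice(terms, size=2, replace=False))
            s2 = frozenset(rng.choice(terms, size=3, replace=False))
            ann = AnnotationMap({"a": s1, "b": s2})
            assert gene_similarity(dag, ann, "a", "b") == pytest.approx(
                gene_similarity(dag, ann, "b", "a"), abs=1e-12
            )

    def test_adding_shared_ancestor_lifts_weakly_related_genes(self, siblings):
        # for terms whose own similarity is below their similarity to the
        # shared ancestor, annotating both genes with that ancestor raises
        # the all-pairs average (the effect reverses for already strongly
        # related terms, where the extra cross-pairs dilute the mean)
        ann1 = AnnotationMap({"g1": frozenset({"A"}), "g2": frozenset({"B"})})
        base = gene_similarity(siblings, ann1, "g1", "g2")
        ann2 = AnnotationMap(
            {"g1": frozenset({"A", "R"}), "g2": frozenset({"B", "R"})}
        )
        assert gene_similarity(siblings, ann2, "g1", "g2") > base

    def test_unannotated_gene_raises(self, chain):
        ann = AnnotationMap({"g1": frozenset({"A"}), "g2": frozenset()})
        with pytest.raises(ValueError, match="g2"):
            gene_similarity(chain, ann, "g1", "g2")


class TestPrioritizeBySemsim:
    def _net(self, hub, partners):
        g = nx.Graph()
        for p in partners:
            g.add_edge(hub, p)
        return g

    def test_median_exactly_at_threshold_not_selected(self, monkeypatch):
        import hubprior.semantic_similarity as ss

        sims = iter([0.2, 0.5, 0.9])
        monkeypatch.setattr(
            ss, "gene_similarity", lambda *a, **k: next(sims)
        )
        dag = dag_from_edges([("A", "R")])
        ann = AnnotationMap({g: frozenset({"A"}) for g in "hxyz"})
        res = ss.prioritize_by_semsim(dag, ann, self._net("h", "xyz"), ["h"])
        assert res.table.loc["h", "median_similarity"] == pytest.approx(0.5)
        assert not res.table.loc["h", "selected"]

    def test_even_count_median_is_mean_of_central_values(self, monkeypatch):
        import hubprior.semantic_similarity as ss

        sims = iter([0.6, 0.8])
        monkeypatch.setattr(ss, "gene_similarity", lambda *a, **k: next(sims))
        dag = dag_from_edges([("A", "R")])
        ann = AnnotationMap({g: frozenset({"A"}) for g in "hxy"})
        res = ss.prioritize_by_semsim(dag, ann, self._net("h", "xy"), ["h"])
        assert res.table.loc["h", "median_similarity"] == pytest.approx(0.7)
        assert bool(res.table.loc["h", "selected"])

    def test_unannotated_hub_and_interactors_excluded(self, chain):
        ann = AnnotationMap(
            {"h1": frozenset({"A"}), "x": frozenset(), "h2": frozenset()}
        )
        net = self._net("h1", ["x"])
        net.add_edge("h2", "h1")
        res = prioritize_by_semsim(chain, ann, net, ["h1", "h2"])
        assert res.excluded["h2"] == "hub unannotated"
        # h1's only partners are unannotated x and h2 -> h2 annotated? no
        assert "h1" not in res.table.index or res.table.loc["h1", "n_scored_interactors"] == 0

    def test_coherence_fixture_selects_exactly_planted(self):
        dag, ann, net, hubs, planted = generate_coherence_fixture(seed=3)
        res = prioritize_by_semsim(dag, ann, net, hubs)
        assert res.selected_hubs().genes == planted.genes
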