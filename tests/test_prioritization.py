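"""Hub-set combination, reference overlap, tissue filter, GO enrichment."""

from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from hubprior.io_formats import AnnotationMap, GoDag, TissueTable, make_gene_set
from hubprior.prioritization import (
    combine_hubs,
    go_enrichment,
    reference_overlap,
    tissue_filter,
)


class TestCombineHubs:
    def test_disjoint_22_plus_10_gives_32(self):
        a = make_gene_set("netvar", {f"a{i}" for i in range(22)})
        b = make_gene_set("semsim", {f"b{i}" for i in range(10)})
        combined = combine_hubs(a, b)
        assert len(combined) == 32

    def test_identical_sets_collapse(self):
        a = make_gene_set("netvar", {"x", "y"})
        combined = combine_hubs(a, a)
        assert len(combined) == 2
        assert (combined.table["provenance"] == "both").all()

    def test_single_source_provenance(self):
        combined = combine_hubs(
            make_gene_set("netvar", {"x"}), make_gene_set("semsim", set())
        )
        assert combined.table.loc["x", "provenance"] == "netvar"

    def test_union_size_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = set(rng.choice(50, size=12, replace=False).astype(str))
            b = set(rng.choice(50, size=8, replace=False).astype(str))
            combined = combine_hubs(make_gene_set("a", a), make_gene_set("b", b))
            assert len(combined) == len(a) + len(b) - len(a & b)

    def test_ordering_both_first_then_abs_avgpcc(self):
        a = make_gene_set("netvar", {"x", "y", "z"})
        b = make_gene_set("semsim", {"x", "w"})
        combined = combine_hubs(
            a, b, avg_pcc={"x": -0.3, "y": 0.9, "z": -0.5}
        )
        assert list(combined.table.index) == ["x", "y", "z", "w"]


class TestReferenceOverlap:
    def test_simple_intersection(self):
        prioritized = combine_hubs(
            make_gene_set("a", {"PSEN1", "TRAF1", "LZTS2"}), make_gene_set("b", set())
        )
        hits = reference_overlap(
            prioritized, make_gene_set("ref", {"PSEN1", "TRAF1", "APOE"})
        )
        assert hits.genes == frozenset({"PSEN1", "TRAF1"})
        assert prioritized.table["reference_hit"].sum() == 2

    def test_disjoint_sets_empty(self):
        prioritized = combine_hubs(make_gene_set("a", {"x"}), make_gene_set("b", set()))
        assert len(reference_overlap(prioritized, make_gene_set("r", {"y"}))) == 0

    def test_subset_returns_whole_list(self):
        prioritized = combine_hubs(make_gene_set("a", {"x", "y"}), make_gene_set("b", set()))
        hits = reference_overlap(prioritized, make_gene_set("r", {"x", "y", "z"}))
        assert hits.genes == frozenset({"x", "y"})


def tissue_table(rows, tissues):
    return TissueTable(pd.DataFrame(rows).T.set_axis(tissues, axis=1))


class TestTissueFilter:
    def _table(self):
        values = pd.DataFrame(
            {
                "brainy": [30.0] + [10.0] * 9,
                "flat": [10.0] * 10,
                "hk": [20.0] * 10,
                "missing_not_here": [1.0] * 10,
            },
            index=[f"t{i}" for i in range(10)],
        ).T
        values.columns = ["whole brain"] + [f"tissue_{i}" for i in range(1, 10)]
        return TissueTable(values.drop(index="missing_not_here"))

    def _prioritized(self, genes):
        return combine_hubs(make_gene_set("a", set(genes)), make_gene_set("b", set()))

    def test_brain_enriched_gene_passes(self):
        res = tissue_filter(
            self._prioritized({"brainy"}), self._table(), ["whole brain"],
            make_gene_set("hk", set()), fold=1.5,
        )
        assert "brainy" in res.passed

    def test_uniform_gene_fails(self):
        res = tissue_filter(
            self._prioritized({"flat"}), self._table(), ["whole brain"],
            make_gene_set("hk", set()), fold=1.5,
        )
        assert "flat" not in res.passed

    def test_housekeeping_reported_not_passed(self):
        table = self._table()
        table.values.loc["hk", "whole brain"] = 60.0  # brain-high profile
        res = tissue_filter(
            self._prioritized({"hk"}), table, ["whole brain"],
            make_gene_set("hk", {"hk"}), fold=1.5,
        )
        assert "hk" not in res.passed
        assert "hk" in res.housekeeping

    def test_unmeasured_gene_flagged(self):
        res = tissue_filter(
            self._prioritized({"ghost"}), self._table(), ["whole brain"],
            make_gene_set("hk", set()),
        )
        assert "ghost" in res.unmeasured
        assert "ghost" not in res.passed

    def test_scale_invariance_of_pass_status(self):
        table = self._table()
        res1 = tissue_filter(
            self._prioritized({"brainy", "flat"}), table, ["whole brain"],
            make_gene_set("hk", set()),
        )
        table.values.loc["brainy"] *= 17.0
        table.values.loc["flat"] *= 0.01
        res2 = tissue_filter(
            self._prioritized({"brainy", "flat"}), table, ["whole brain"],
            make_gene_set("hk", set()),
        )
        assert res1.passed.genes == res2.passed.genes

    def test_unknown_target_tissue_rejected(self):
        with pytest.raises(ValueError, match="unknown target"):
            tissue_filter(
                self._prioritized({"flat"}), self._table(), ["no such tissue"],
                make_gene_set("hk", set()),
            )


def hypergeom_tail_oracle(k, N, K, n):
    """P(X >= k) by direct combinatorial enumeration."""
    return sum(
        comb(K, i) * comb(N - K, n - i) / comb(N, n)
        for i in range(k, min(n, K) + 1)
    )


class TestGoEnrichment:
    def _dag(self):
        g = nx.DiGraph()
        for t in ("R", "T1", "T2"):
            g.add_node(t, namespace="biological_process")
        g.add_edge("T1", "R", relation="is_a")
        g.add_edge("T2", "R", relation="is_a")
        return GoDag(g)

    def test_term_covering_background_has_p_one(self):
        genes = [f"g{i}" for i in range(10)]
        ann = AnnotationMap({g: frozenset({"T1"}) for g in genes})
        rows = go_enrichment(
            make_gene_set("list", set(genes[:3])),
            make_gene_set("bg", set(genes)),
            ann, self._dag(),
        )
        assert np.allclose(rows["p_value"], 1.0)

    def test_exact_tail_matches_combinatorial_oracle(self):
        genes = [f"g{i}" for i in range(100)]
        annotated = set(genes[:5])
        ann = AnnotationMap(
            {g: frozenset({"T1"} if g in annotated else set()) for g in genes}
        )
        listed = set(genes[:3]) | set(genes[50:57])  # k=3 of K=5, n=10
        rows = go_enrichment(
            make_gene_set("list", listed), make_gene_set("bg", set(genes)),
            ann, self._dag(),
        ).set_index("term_id")
        expected = hypergeom_tail_oracle(3, 100, 5, 10)
        assert rows.loc["T1", "p_value"] == pytest.approx(expected, rel=1e-12)
        assert rows.loc["T1", "list_count"] == 3

    def test_zero_hits_give_p_one(self):
        genes = [f"g{i}" for i in range(20)]
        ann = AnnotationMap(
            {g: frozenset({"T1"} if i < 5 else {"T2"}) for i, g in enumerate(genes)}
        )
        rows = go_enrichment(
            make_gene_set("list", set(genes[10:13])), make_gene_set("bg", set(genes)),
            ann, self._dag(),
        ).set_index("term_id")
        assert rows.loc["T1", "p_value"] == pytest.approx(1.0)

    def test_annotations_propagate_to_ancestors(self):
        genes = [f"g{i}" for i in range(10)]
        ann = AnnotationMap({g: frozenset({"T1"}) for g in genes})
        rows = go_enrichment(
            make_gene_set("list", set(genes[:2])), make_gene_set("bg", set(genes)),
            ann, self._dag(),
        )
        assert set(rows["term_id"]) == {"T1", "R"}

    def test_bh_adjustment_is_monotone(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(60)]
        terms = [f"T{i}" for i in range(8)]
        g = nx.DiGraph()
        g.add_node("R", namespace="biological_process")
        for t in terms:
            g.add_node(t, namespace="biological_process")
            g.add_edge(t, "R", relation="is_a")
        ann = AnnotationMap(
            {
                gene: frozenset(rng.choice(terms, size=2, replace=False))
                for gene in genes
            }
        )
        rows = go_enrichment(
            make_gene_set("list", set(genes[:12])), make_gene_set("bg", set(genes)),
            ann, GoDag(g),
        )
        ordered = rows.sort_values("p_value")["adjusted_p"].to_numpy()
        assert (np.diff(ordered) >= -1e-12).all()

    def test_list_must_be_subset_of_background(self):
        ann = AnnotationMap({"a": frozenset({"T1"})})
        with pytest.raises(ValueError, match="subset"):
            go_enrichment(
                make_gene_set("list", {"zz"}), make_gene_set("bg", {"a"}),
                ann, self._dag(),
            )

    def test_empty_list_gives_empty_result(self):
        ann = AnnotationMap({"a": frozenset({"T1"})})
        rows = go_enrichment(
            make_gene_set("list", set()), make_gene_set("bg", {"a"}),
            ann, self._dag(),
        )
        assert rows.empty
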