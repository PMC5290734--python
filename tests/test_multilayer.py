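import networkx as nx
import pytest

from complexome import (
    common_nodes,
    in_out_connections,
    rank_candidates,
    screen_high_bc_low_k,
    subset_clustering_ratio,
)
from complexome.graph_io import LayerFamily
from complexome.multilayer import join_annotations, subtractive_report

from conftest import as_net


def family_of(node_sets_by_layer):
    fam = LayerFamily()
    for (tissue, cond), nodes in node_sets_by_layer.items():
        g = nx.Graph()
        g.add_nodes_from(nodes)
        fam.add(tissue, cond, as_net(g, f"{tissue}_{cond}"))
    return fam


class TestCommonNodes:
    def test_strict_intersection(self):
        fam = family_of({
            ("t1", "disease"): {"a", "b", "c"},
            ("t2", "disease"): {"b", "c", "d"},
            ("t3", "disease"): {"b", "c"},
            ("t1", "normal"): {"b", "x"},
        })
        rep = common_nodes(fam)
        assert rep.common_disease == {"b", "c"}
        assert rep.common_normal == {"b", "x"}
        assert rep.common_both == {"b"}
        assert rep.union_normal_disease == {"b", "c", "x"}

    def test_disjoint_layers_empty(self):
        fam = family_of({
            ("t1", "disease"): {"a"},
            ("t2", "disease"): {"b"},
            ("t1", "normal"): {"c"},
        })
        assert common_nodes(fam).common_disease == set()

    def test_missing_condition_errors(self):
        fam = family_of({("t1", "disease"): {"a"}})
        with pytest.raises(ValueError):
            common_nodes(fam)

    def test_venn_identity(self, default_family):
        family, _truth = default_family
        rep = common_nodes(family)
        assert len(rep.common_both) <= min(len(rep.common_disease),
                                           len(rep.common_normal))


class TestInOutConnections:
    def _layer(self):
        g = nx.complete_graph(["a", "b", "c"])
        g.add_edge("a", "d")
        return as_net(g, "toy")

    def test_triangle_plus_pendant(self):
        in_count, out_deg, ratio = in_out_connections(self._layer(), {"a", "b"})
        assert in_count == 1
        assert out_deg == {"a": 2, "b": 1}
        mean_k = 2 * 4 / 4
        assert ratio == pytest.approx(1.5 / mean_k)

    def test_common_equals_all_nodes(self):
        layer = self._layer()
        _in, out_deg, _r = in_out_connections(layer, layer.nodes)
        assert all(v == 0 for v in out_deg.values())

    def test_empty_common_errors(self):
        with pytest.raises(ValueError):
            in_out_connections(self._layer(), set())

    def test_hub_enriched_commons_show_twofold_out_ratio(self):
        # hubs of a star-rich network: their spokes are OUT connections, so
        # the common set's mean OUT degree far exceeds the network <k>
        g = nx.Graph()
        hubs = [f"h{i}" for i in range(4)]
        for i, h in enumerate(hubs):
            g.add_edges_from((h, f"leaf{i}_{j}") for j in range(10))
        g.add_edges_from(zip(hubs, hubs[1:]))
        _in, _out, ratio = in_out_connections(as_net(g), set(hubs))
        assert ratio >= 2

    def test_edge_partition_invariant(self, default_family):
        # 2*IN + sum(OUT) counts each edge touching the common set at most twice
        family, truth = default_family
        for (_t, cond), layer in family.items():
            if cond != "disease":
                continue
            in_count, out_deg, _ = in_out_connections(layer, truth.common_disease)
            assert 2 * in_count + sum(out_deg.values()) <= 2 * layer.n_edges


class TestSubsetClusteringRatio:
    def test_clustered_subset_ratio_above_one(self):
        g = nx.complete_graph(["a", "b", "c"])
        g.update(nx.path_graph(["c", "p1", "p2", "p3", "p4"]))
        ratio = subset_clustering_ratio(as_net(g), {"a", "b", "c"})
        assert ratio > 1

    def test_whole_set_ratio_is_one(self):
        g = nx.complete_graph(4)
        assert subset_clustering_ratio(as_net(g), set(g.nodes)) == pytest.approx(1.0)

    def test_induced_variant_differs(self):
        g = nx.complete_graph(["a", "b", "c"])
        g.add_edge("a", "d")
        in_situ = subset_clustering_ratio(as_net(g), {"a", "b"})
        induced = subset_clustering_ratio(as_net(g), {"a", "b"}, induced=True)
        assert induced != in_situ

    def test_cliquish_commons_on_sparse_periphery_near_twofold(self):
        # commons sit in triangles, the rest of the layer is a long path:
        # subset <CC> is about twice the whole-network average
        g = nx.Graph()
        for i in range(6):
            g.add_edges_from([(f"c{i}a", f"c{i}b"), (f"c{i}b", f"c{i}c"),
                              (f"c{i}a", f"c{i}c")])
        g.add_edge("c0a", "p0")
        g.add_edges_from((f"p{j}", f"p{j + 1}") for j in range(19))
        commons = {f"c{i}{x}" for i in range(6) for x in "abc"}
        ratio = subset_clustering_ratio(as_net(g), commons)
        assert ratio == pytest.approx(2.0, abs=0.5)

    def test_report_bundle(self, default_family):
        family, truth = default_family
        layer = family.layers[("tissue1", "disease")]
        rep = subtractive_report(layer, truth.common_disease)
        assert rep.in_connections >= 0
        assert rep.clustering_ratio > 0


class TestScreenHighBcLowK:
    def test_connector_between_cliques_selected(self):
        g = nx.disjoint_union(nx.complete_graph(8), nx.complete_graph(8))
        g.add_edges_from([(0, "conn"), (8, "conn")])
        picked = screen_high_bc_low_k(as_net(g))
        assert "conn" in picked

    def test_complete_graph_empty(self):
        assert screen_high_bc_low_k(as_net(nx.complete_graph(6))) == set()

    def test_restrict_to(self):
        g = nx.disjoint_union(nx.complete_graph(8), nx.complete_graph(8))
        g.add_edges_from([(0, "conn"), (8, "conn")])
        assert screen_high_bc_low_k(as_net(g), restrict_to={0, 1}) <= {0, 1}


class TestRankCandidates:
    def _single_layer_family(self):
        g = nx.disjoint_union(nx.complete_graph(8), nx.complete_graph(8))
        g.add_edges_from([(0, "conn"), (8, "conn")])
        fam = LayerFamily()
        fam.add("t1", "disease", as_net(g, "t1_disease"))
        fam.add("t1", "normal", as_net(nx.complete_graph(4), "t1_normal"))
        return fam

    def test_single_layer_reduction(self):
        fam = self._single_layer_family()
        common = set(fam.layers[("t1", "disease")].nodes)
        rep = rank_candidates(fam, common, min_layers_bc=1)
        # the connector passes the screen and sits on the two weak-tie edges
        assert rep.candidates == {"conn"}

    def test_weak_tie_requirement_is_monotone(self):
        fam = self._single_layer_family()
        common = set(fam.layers[("t1", "disease")].nodes)
        with_wt = rank_candidates(fam, common, min_layers_bc=1,
                                  require_weak_tie=True).candidates
        without = rank_candidates(fam, common, min_layers_bc=1,
                                  require_weak_tie=False).candidates
        assert with_wt <= without

    def test_monotone_in_min_layers(self, default_family):
        family, truth = default_family
        prev = None
        for m in (2, 4, 6):
            cand = rank_candidates(family, truth.common_disease,
                                   min_layers_bc=m).candidates
            if prev is not None:
                assert cand <= prev
            prev = cand

    def test_evidence_table_schema(self):
        fam = self._single_layer_family()
        common = set(fam.layers[("t1", "disease")].nodes)
        rep = rank_candidates(fam, common, min_layers_bc=1)
        assert {"protein", "n_layers_screened", "n_layers_weak_tie",
                "candidate"} <= set(rep.evidence.columns)
        assert len(rep.evidence) == len(common)

    def test_empty_common_errors(self):
        fam = self._single_layer_family()
        with pytest.raises(ValueError):
            rank_candidates(fam, set())


def test_join_annotations():
    import pandas as pd

    evidence = pd.DataFrame({"protein": ["a", "b"], "candidate": [True, False]})
    out = join_annotations(evidence, {"a": "sensor"})
    assert list(out["annotation"]) == ["sensor", ""]
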