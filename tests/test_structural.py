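import math

import networkx as nx
import numpy as np
import pytest

from complexome import (
    assortativity,
    betweenness_centrality,
    clustering_coefficients,
    degree_statistics,
    fit_two_powerlaws,
    metric_correlation,
    network_diameter,
    sample_piecewise_powerlaw,
    structural_summary,
)
from complexome.structural import summaries_to_frame, write_summaries

from conftest import as_net
import oracles


class TestDegreeStatistics:
    def test_path(self):
        n, m, mk, degs = degree_statistics(as_net(nx.path_graph(3)))
        assert (n, m) == (3, 2)
        assert sorted(degs) == [1, 1, 2]
        assert mk == pytest.approx(4 / 3)

    def test_complete_graph(self):
        assert degree_statistics(as_net(nx.complete_graph(4)))[2] == pytest.approx(3)

    def test_star(self):
        n, m, mk, degs = degree_statistics(as_net(nx.star_graph(5)))
        assert sorted(degs, reverse=True) == [5, 1, 1, 1, 1, 1]
        assert mk == pytest.approx(10 / 6)

    def test_handshake_identity(self, atlas_small):
        for g in atlas_small:
            if g.number_of_nodes():
                _n, m, _mk, degs = degree_statistics(as_net(g))
                assert sum(degs) == 2 * m

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            degree_statistics(as_net(nx.Graph()))


class TestClustering:
    def test_triangle_is_one(self):
        cc, mean = clustering_coefficients(as_net(nx.complete_graph(3)))
        assert all(v == 1.0 for v in cc.values()) and mean == 1.0

    def test_star_is_zero(self):
        _cc, mean = clustering_coefficients(as_net(nx.star_graph(4)))
        assert mean == 0.0

    def test_triangle_free_graph_zero(self):
        _cc, mean = clustering_coefficients(as_net(nx.cycle_graph(6)))
        assert mean == 0.0

    def test_matches_enumeration_oracle_exhaustively(self, atlas_small):
        for g in atlas_small:
            cc, _ = clustering_coefficients(as_net(g))
            expected = oracles.clustering_oracle(g)
            for v in g.nodes:
                assert cc[v] == pytest.approx(expected[v], abs=1e-12)

    def test_exclude_low_degree_flag(self):
        g = nx.complete_graph(3)
        g.add_edge(0, "pendant")
        incl = clustering_coefficients(as_net(g))[1]
        excl = clustering_coefficients(as_net(g), include_low_degree=False)[1]
        assert excl > incl


class TestDiameter:
    def test_path(self):
        assert network_diameter(as_net(nx.path_graph(4)))[0] == 3

    def test_complete(self):
        assert network_diameter(as_net(nx.complete_graph(5)))[0] == 1

    def test_disconnected_reports_lcc_fraction(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        g.add_node("iso")
        d, frac = network_diameter(as_net(g))
        assert d == 1
        assert frac == pytest.approx(3 / 7)

    def test_edgeless_errors(self):
        g = nx.Graph()
        g.add_nodes_from("ab")
        with pytest.raises(ValueError, match="diameter undefined"):
            network_diameter(as_net(g))

    def test_adding_edge_never_increases_diameter(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            g = nx.gnp_random_graph(12, 0.25, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0 or not nx.is_connected(g):
                continue
            d0 = network_diameter(as_net(g))[0]
            missing = [e for e in nx.non_edges(g)]
            if not missing:
                continue
            g.add_edge(*missing[0])
            assert network_diameter(as_net(g))[0] <= d0


class TestAssortativity:
    @pytest.mark.parametrize("n_leaves", [3, 5, 9])
    def test_star_is_minus_one(self, n_leaves):
        assert assortativity(as_net(nx.star_graph(n_leaves))) == pytest.approx(-1.0)

    def test_regular_graph_undefined(self):
        assert math.isnan(assortativity(as_net(nx.cycle_graph(4))))

    def test_matches_direct_pearson_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            g = nx.gnp_random_graph(20, 0.25, seed=int(rng.integers(2**31)))
            if g.number_of_edges() < 2:
                continue
            r = assortativity(as_net(g))
            expected = oracles.assortativity_oracle(g)
            if math.isnan(expected):
                assert math.isnan(r)
            else:
                assert r == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_networkx(self):
        g = nx.gnp_random_graph(40, 0.15, seed=3)
        assert assortativity(as_net(g)) == pytest.approx(
            nx.degree_assortativity_coefficient(g), abs=1e-10)


class TestBetweenness:
    def test_path_three(self):
        bc = betweenness_centrality(as_net(nx.path_graph(3)))
        assert bc[1] == pytest.approx(1.0)
        assert bc[0] == bc[2] == 0.0

    def test_path_four(self):
        bc = betweenness_centrality(as_net(nx.path_graph(4)))
        assert bc[1] == bc[2] == pytest.approx(2.0)
        assert bc[0] == bc[3] == 0.0

    def test_disconnected_pairs_contribute_zero(self):
        g = nx.disjoint_union(nx.path_graph(3), nx.path_graph(3))
        bc = betweenness_centrality(as_net(g))
        assert bc[1] == bc[4] == pytest.approx(1.0)


class TestMetricCorrelation:
    def test_identity(self):
        assert metric_correlation([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_negation(self):
        assert metric_correlation([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_constant_is_nan(self):
        assert math.isnan(metric_correlation([1, 1, 1], [1, 2, 3]))

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            metric_correlation([1, 2], [1, 2, 3])

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            metric_correlation([1, 2], [3, 4])

    def test_hierarchical_toy_graph_negative_k_cc(self):
        # two triangles whose nodes all attach to one central hub: the hub
        # has the highest degree and the lowest clustering
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                          ("d", "e"), ("e", "f"), ("d", "f")])
        g.add_edges_from(("hub", v) for v in "abcdef")
        s = structural_summary(as_net(g))
        assert s.corr_k_cc < 0


class TestTwoPowerLawFit:
    def test_recovers_known_piecewise_law(self):
        degs = sample_piecewise_powerlaw(
            5000, exponent_low=1.2, exponent_high=3.0, k_break=20, seed=1)
        fit = fit_two_powerlaws(degs)
        assert fit.exponent_low == pytest.approx(1.2, abs=0.3)
        assert fit.exponent_high == pytest.approx(3.0, abs=0.3)
        assert 20 / 1.5 <= fit.breakpoint_degree <= 20 * 1.5

    def test_pure_power_law_no_spurious_break(self):
        degs = sample_piecewise_powerlaw(
            5000, exponent_low=2.5, exponent_high=2.5, k_break=20, seed=0)
        fit = fit_two_powerlaws(degs)
        assert abs(fit.exponent_low - fit.exponent_high) < 0.3

    def test_constant_degrees_error(self):
        with pytest.raises(ValueError, match="insufficient support"):
            fit_two_powerlaws([5] * 200)

    def test_breakpoint_inside_degree_range(self):
        degs = sample_piecewise_powerlaw(3000, seed=2)
        fit = fit_two_powerlaws(degs)
        assert degs.min() < fit.breakpoint_degree < degs.max()


class TestSummaryOutput:
    def test_tidy_frame_and_files(self, tmp_path):
        nets = [as_net(nx.complete_graph(5), "k5"),
                as_net(nx.path_graph(6), "p6")]
        summaries = [structural_summary(n) for n in nets]
        frame = summaries_to_frame(summaries)
        assert list(frame["name"]) == ["k5", "p6"]
        assert frame.loc[0, "mean_clustering"] == 1.0
        write_summaries(summaries, tmp_path / "s.tsv", format="tsv")
        write_summaries(summaries, tmp_path / "s.json", format="json")
        assert (tmp_path / "s.tsv").read_text().count("\n") == 3
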