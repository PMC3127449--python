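from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import (
    bfs_component,
    bruteforce_global_clustering,
    bruteforce_local_clustering,
    naive_stub_pairing,
)
from epiclust.networks import (
    BernoulliParams,
    PowerLawParams,
    assemble_configuration_model,
    degree_histogram,
    global_clustering,
    largest_component,
    local_clustering,
    read_edgelist,
    read_graphml,
    sample_bernoulli,
    sample_power_law,
    sample_power_law_degrees,
    validate_network,
    write_edgelist,
    write_graphml,
)


class TestBernoulli:
    def test_extreme_probabilities(self, rng):
        assert sample_bernoulli(BernoulliParams(5, 0.0), rng).number_of_edges() == 0
        full = sample_bernoulli(BernoulliParams(5, 1.0), rng)
        assert full.number_of_edges() == 10

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            BernoulliParams(5, 1.5)
        with pytest.raises(ValueError):
            BernoulliParams(1, 0.5)

    def test_edge_count_matches_binomial_moments(self, rng):
        """Mean edge count over replicates sits within 3 SE of N(N-1)p/2."""
        n, p, reps = 500, 0.014, 200
        n_pairs = n * (n - 1) // 2
        counts = [
            sample_bernoulli(BernoulliParams(n, p), rng).number_of_edges()
            for _ in range(reps)
        ]
        expected_mean = n_pairs * p  # = 1746.5
        se = math.sqrt(n_pairs * p * (1 - p) / reps)
        assert abs(np.mean(counts) - expected_mean) < 3 * se
        # variance sanity at the same confidence scale
        expected_var = n_pairs * p * (1 - p)
        se_var = expected_var * math.sqrt(2 / (reps - 1))
        assert abs(np.var(counts, ddof=1) - expected_var) < 3 * se_var

    def test_generated_networks_are_simple(self, rng):
        for _ in range(5):
            validate_network(sample_bernoulli(BernoulliParams(60, 0.1), rng))


class TestPowerLawDegrees:
    def test_large_exponent_concentrates_at_one(self, rng):
        degrees = sample_power_law_degrees(PowerLawParams(10_000, 50.0), rng)
        assert np.all(degrees == 1) or degrees.sum() % 2 == 0
        assert np.mean(degrees == 1) > 0.999

    def test_degree_ratio_matches_power_law(self, rng):
        """P(d=1)/P(d=2) = 2**alpha: check the conditional frequency of 1s
        among {1, 2} draws against its binomial standard error."""
        alpha = 1.8
        degrees = sample_power_law_degrees(PowerLawParams(600, alpha, 599), rng)
        draws = np.concatenate(
            [
                sample_power_law_degrees(PowerLawParams(600, alpha, 599), rng)
                for _ in range(170)
            ]
        )  # ~1e5 draws
        ones = int((draws == 1).sum())
        twos = int((draws == 2).sum())
        q = 2**alpha / (1 + 2**alpha)  # P(d=1 | d in {1,2})
        n = ones + twos
        se = math.sqrt(q * (1 - q) / n)
        assert abs(ones / n - q) < 3 * se

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_degree_sum_always_even(self, seed):
        rng = np.random.default_rng(seed)
        degrees = sample_power_law_degrees(PowerLawParams(51, 1.8), rng)
        assert degrees.sum() % 2 == 0
        assert degrees.min() >= 1


class TestConfigurationModel:
    def test_two_stubs_make_one_edge(self, rng):
        g = assemble_configuration_model([1, 1], rng)
        assert set(g.edges) == {(0, 1)}

    def test_loops_and_duplicates_collapse(self, rng):
        for _ in range(10):
            g = assemble_configuration_model([2, 2], rng)
            assert g.number_of_edges() <= 1
            validate_network(g)

    def test_odd_stub_total_rejected(self, rng):
        with pytest.raises(ValueError):
            assemble_configuration_model([1, 1, 1], rng)

    def test_realized_degrees_never_exceed_requested(self, rng):
        degrees = sample_power_law_degrees(PowerLawParams(200, 1.8), rng)
        g = assemble_configuration_model(degrees, rng)
        for i, d in enumerate(degrees):
            assert g.degree(i) <= d

    def test_mean_degree_matches_naive_pairing_oracle(self, rng):
        """degrees (3,3,3,3): cleanup loses edges; the realized mean degree
        must match an explicit sample-stub-pairs-without-replacement oracle."""
        reps = 10_000
        impl = np.array(
            [
                np.mean([d for _, d in assemble_configuration_model([3] * 4, rng).degree()])
                for _ in range(reps)
            ]
        )
        oracle = np.array(
            [
                np.mean([d for _, d in naive_stub_pairing([3] * 4, rng).degree()])
                for _ in range(reps)
            ]
        )
        assert impl.mean() < 3.0
        se = math.sqrt(impl.var(ddof=1) / reps + oracle.var(ddof=1) / reps)
        assert abs(impl.mean() - oracle.mean()) < 3 * se


class TestLargestComponent:
    def test_connected_graph_is_its_own_component(self):
        g = nx.cycle_graph(6)
        assert set(largest_component(g).nodes) == set(g.nodes)

    def test_tie_break_prefers_smallest_node_id(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)])
        g.add_node(6)
        comp = largest_component(g)
        assert set(comp.nodes) == {0, 1, 2}
        assert comp.number_of_edges() == 3

    def test_matches_bfs_oracle_on_bernoulli_sample(self, rng):
        g = sample_bernoulli(BernoulliParams(500, 0.014), rng)
        comp = largest_component(g)
        # oracle: BFS from every node, take the largest reachable set
        best: set[int] = set()
        seen: set[int] = set()
        for u in g.nodes:
            if u in seen:
                continue
            c = bfs_component(g, u)
            seen |= c
            if len(c) > len(best) or (len(c) == len(best) and min(c) < min(best)):
                best = c
        assert set(comp.nodes) == best

    def test_empty_graph(self):
        assert largest_component(nx.Graph()).number_of_nodes() == 0


class TestClustering:
    def test_triangle_node(self):
        assert local_clustering(nx.complete_graph(3), 0) == 1.0

    def test_path_centre_has_no_clustering(self):
        assert local_clustering(nx.path_graph(3), 1) == 0.0

    def test_low_degree_nodes_score_zero(self):
        g = nx.path_graph(2)
        assert local_clustering(g, 0) == 0.0

    def test_unknown_node_raises(self):
        with pytest.raises(KeyError):
            local_clustering(nx.path_graph(3), 99)

    def test_k4_minus_edge(self, k4_minus_edge):
        # high-degree nodes 2, 3 see 2 of 3 neighbour pairs connected
        assert local_clustering(k4_minus_edge, 2) == pytest.approx(2 / 3)
        assert global_clustering(k4_minus_edge) == pytest.approx(5 / 6)

    def test_triangle_free_graph_scores_zero(self):
        assert global_clustering(nx.cycle_graph(8)) == 0.0

    def test_empty_graph_convention(self):
        assert global_clustering(nx.Graph()) == 0.0

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_bruteforce_triangle_enumeration(self, seed):
        r = np.random.default_rng(seed)
        g = nx.gnp_random_graph(int(r.integers(2, 21)), float(r.uniform(0, 0.6)),
                                seed=int(r.integers(2**31)))
        assert global_clustering(g) == pytest.approx(
            bruteforce_global_clustering(g), abs=1e-12
        )
        for node in list(g.nodes)[:5]:
            assert local_clustering(g, node) == pytest.approx(
                bruteforce_local_clustering(g, node), abs=1e-12
            )


class TestDegreeHistogram:
    @pytest.mark.parametrize(
        "graph, expected",
        [
            (nx.empty_graph(3), [3]),
            (nx.complete_graph(3), [0, 0, 3]),
            (nx.star_graph(4), [0, 4, 0, 0, 1]),
        ],
    )
    def test_known_histograms(self, graph, expected):
        assert degree_histogram(graph).tolist() == expected


class TestFileFormats:
    def test_edgelist_roundtrip(self, tmp_path, rng):
        g = sample_bernoulli(BernoulliParams(30, 0.2), rng)
        path = tmp_path / "net.edgelist"
        write_edgelist(g, path)
        back = read_edgelist(path, n_nodes=30)
        assert set(back.nodes) == set(g.nodes)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, g.edges))
        first = path.read_text().splitlines()[0].split("\t")
        assert int(first[0]) < int(first[1])

    def test_graphml_roundtrip(self, tmp_path, rng):
        g = sample_power_law(PowerLawParams(40, 2.0), rng)
        path = tmp_path / "net.graphml"
        write_graphml(g, path)
        back = read_graphml(path)
        assert set(back.nodes) == set(g.nodes)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, g.edges))
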