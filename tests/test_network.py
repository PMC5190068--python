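import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from recursig.network import (
    NetworkError,
    build_graph,
    detect_communities,
    direction_consensus,
    enumerate_dags_oracle,
    enumerate_paths_oracle,
    extract_centered_subnetwork,
    hub_nodes,
    hypergeometric_enrichment,
    learn_dag_hc,
    score_dag,
    shortest_axis_path,
    DAGStructure,
)
from recursig.simulate import generate_interaction_fixture


def _edges(*rows):
    return pd.DataFrame(rows, columns=["node1", "node2", "combined_score"])


class TestBuildGraph:
    def test_threshold_drops_low_confidence_shortcut(self):
        fixture = generate_interaction_fixture(n_decoys=2, seed=0)
        G = build_graph(fixture, 600)
        assert not G.has_edge("KCNN4", "S100A14")
        assert all(d["combined_score"] >= 600 for _, _, d in G.edges(data=True))

    def test_threshold_zero_retains_all(self):
        fixture = generate_interaction_fixture(n_decoys=2, seed=0)
        G = build_graph(fixture, 0)
        assert G.has_edge("KCNN4", "S100A14")

    def test_duplicate_edge_keeps_max_score(self):
        G = build_graph(_edges(("a", "b", 650), ("b", "a", 700)), 600)
        assert G["a"]["b"]["combined_score"] == 700

    def test_self_loops_removed(self):
        G = build_graph(_edges(("a", "a", 900), ("a", "b", 900)), 600)
        assert not G.has_edge("a", "a")

    def test_malformed_score_names_row(self):
        with pytest.raises(NetworkError, match="row 1"):
            build_graph(_edges(("a", "b", 700), ("b", "c", "oops")), 600)

    def test_out_of_range_score_rejected(self):
        with pytest.raises(NetworkError, match="range"):
            build_graph(_edges(("a", "b", 1500)), 600)


class TestSubnetwork:
    def test_fixture_one_hop_union(self):
        G = build_graph(generate_interaction_fixture(n_decoys=2, seed=0), 600)
        sub = extract_centered_subnetwork(G, ["KCNN4", "S100A14"], k=1)
        # seeds' 1-hop neighborhoods: chain ends, their chain neighbors and decoys
        assert {"KCNN4", "UBA52", "KLF4", "S100A14"} <= set(sub.nodes)
        assert "DEC_KCNN4_0" in sub.nodes and "DEC_S100A14_1" in sub.nodes
        # decoys of the middle genes are 2 hops from both seeds: excluded
        assert "DEC_UBA52_0" not in sub.nodes

    def test_monotone_in_k(self):
        G = build_graph(generate_interaction_fixture(n_decoys=3, seed=1), 600)
        nodes = [set(extract_centered_subnetwork(G, ["KCNN4", "S100A14"], k=k))
                 for k in (1, 2, 3)]
        assert nodes[0] <= nodes[1] <= nodes[2]

    def test_saturating_k_returns_component(self):
        G = build_graph(generate_interaction_fixture(n_decoys=1, seed=0), 600)
        sub = extract_centered_subnetwork(G, ["KCNN4", "S100A14"], k=10)
        assert set(sub.nodes) == set(nx.node_connected_component(G, "KCNN4"))

    def test_absent_seed_rejected(self):
        G = build_graph(_edges(("a", "b", 700)), 600)
        with pytest.raises(NetworkError, match="absent"):
            extract_centered_subnetwork(G, ["a", "zz"])

    def test_disconnected_seeds_rejected(self):
        G = build_graph(_edges(("a", "b", 700), ("c", "d", 700)), 600)
        with pytest.raises(NetworkError, match="no connecting"):
            extract_centered_subnetwork(G, ["a", "c"])


class TestAxisPath:
    def test_fixture_axis(self):
        G = build_graph(generate_interaction_fixture(n_decoys=3, seed=0), 600)
        sub = extract_centered_subnetwork(G, ["KCNN4", "S100A14"])
        assert shortest_axis_path(sub, ["KCNN4", "S100A14"]) == \
            ["KCNN4", "UBA52", "KLF4", "S100A14"]

    def test_adjacent_seeds(self):
        G = build_graph(_edges(("a", "b", 700)), 600)
        assert shortest_axis_path(G, ["a", "b"]) == ["a", "b"]

    def test_lexicographic_tie_break(self):
        G = build_graph(_edges(("s", "AAA", 700), ("AAA", "t", 700),
                               ("s", "BBB", 700), ("BBB", "t", 700)), 600)
        assert shortest_axis_path(G, ["s", "t"]) == ["s", "AAA", "t"]

    def test_matches_enumeration_oracle(self):
        for seed in range(5):
            G = build_graph(generate_interaction_fixture(n_decoys=2, seed=seed), 600)
            sub = extract_centered_subnetwork(G, ["KCNN4", "S100A14"])
            assert sub.number_of_nodes() <= 12
            assert shortest_axis_path(sub, ["KCNN4", "S100A14"]) == \
                enumerate_paths_oracle(sub, ["KCNN4", "S100A14"])


class TestCommunities:
    def test_two_disjoint_triangles(self):
        G = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        part = detect_communities(G)
        assert part.n_communities == 2

    def test_bridged_triangles_modularity(self):
        # exhaustively verified optimum: Q = 5/14 with m = 7 edges
        G = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
        part = detect_communities(G)
        assert part.n_communities == 2
        assert part.modularity_q == pytest.approx(5 / 14)

    def test_star_is_single_community(self):
        G = nx.star_graph(5)
        assert detect_communities(G).n_communities == 1

    def test_hub_is_top_degree_node_per_community(self):
        G = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3), (1, 6)])
        part = detect_communities(G)
        hubs = hub_nodes(G, part)
        assert hubs[part.membership[1]] == 1  # degree 4


def _chain_data(n, seed, coef=1.2, noise=0.3):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = coef * x + noise * rng.standard_normal(n)
    z = coef * y + noise * rng.standard_normal(n)
    return pd.DataFrame({"X": x, "Y": y, "Z": z})


class TestBayesianNetwork:
    def test_aic_empty_graph_rate_matches_false_positive_theory(self):
        # AIC adds a spurious edge per pair with P(chi2_1 > 2) = 0.157, so
        # 3 independent Gaussians stay empty at rate 0.843^3 ~ 0.60;
        # binomial(20, 0.60) bounds: P(outside 6..18) < 1e-2
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            data = pd.DataFrame(rng.standard_normal((500, 3)), columns=list("ABC"))
            if learn_dag_hc(data).edges == ():
                hits += 1
        assert 6 <= hits <= 18

    def test_bic_empty_graph_on_independent_data(self):
        # the consistent penalty keeps null data empty almost always
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            data = pd.DataFrame(rng.standard_normal((500, 3)), columns=list("ABC"))
            if learn_dag_hc(data, penalty="bic").edges == ():
                hits += 1
        assert hits >= 18

    def test_strong_chain_recovers_skeleton(self):
        # AIC: true recovery rate ~0.843 (spurious X-Z edge at 0.157);
        # BIC: ~0.97. Bounds chosen from the respective binomials.
        skel = {frozenset(("X", "Y")), frozenset(("Y", "Z"))}
        aic_hits = sum(
            learn_dag_hc(_chain_data(500, seed)).skeleton() == skel
            for seed in range(20))
        bic_hits = sum(
            learn_dag_hc(_chain_data(500, seed), penalty="bic").skeleton() == skel
            for seed in range(20))
        assert aic_hits >= 12
        assert bic_hits >= 18
        # the true edges are never missed under either penalty
        assert all(skel <= learn_dag_hc(_chain_data(500, s)).skeleton()
                   for s in range(5))

    def test_score_never_below_empty_graph(self, rng):
        data = pd.DataFrame(rng.standard_normal((100, 3)), columns=list("ABC"))
        dag = learn_dag_hc(data)
        assert dag.score_aic >= score_dag(data, []) - 1e-9

    def test_learned_structure_is_acyclic(self):
        dag = learn_dag_hc(_chain_data(300, 0))
        G = nx.DiGraph(list(dag.edges))
        G.add_nodes_from(dag.nodes)
        assert nx.is_directed_acyclic_graph(G)

    def test_markov_equivalent_two_node_scores_match(self, rng):
        data = pd.DataFrame(rng.standard_normal((200, 2)), columns=["A", "B"])
        data["B"] += 0.8 * data["A"]
        assert score_dag(data, [("A", "B")]) == pytest.approx(
            score_dag(data, [("B", "A")]), abs=1e-9)

    def test_oracle_enumerates_543_dags_on_4_nodes(self, rng):
        data = pd.DataFrame(rng.standard_normal((30, 4)), columns=list("ABCD"))
        assert enumerate_dags_oracle(data).n_enumerated == 543

    def test_oracle_enumerates_3_structures_on_2_nodes(self, rng):
        data = pd.DataFrame(rng.standard_normal((30, 2)), columns=list("AB"))
        assert enumerate_dags_oracle(data).n_enumerated == 3

    def test_constant_column_rejected(self):
        data = pd.DataFrame({"A": [1.0] * 20, "B": np.arange(20.0)})
        with pytest.raises(NetworkError, match="constant"):
            learn_dag_hc(data)


class TestDirectionConsensus:
    def _dag(self, edges):
        return DAGStructure(nodes=("A", "B"), edges=tuple(edges),
                            score_aic=0.0, search="hill_climb")

    def test_unanimous_among_present(self):
        dags = [self._dag([("A", "B")])] * 5 + [self._dag([])] * 2
        cons = direction_consensus(dags)
        assert cons.calls[frozenset(("A", "B"))] == "A->B"
        assert cons.tallies[frozenset(("A", "B"))]["absent"] == 2

    def test_tied_directions_undetermined(self):
        dags = [self._dag([("A", "B")])] * 3 + [self._dag([("B", "A")])] * 3
        assert direction_consensus(dags).calls[frozenset(("A", "B"))] == "undetermined"

    def test_all_absent_undetermined(self):
        dags = [self._dag([])] * 4
        cons = direction_consensus(dags)
        assert cons.calls[frozenset(("A", "B"))] == "undetermined"
        assert cons.tallies[frozenset(("A", "B"))]["absent"] == 4

    def test_node_set_mismatch_rejected(self):
        other = DAGStructure(nodes=("A", "C"), edges=(), score_aic=0.0,
                             search="hill_climb")
        with pytest.raises(NetworkError):
            direction_consensus([self._dag([]), other])


class TestEnrichment:
    def test_single_term_hypergeometric(self):
        # universe 10, annotated 5, query 5 all annotated: p = 1/C(10,5)
        universe = {f"g{i}" for i in range(10)}
        annotated = {f"g{i}" for i in range(5)}
        df = hypergeometric_enrichment(annotated, {"term": annotated}, universe)
        assert df.loc[0, "p"] == pytest.approx(1 / 252)

    def test_disjoint_query_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        df = hypergeometric_enrichment({"g0"}, {"term": {"g5", "g6"}}, universe)
        assert df.loc[0, "p"] == pytest.approx(1.0)

    def test_bh_across_sets(self):
        universe = {f"g{i}" for i in range(40)}
        df = hypergeometric_enrichment(
            {"g0", "g1", "g2"},
            {"hit": {"g0", "g1", "g2"}, "miss": {f"g{i}" for i in range(20, 30)}},
            universe,
        )
        assert (df["p_adjusted"] >= df["p"] - 1e-12).all()

    def test_query_outside_universe_rejected(self):
        with pytest.raises(NetworkError):
            hypergeometric_enrichment({"zz"}, {"t": {"a"}}, {"a", "b"})
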