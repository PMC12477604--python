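import networkx as nx
import numpy as np
import pytest
from scipy.stats import spearmanr

from littersuccession.errors import InputError, ParameterError
from littersuccession.io import FeatureTable
from littersuccession.network import (
    CooccurrenceNetwork,
    build_network,
    centralities,
    classify_origin,
    identify_keystones,
    keystone_report,
    loo_impact_scores,
    niche_overlap,
)
from littersuccession.synth import simulate_correlated_blocks


def _star(n_leaves=4):
    g = nx.star_graph(n_leaves)
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
    return CooccurrenceNetwork(graph=g)


class TestBuildNetwork:
    def test_planted_block_forms_clique(self):
        table, truth = simulate_correlated_blocks(20, [5], 1.0, 100, seed=1)
        net = build_network(table, top_n=20)
        block = [t for t, b in truth.block_assignments.items() if b == 0]
        for i, a in enumerate(block):
            for b in block[i + 1:]:
                assert net.graph.has_edge(a, b)

    def test_threshold_is_strictly_greater(self):
        table, _ = simulate_correlated_blocks(6, [2], 0.6, 60, seed=2)
        idx = table.taxon_index()
        r = abs(spearmanr(table.counts[idx["ASV0000"]], table.counts[idx["ASV0001"]]).statistic)
        at_r = build_network(table, top_n=6, r_threshold=r, p_threshold=1.0)
        assert not at_r.graph.has_edge("ASV0000", "ASV0001")
        below_r = build_network(table, top_n=6, r_threshold=r - 1e-9, p_threshold=1.0)
        assert below_r.graph.has_edge("ASV0000", "ASV0001")

    def test_independent_taxa_produce_almost_no_edges(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(50, size=(200, 100))
        table = FeatureTable(tuple(f"t{i:03d}" for i in range(200)),
                             tuple(f"s{j:03d}" for j in range(100)), counts)
        net = build_network(table, top_n=200)
        assert net.n_edges <= 0.01 * (200 * 199 / 2)

    def test_input_validation(self, small_table):
        with pytest.raises(InputError, match="4 samples"):
            build_network(small_table, top_n=4)
        table, _ = simulate_correlated_blocks(6, [2], 0.5, 10, seed=4)
        with pytest.raises(ParameterError):
            build_network(table, top_n=1)
        with pytest.raises(ParameterError):
            build_network(table, r_threshold=1.5)


class TestCentralities:
    def test_star_degrees_and_betweenness(self):
        cent = centralities(_star())
        assert cent.loc["n0", "degree"] == 4
        assert cent.loc["n0", "betweenness"] == 6  # C(4,2) leaf pairs
        assert (cent.drop("n0")["degree"] == 1).all()
        assert (cent.drop("n0")["betweenness"] == 0).all()

    def test_path_harmonic_closeness(self):
        g = nx.path_graph(3)
        g = nx.relabel_nodes(g, {0: "A", 1: "B", 2: "C"})
        cent = centralities(g)
        assert cent.loc["B", "closeness"] == pytest.approx(2.0)
        assert cent.loc["A", "closeness"] == pytest.approx(1.0 + 0.5)

    def test_isolated_node_all_zero(self):
        g = nx.Graph()
        g.add_nodes_from(["x", "y", "z"])
        g.add_edge("x", "y")
        cent = centralities(g)
        assert cent.loc["z"].tolist() == [0, 0, 0]


def _oracle_impact_scores(graph):
    """Naive oracle: Floyd-Warshall distances + path counting per subgraph."""

    def means(g):
        nodes = sorted(g.nodes)
        n = len(nodes)
        index = {v: i for i, v in enumerate(nodes)}
        inf = float("inf")
        dist = np.full((n, n), inf)
        np.fill_diagonal(dist, 0.0)
        for a, b in g.edges:
            dist[index[a], index[b]] = dist[index[b], index[a]] = 1.0
        for k in range(n):
            for i in range(n):
                for j in range(n):
                    alt = dist[i, k] + dist[k, j]
                    if alt < dist[i, j]:
                        dist[i, j] = alt
        # shortest-path counts by dynamic programming over distance layers
        paths = np.zeros((n, n))
        np.fill_diagonal(paths, 1.0)
        order = sorted(
            ((i, j) for i in range(n) for j in range(n) if i != j and dist[i, j] < inf),
            key=lambda ij: dist[ij[0], ij[1]],
        )
        adj = {i: [index[w] for w in g.neighbors(nodes[i])] for i in range(n)}
        for i, j in order:
            if dist[i, j] == 1.0:
                paths[i, j] = 1.0
            else:
                paths[i, j] = sum(
                    paths[i, k] for k in adj[j] if dist[i, k] == dist[i, j] - 1
                )
        degree = np.array([g.degree(v) for v in nodes], dtype=float)
        betweenness = np.zeros(n)
        for s in range(n):
            for t in range(s + 1, n):
                if dist[s, t] == inf or paths[s, t] == 0:
                    continue
                for v in range(n):
                    if v in (s, t):
                        continue
                    if dist[s, v] + dist[v, t] == dist[s, t]:
                        betweenness[v] += paths[s, v] * paths[v, t] / paths[s, t]
        closeness = np.array(
            [sum(1.0 / dist[i, j] for j in range(n) if j != i and dist[i, j] < inf)
             for i in range(n)]
        )
        return np.array([degree.mean(), betweenness.mean(), closeness.mean()])

    base = means(graph)
    scores = {}
    for v in graph.nodes:
        reduced = graph.copy()
        reduced.remove_node(v)
        scores[v] = float(np.abs(means(reduced) - base).sum())
    return scores


class TestLooImpact:
    def test_vertex_transitive_graph_scores_equal(self):
        g = nx.cycle_graph(6)
        g = nx.relabel_nodes(g, {i: f"c{i}" for i in g.nodes})
        scores = loo_impact_scores(g)
        assert np.allclose(scores, scores.iloc[0])

    def test_star_hub_dominates(self):
        scores = loo_impact_scores(_star())
        assert scores["n0"] > scores.drop("n0").max()

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_from_scratch_oracle(self, seed):
        g = nx.gnp_random_graph(30, 0.15, seed=seed)
        g = nx.relabel_nodes(g, {i: f"ASV{i:02d}" for i in g.nodes})
        scores = loo_impact_scores(g)
        oracle = _oracle_impact_scores(g)
        for node, expected in oracle.items():
            assert scores[node] == pytest.approx(expected, abs=1e-9)

    def test_too_small_graph_rejected(self):
        g = nx.path_graph(2)
        with pytest.raises(InputError):
            loo_impact_scores(g)


class TestKeystones:
    def test_exactly_ten_percent_of_400(self):
        rng = np.random.default_rng(0)
        scores = {f"n{i:03d}": v for i, v in enumerate(rng.permutation(400).astype(float))}
        keys = identify_keystones(scores)
        assert len(keys) == 40
        assert min(scores[k] for k in keys) > max(
            v for n, v in scores.items() if n not in keys
        )

    def test_single_top_node(self):
        scores = {f"n{i}": float(i == 3) for i in range(10)}
        assert identify_keystones(scores) == ["n3"]

    def test_all_ties_resolved_deterministically(self):
        scores = {f"n{i}": 1.0 for i in range(10)}
        degrees = {f"n{i}": i for i in range(10)}
        assert identify_keystones(scores, degrees=degrees) == ["n9"]
        assert identify_keystones(scores) == ["n0"]  # id tie-break

    def test_input_order_invariance(self):
        rng = np.random.default_rng(1)
        import pandas as pd

        scores = pd.Series(rng.normal(size=50), index=[f"n{i:02d}" for i in range(50)])
        shuffled = scores.sample(frac=1, random_state=2)
        assert identify_keystones(scores) == identify_keystones(shuffled)


class TestOriginAndOverlap:
    def _habitat_tables(self):
        phyllo = FeatureTable(("a", "b", "c"), ("p1",), np.array([[5], [0], [0]]))
        soil = FeatureTable(("a", "b", "c"), ("s1",), np.array([[0], [3], [0]]))
        return phyllo, soil

    def test_origin_labels(self):
        phyllo, soil = self._habitat_tables()
        labels = classify_origin(["a", "b", "c"], phyllo, soil)
        assert labels == {"a": "phyllosphere", "b": "soil", "c": "unknown"}
        both = classify_origin(["a"], phyllo, FeatureTable(("a",), ("s1",), np.array([[2]])))
        assert both["a"] == "both"

    def test_pianka_identity_disjoint_and_worked_example(self):
        counts = np.array([[2, 2, 0], [0, 2, 2], [2, 0, 2]])
        litter = FeatureTable(("X", "Y", "F"), ("l1", "l2", "l3"), counts)
        assert niche_overlap(["X"], ["X"], litter) == pytest.approx(1.0)
        # p = (0.5, 0.5, 0) vs q = (0, 0.5, 0.5) -> Pianka 0.5
        assert niche_overlap(["X"], ["Y"], litter) == pytest.approx(0.5)
        disjoint = FeatureTable(
            ("X", "Y"), ("l1", "l2"), np.array([[4, 0], [0, 4]])
        )
        assert niche_overlap(["X"], ["Y"], disjoint) == pytest.approx(0.0)

    def test_zero_abundance_group_flagged_nan(self):
        litter = FeatureTable(("X", "Y"), ("l1",), np.array([[3], [0]]))
        with pytest.warns(UserWarning, match="zero abundance"):
            assert np.isnan(niche_overlap(["Y"], ["X"], litter))


def test_keystone_report_end_to_end():
    table, truth = simulate_correlated_blocks(30, [6, 5], 0.95, 80, seed=5)
    net = build_network(table, top_n=30)
    phyllo = FeatureTable(table.taxon_ids, ("p1",),
                          np.vstack([np.ones((15, 1), int), np.zeros((15, 1), int)]))
    soil = FeatureTable(table.taxon_ids, ("s1",),
                        np.vstack([np.zeros((15, 1), int), np.ones((15, 1), int)]))
    report = keystone_report(net, phyllo, soil)
    assert report["keystone"].sum() == 3  # ceil(0.1 * 30)
    assert set(report.loc[report["keystone"], "origin"]) <= {"phyllosphere", "soil", "both", "unknown"}
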