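import itertools
from collections import deque

import networkx as nx
import numpy as np
import pytest

from coexnet import (
    AssociationMatrix,
    CoexpressionNetwork,
    ValidationError,
    betweenness_all,
    build_adjacency,
    degree_centrality,
    extract_modules,
    rank_genes,
    score_nodes,
)
from coexnet.network import write_graphml, write_sif


def _assoc(values, measure="pcc", genes=None):
    values = np.asarray(values, float)
    genes = genes or tuple(f"G{i}" for i in range(values.shape[0]))
    return AssociationMatrix(tuple(genes), values, measure)


def _net_from_edges(edges, nodes=None):
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return CoexpressionNetwork(graph=g)


def _sym(rng, n, scale=1.0):
    v = rng.random((n, n)) * scale
    v = (v + v.T) / 2
    np.fill_diagonal(v, 1.0)
    return v


class TestBuildAdjacency:
    def _pair(self, pcc_val, mi_val):
        pcc = _assoc([[1, pcc_val, 0], [pcc_val, 1, 0], [0, 0, 1]])
        mi = _assoc([[1, mi_val, 0], [mi_val, 1, 0], [0, 0, 1]], measure="mi")
        return pcc, mi

    def test_edge_from_correlation_alone(self):
        pcc, mi = self._pair(0.95, 0.1)
        net = build_adjacency(pcc, mi, t_pcc=0.9, t_mi=0.7)
        assert ("G0", "G1") in net.edges

    def test_edge_rescued_by_mutual_information(self):
        # nonlinear dependence: low correlation, high MI
        pcc, mi = self._pair(0.2, 0.8)
        net = build_adjacency(pcc, mi, t_pcc=0.9, t_mi=0.7)
        assert ("G0", "G1") in net.edges

    def test_equality_never_creates_edge(self):
        pcc, mi = self._pair(0.9, 0.7)
        net = build_adjacency(pcc, mi, t_pcc=0.9, t_mi=0.7)
        assert net.n_edges == 0

    def test_no_self_loops(self, rng):
        pcc = _assoc(_sym(rng, 6))
        mi = _assoc(_sym(rng, 6), measure="mi")
        net = build_adjacency(pcc, mi, 0.5, 0.5)
        assert all(a != b for a, b in net.edges)

    def test_gene_id_mismatch_rejected(self):
        pcc = _assoc(np.eye(2), genes=("A", "B"))
        mi = _assoc(np.eye(2), measure="mi", genes=("B", "A"))
        with pytest.raises(ValidationError):
            build_adjacency(pcc, mi, 0.5, 0.5)

    def test_hybrid_edges_superset_of_single_measure(self, rng):
        for _ in range(20):
            pcc = _assoc(_sym(rng, 8))
            mi = _assoc(_sym(rng, 8, scale=2.0), measure="mi")
            tp, tm = rng.random(), rng.random() * 2
            hybrid = set(map(frozenset, build_adjacency(pcc, mi, tp, tm).edges))
            pcc_only = set(map(frozenset, build_adjacency(pcc, pcc, tp, np.inf).edges))
            mi_only = set(map(frozenset, build_adjacency(mi, mi, np.inf, tm).edges))
            assert pcc_only <= hybrid
            assert mi_only <= hybrid


def components_oracle(nodes, edges):
    """Union-find reimplementation, independent of networkx."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return sorted(groups.values(), key=lambda s: (-len(s), min(s)))


class TestExtractModules:
    def test_two_triangles_and_isolate(self):
        net = _net_from_edges(
            [("A", "B"), ("B", "C"), ("A", "C"), ("X", "Y"), ("Y", "Z"), ("X", "Z")],
            nodes=["A", "B", "C", "X", "Y", "Z", "Q"],
        )
        mod = extract_modules(net, min_module_size=3)
        assert len(mod.modules) == 2
        assert mod.graph.number_of_nodes() == 6
        assert extract_modules(net, min_module_size=4).modules == ()

    def test_modules_disjoint_and_cover_retained_nodes(self, rng):
        g = nx.gnp_random_graph(30, 0.08, seed=3)
        g = nx.relabel_nodes(g, {i: f"G{i}" for i in range(30)})
        mod = extract_modules(CoexpressionNetwork(graph=g), min_module_size=3)
        all_nodes = [n for m in mod.modules for n in m]
        assert len(all_nodes) == len(set(all_nodes)) == mod.graph.number_of_nodes()

    def test_matches_union_find_oracle(self, rng):
        for seed in range(10):
            g = nx.gnp_random_graph(25, 0.07, seed=seed)
            net = CoexpressionNetwork(graph=g)
            expected = [c for c in components_oracle(g.nodes, g.edges) if len(c) >= 2]
            mod = extract_modules(net, min_module_size=2)
            assert sorted(map(sorted, mod.modules)) == sorted(map(sorted, expected))

    def test_min_size_below_two_rejected(self):
        with pytest.raises(ValidationError):
            extract_modules(_net_from_edges([("A", "B")]), min_module_size=1)


def betweenness_oracle(graph):
    """Exhaustive BFS shortest-path enumeration, per component, normalized."""
    result = {n: 0.0 for n in graph.nodes}
    for comp in nx.connected_components(graph):
        comp = sorted(comp)
        n_c = len(comp)
        if n_c <= 2:
            continue
        sub = graph.subgraph(comp)
        for i, j in itertools.combinations(comp, 2):
            paths = _all_shortest_paths_bfs(sub, i, j)
            if not paths:
                continue
            for x in comp:
                if x in (i, j):
                    continue
                through = sum(1 for p in paths if x in p)
                result[x] += through / len(paths)
    for comp in nx.connected_components(graph):
        n_c = len(comp)
        if n_c > 2:
            for x in comp:
                result[x] /= (n_c - 1) * (n_c - 2) / 2
    return result


def _all_shortest_paths_bfs(graph, source, target):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in graph.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    if target not in dist:
        return []
    paths = []

    def back(path):
        u = path[-1]
        if u == source:
            paths.append(list(reversed(path)))
            return
        for v in graph.neighbors(u):
            if dist.get(v, -1) == dist[u] - 1:
                back(path + [v])

    back([target])
    return paths


class TestCentrality:
    def test_degree_examples(self):
        tri = _net_from_edges([("A", "B"), ("B", "C"), ("A", "C")])
        assert degree_centrality(tri, "A") == 2
        star = _net_from_edges([("C", f"L{i}") for i in range(5)])
        assert degree_centrality(star, "C") == 5

    def test_degree_unknown_gene_rejected(self):
        with pytest.raises(ValidationError):
            degree_centrality(_net_from_edges([("A", "B")]), "Z")

    def test_degree_equals_adjacency_row_sum(self, rng):
        g = nx.gnp_random_graph(15, 0.3, seed=5)
        adj = nx.to_numpy_array(g)
        net = CoexpressionNetwork(graph=g)
        for i, node in enumerate(g.nodes):
            assert degree_centrality(net, node) == int(adj[i].sum())

    def test_path_graph_betweenness(self):
        net = _net_from_edges([("A", "B"), ("B", "C")])
        b = betweenness_all(net)
        assert b["B"] == pytest.approx(1.0)
        assert b["A"] == b["C"] == 0.0

    def test_complete_graph_betweenness_zero(self):
        net = CoexpressionNetwork(graph=nx.complete_graph(4))
        assert all(v == 0.0 for v in betweenness_all(net).values())

    def test_matches_bfs_enumeration_oracle(self):
        for seed in range(50):
            g = nx.gnp_random_graph(8, 0.35, seed=seed)
            net = CoexpressionNetwork(graph=g)
            ours = betweenness_all(net)
            expected = betweenness_oracle(g)
            for node in g.nodes:
                assert ours[node] == pytest.approx(expected[node], abs=1e-12)

    def test_values_in_unit_interval(self):
        g = nx.gnp_random_graph(20, 0.15, seed=11)
        for v in betweenness_all(CoexpressionNetwork(graph=g)).values():
            assert 0.0 <= v <= 1.0


class TestScoring:
    def _scored_path(self):
        net = _net_from_edges([("A", "B"), ("B", "C")])
        return score_nodes(extract_modules(net, min_module_size=3))

    def test_weight_is_degree_times_betweenness(self):
        scores = {s.gene_id: s for s in self._scored_path()}
        assert scores["B"].degree == 2
        assert scores["B"].betweenness == pytest.approx(1.0)
        assert scores["B"].weight == pytest.approx(2.0)

    def test_leaf_weight_zero(self):
        scores = {s.gene_id: s for s in self._scored_path()}
        assert scores["A"].degree == 1
        assert scores["A"].weight == 0.0

    def test_path_center_ranks_first(self):
        table = rank_genes(self._scored_path(), top_k=3)
        assert table.iloc[0]["gene_id"] == "B"
        assert table.iloc[0]["weight"] == pytest.approx(2.0)

    def test_ties_broken_by_degree_then_name(self):
        from coexnet import NodeScore

        scores = [
            NodeScore("GB", "M1", 3, 0.0, 0.0),
            NodeScore("GA", "M1", 1, 0.0, 0.0),
            NodeScore("GC", "M1", 3, 0.0, 0.0),
        ]
        table = rank_genes(scores, top_k=3)
        assert list(table["gene_id"]) == ["GB", "GC", "GA"]

    def test_top_k_clamped_to_node_count(self):
        table = rank_genes(self._scored_path(), top_k=100)
        assert len(table) == 3

    def test_scoring_requires_extracted_modules(self):
        with pytest.raises(ValidationError):
            score_nodes(_net_from_edges([("A", "B")]))

    def test_ranking_deterministic(self):
        a = rank_genes(self._scored_path(), top_k=3).to_csv()
        b = rank_genes(self._scored_path(), top_k=3).to_csv()
        assert a == b


class TestExports:
    def test_sif_round_trippable(self, tmp_path):
        net = extract_modules(
            _net_from_edges([("A", "B"), ("B", "C"), ("A", "C")]), min_module_size=3
        )
        path = tmp_path / "net.sif"
        write_sif(net, path)
        lines = path.read_text().strip().splitlines()
        assert "A\tcoexp\tB" in lines and len(lines) == 3

    def test_graphml_loadable_with_module_attribute(self, tmp_path):
        net = extract_modules(
            _net_from_edges([("A", "B"), ("B", "C"), ("A", "C")]), min_module_size=3
        )
        path = tmp_path / "net.graphml"
        write_graphml(net, path)
        loaded = nx.read_graphml(path)
        assert set(loaded.nodes) == {"A", "B", "C"}
        assert loaded.nodes["A"]["module"] == "M1"
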