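"""Graph operations against brute-force oracles on random instances."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from factorialtx.errors import DataError
from factorialtx.network import (
    all_shortest_paths,
    bfs_shells,
    build_network,
    connected_component,
    induce_subnetwork,
    shell_enrichment,
)


def edges_frame(pairs, types=None):
    types = types or ["negative genetic"] * len(pairs)
    return pd.DataFrame(
        {
            "gene_a": [a for a, _ in pairs],
            "gene_b": [b for _, b in pairs],
            "interaction_type": types,
            "system_type": ["genetic"] * len(pairs),
        }
    )


def random_graph(rng, n_max=50, p=0.15) -> nx.Graph:
    n = int(rng.integers(4, n_max + 1))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
    return nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


class TestBuildNetwork:
    def test_duplicate_edges_merge_type_labels(self):
        edges = edges_frame([("A", "B"), ("B", "A")], ["negative genetic", "synthetic lethal"])
        g = build_network(edges)
        assert g.number_of_edges() == 1
        assert g["A"]["B"]["types"] == {"negative genetic", "synthetic lethal"}

    def test_self_loop_dropped_node_kept(self):
        g = build_network(edges_frame([("A", "A")], ["positive genetic"]))
        assert g.number_of_edges() == 0
        assert "A" in g.nodes

    def test_edge_count_equals_distinct_unordered_pairs(self):
        rng = np.random.default_rng(0)
        nodes = [f"N{i}" for i in range(30)]
        pairs = [
            (nodes[rng.integers(30)], nodes[rng.integers(30)]) for _ in range(1000)
        ]
        g = build_network(edges_frame(pairs))
        distinct = {frozenset(p) for p in pairs if p[0] != p[1]}
        assert g.number_of_edges() == len(distinct)


class TestInduceAndComponent:
    def test_triangle_induced_to_single_edge(self):
        g = build_network(edges_frame([("A", "B"), ("B", "C"), ("C", "A")]))
        sub = induce_subnetwork(g, {"A", "B"})
        assert set(sub.nodes) == {"A", "B"} and sub.number_of_edges() == 1

    def test_disjoint_gene_set_gives_empty_network(self):
        g = build_network(edges_frame([("A", "B")]))
        assert induce_subnetwork(g, {"X"}).number_of_nodes() == 0

    def test_component_of_two_triangles(self):
        g = build_network(
            edges_frame([("A", "B"), ("B", "C"), ("C", "A"), ("X", "Y"), ("Y", "Z"), ("Z", "X")])
        )
        comp = connected_component(g, "A")
        assert set(comp.nodes) == {"A", "B", "C"}
        with pytest.raises(DataError):
            connected_component(g, "missing")

    def test_induction_matches_brute_force_edge_filter(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            g = random_graph(rng)
            keep = {n for n in g.nodes if rng.random() < 0.5}
            sub = induce_subnetwork(g, keep)
            expected = {frozenset(e) for e in g.edges if set(e) <= keep}
            assert {frozenset(e) for e in sub.edges} == expected


# ---------------------------------------------------------------------------
# shells
# ---------------------------------------------------------------------------


class TestBfsShells:
    def test_path_graph_shells_and_eccentricity(self):
        g = build_network(edges_frame([("A", "B"), ("B", "C"), ("C", "D")]))
        dec = bfs_shells(g, "A")
        assert dec.shells == {1: {"B"}, 2: {"C"}, 3: {"D"}}
        assert dec.eccentricity == 3
        assert dec.unreachable == set()

    def test_star_center_has_single_shell(self):
        g = build_network(edges_frame([("HUB", f"L{i}") for i in range(6)]))
        dec = bfs_shells(g, "HUB")
        assert dec.shells == {1: {f"L{i}" for i in range(6)}}
        assert dec.eccentricity == 1

    def test_shells_match_floyd_warshall_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            g = random_graph(rng)
            focal = sorted(g.nodes)[0]
            dec = bfs_shells(g, focal)
            dist = nx.floyd_warshall_numpy(g, nodelist=sorted(g.nodes))
            nodes = sorted(g.nodes)
            fi = nodes.index(focal)
            for j, node in enumerate(nodes):
                d = dist[fi, j]
                if node == focal:
                    continue
                if np.isinf(d):
                    assert node in dec.unreachable
                else:
                    assert node in dec.shells[int(d)]

    def test_shells_partition_reachable_nodes(self):
        rng = np.random.default_rng(5)
        g = random_graph(rng, n_max=40)
        focal = sorted(g.nodes)[0]
        dec = bfs_shells(g, focal)
        union = set().union(*dec.shells.values()) if dec.shells else set()
        assert union | {focal} | dec.unreachable == set(g.nodes)
        sizes = sum(len(s) for s in dec.shells.values())
        assert sizes == len(union)  # pairwise disjoint


# ---------------------------------------------------------------------------
# shortest paths
# ---------------------------------------------------------------------------


def exhaustive_shortest_paths(g: nx.Graph, source: str, target: str) -> set:
    """Oracle: depth-bounded DFS enumeration of all minimal-length paths."""
    shortest = nx.shortest_path_length(g, source, target)
    return {
        tuple(p)
        for p in nx.all_simple_paths(g, source, target, cutoff=shortest)
        if len(p) == shortest + 1
    }


class TestAllShortestPaths:
    def test_four_cycle_has_two_paths(self):
        g = build_network(edges_frame([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")]))
        ps = all_shortest_paths(g, "A", "C")
        assert set(ps.paths) == {("A", "B", "C"), ("A", "D", "C")}
        assert ps.length == 2 and not ps.truncated

    def test_tree_has_exactly_one_path(self):
        g = build_network(edges_frame([("R", "A"), ("R", "B"), ("A", "C"), ("A", "D")]))
        ps = all_shortest_paths(g, "R", "D")
        assert ps.paths == [("R", "A", "D")]

    def test_absent_vs_disconnected_distinguished(self):
        g = build_network(edges_frame([("A", "B"), ("X", "Y")]))
        with pytest.raises(DataError, match="absent"):
            all_shortest_paths(g, "A", "NOPE")
        with pytest.raises(DataError, match="disconnected"):
            all_shortest_paths(g, "A", "X")

    def test_truncation_flag_at_max_paths(self):
        # complete bipartite ladder: many equal-length paths
        g = nx.complete_bipartite_graph(4, 4)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
        ps = all_shortest_paths(g, "N0", "N1", max_paths=2)
        assert ps.truncated and len(ps.paths) == 2

    def test_matches_exhaustive_dfs_on_random_graphs(self):
        rng = np.random.default_rng(23)
        done = 0
        while done < 100:
            g = random_graph(rng, n_max=30, p=0.2)
            nodes = sorted(g.nodes)
            source, target = nodes[0], nodes[-1]
            if not nx.has_path(g, source, target) or source == target:
                continue
            ps = all_shortest_paths(g, source, target)
            assert set(ps.paths) == exhaustive_shortest_paths(g, source, target)
            assert all(len(p) - 1 == ps.length for p in ps.paths)
            # interior nodes of a shortest path sit in strictly increasing shells
            dec = bfs_shells(g, source)
            for p in ps.paths:
                for depth, node in enumerate(p[1:], start=1):
                    assert node in dec.shells[depth]
            done += 1

    def test_paths_emitted_in_lexicographic_order(self):
        g = build_network(edges_frame([("A", "B"), ("B", "C"), ("A", "D"), ("D", "C")]))
        ps = all_shortest_paths(g, "A", "C")
        assert ps.paths == sorted(ps.paths)


# ---------------------------------------------------------------------------
# shell enrichment
# ---------------------------------------------------------------------------


class TestShellEnrichment:
    def test_zero_hits_gives_p_one(self):
        res = shell_enrichment(["A", "B"], ["A", "B", "C", "D"], {"C": {"t"}}, "t")
        assert res.p == 1.0

    def test_counts_from_background_and_shell(self):
        annotation = {"A": {"t"}, "B": {"t"}, "C": {"t"}}
        res = shell_enrichment(["A", "B"], ["A", "B", "C", "D", "E"], annotation, "t")
        assert (res.k, res.n, res.K, res.N) == (2, 2, 3, 5)

    def test_empty_background_rejected(self):
        with pytest.raises(DataError):
            shell_enrichment(["A"], [], {}, "t")
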