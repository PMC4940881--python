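"""Genetic-interaction network analysis: typed simple graphs, BFS distance
shells around a focal gene, shortest-path enumeration, and shell-conditioned
annotation enrichment.

Edges are undirected and unweighted; parallel records collapse onto a single
edge that keeps the union of interaction-type labels (duplicate-edge
removal). "Distance" is always unweighted shortest-path length, and a shell
is the set of nodes at one fixed distance from the focal gene.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .containers import EnrichmentResult
from .enrichment import hypergeom_upper_tail
from .errors import DataError


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def build_network(edges: pd.DataFrame) -> nx.Graph:
    """Build an undirected simple graph from an interaction edge list.

    Self-loops are dropped (the node is kept); records for the same
    unordered pair merge, unioning their ``interaction_type`` labels into
    the edge attribute ``types``.
    """
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        a, b, itype = row.gene_a, row.gene_b, row.interaction_type
        g.add_node(a)
        g.add_node(b)
        if a == b:
            continue
        if g.has_edge(a, b):
            g[a][b]["types"].add(itype)
        else:
            g.add_edge(a, b, types={itype})
    return g


def induce_subnetwork(network: nx.Graph, gene_set) -> nx.Graph:
    """Subgraph on ``network ∩ gene_set`` (edges with both endpoints kept)."""
    nodes = set(gene_set) & set(network.nodes)
    return network.subgraph(nodes).copy()


def connected_component(network: nx.Graph, focal: str) -> nx.Graph:
    """Maximal connected subgraph containing ``focal``."""
    if focal not in network:
        raise DataError(f"focal gene {focal!r} is not in the network")
    return network.subgraph(nx.node_connected_component(network, focal)).copy()


# ---------------------------------------------------------------------------
# shells and paths
# ---------------------------------------------------------------------------


@dataclass
class ShellDecomposition:
    """Nodes grouped by unweighted distance to a focal gene."""

    focal: str
    shells: dict[int, set[str]]          # distance >= 1 -> node set
    eccentricity: int
    unreachable: set[str] = field(default_factory=set)

    def shell(self, d: int) -> set[str]:
        return self.shells.get(d, set())


def bfs_shells(network: nx.Graph, focal: str) -> ShellDecomposition:
    """Group every reachable node by its shortest-path distance to ``focal``."""
    if focal not in network:
        raise DataError(f"focal gene {focal!r} is not in the network")
    dist = nx.single_source_shortest_path_length(network, focal)
    shells: dict[int, set[str]] = {}
    for node, d in dist.items():
        if d > 0:
            shells.setdefault(d, set()).add(node)
    unreachable = set(network.nodes) - set(dist)
    ecc = max(shells) if shells else 0
    return ShellDecomposition(focal=focal, shells=shells, eccentricity=ecc, unreachable=unreachable)


@dataclass
class PathSet:
    """All shortest paths between one node pair."""

    source: str
    target: str
    length: int
    paths: list[tuple[str, ...]]
    truncated: bool = False


def all_shortest_paths(
    network: nx.Graph, source: str, target: str, max_paths: int = 10_000
) -> PathSet:
    """Enumerate every shortest path from source to target.

    Paths are generated from the BFS predecessor DAG in lexicographic node
    order and truncated (with a flag) at ``max_paths``. Distinguishes a
    target absent from the network from one in a different component.
    """
    for name, node in (("source", source), ("target", target)):
        if node not in network:
            raise DataError(f"{name} gene {node!r} is absent from the network")
    dist = nx.single_source_shortest_path_length(network, source)
    if target not in dist:
        raise DataError(f"target {target!r} is disconnected from source {source!r}")
    length = dist[target]

    paths: list[tuple[str, ...]] = []
    truncated = False

    def walk(node: str, suffix: tuple[str, ...]) -> bool:
        """Extend backwards from node; return False once truncated."""
        if node == source:
            if len(paths) >= max_paths:
                return False
            paths.append((source,) + suffix)
            return True
        preds = sorted(p for p in network.neighbors(node) if dist.get(p) == dist[node] - 1)
        for p in preds:
            if not walk(p, (node,) + suffix):
                return False
        return True

    truncated = not walk(target, ())
    return PathSet(source=source, target=target, length=length, paths=paths, truncated=truncated)


# ---------------------------------------------------------------------------
# shell-conditioned enrichment
# ---------------------------------------------------------------------------


def shell_enrichment(
    shell_genes,
    background_genes,
    annotation: dict[str, set[str]],
    term: str,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Hypergeometric over-representation of ``term`` in a distance shell.

    The background population need not contain the shell (the shell may come
    from a subnetwork while the background is a shell of the complete
    network); N and K are counted on the background, n and k on the shell.
    """
    background = set(background_genes)
    if not background:
        raise DataError("empty background population")
    shell = set(shell_genes)
    N, n = len(background), len(shell)
    K = sum(1 for g in background if term in annotation.get(g, ()))
    k = sum(1 for g in shell if term in annotation.get(g, ()))
    k = min(k, K)  # the background defines the annotated sub-population size
    p = hypergeom_upper_tail(k, n, K, N)
    return EnrichmentResult(term, k, n, K, N, p, p_adj=p, significant=p < alpha)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def write_sif(network: nx.Graph, path: str | os.PathLike) -> None:
    """Write the network as SIF lines ``node <type> node`` (one per type label)."""
    with open(path, "w", newline="\n") as fh:
        isolated = sorted(n for n in network.nodes if network.degree(n) == 0)
        for a, b, data in sorted(network.edges(data=True)):
            for t in sorted(data.get("types", {"other"})):
                fh.write(f"{a}\t{t.replace(' ', '_')}\t{b}\n")
        for node in isolated:
            fh.write(f"{node}\n")


def shell_table(decomposition: ShellDecomposition) -> pd.DataFrame:
    """Tabulate a shell decomposition (distance, size, members)."""
    rows = [
        {"distance": d, "size": len(nodes), "genes": ";".join(sorted(nodes))}
        for d, nodes in sorted(decomposition.shells.items())
    ]
    return pd.DataFrame(rows, columns=["distance", "size", "genes"])
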