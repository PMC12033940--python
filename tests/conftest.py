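"""Shared generators and independent brute-force oracles.

The oracles here deliberately avoid the code paths they check: distances
come from a hand-rolled BFS or Floyd-Warshall, clustering from explicit
triangle counting, modularity from the double sum over node pairs, and
set partitions from direct enumeration.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest


def random_graph(rng: np.random.Generator, n_max: int = 30, p: float | None = None) -> nx.Graph:
    """Erdos-Renyi-style random graph with confidence attributes, >= 1 edge."""
    while True:
        n = int(rng.integers(2, n_max + 1))
        p_edge = p if p is not None else float(rng.uniform(0.15, 0.7))
        g = nx.Graph()
        nodes = [f"N{i:03d}" for i in range(n)]
        g.add_nodes_from(nodes)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p_edge:
                    g.add_edge(nodes[i], nodes[j], confidence=float(rng.uniform(0.5, 1.0)))
        if g.number_of_edges() >= 1:
            return g


def bfs_distances(g: nx.Graph, source) -> dict:
    """Plain breadth-first distances, independent of networkx shortest paths."""
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in g.adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def brute_clustering(g: nx.Graph) -> dict:
    """Per-node clustering coefficient by explicit triangle counting."""
    out = {}
    for u in g.nodes:
        nbrs = list(g.adj[u])
        k = len(nbrs)
        if k < 2:
            out[u] = 0.0
            continue
        tri = sum(
            1
            for a, b in itertools.combinations(nbrs, 2)
            if g.has_edge(a, b)
        )
        out[u] = 2.0 * tri / (k * (k - 1))
    return out


def brute_modularity(g: nx.Graph, membership: dict) -> float:
    """Q as the explicit double sum over ordered node pairs."""
    two_e = 2.0 * g.number_of_edges()
    deg = dict(g.degree())
    nodes = list(g.nodes)
    q = 0.0
    for i in nodes:
        for j in nodes:
            if membership[i] != membership[j]:
                continue
            a_ij = 1.0 if g.has_edge(i, j) else 0.0
            q += a_ij - deg[i] * deg[j] / two_e
    return q / two_e


def brute_diameter(g: nx.Graph) -> int:
    """All-pairs BFS on the largest component."""
    comps = list(nx.connected_components(g))
    nodes = max(comps, key=len)
    sub = g.subgraph(nodes)
    best = 0
    for u in nodes:
        best = max(best, max(bfs_distances(sub, u).values()))
    return best


def set_partitions(items: list):
    """All set partitions of ``items`` (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1 :]
        yield [[first]] + smaller


def propagation_oracle(
    g: nx.Graph, initial: dict, n_repetitions: int, n_iterations: int, normalize: bool = True
) -> dict:
    """Exhaustive message-enumeration NetScore oracle via Floyd-Warshall."""
    nodes = sorted(g.nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v in g.edges:
        dist[idx[u], idx[v]] = dist[idx[v], idx[u]] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, k : k + 1] + dist[k : k + 1, :])

    s = np.array([float(initial.get(u, 0.0)) for u in nodes])
    for _ in range(n_repetitions):
        new = np.zeros(n)
        for i in range(n):
            origins = [j for j in range(n) if dist[i, j] <= n_iterations]
            new[i] = sum(s[j] / (dist[i, j] + 1.0) for j in origins) / len(origins)
        if normalize and new.max() > 0:
            new = new / new.max()
        s = new
    return dict(zip(nodes, s.tolist()))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
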