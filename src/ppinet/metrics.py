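"""Network characterisation: degree, clustering, density, modularity, diameter.

The five statistics printed for every baseline network:

* average degree  AD = 2E/N
* average clustering coefficient  Ca = (1/N) sum_i C_i, with C_i the
  triangle density around node i (C_i = 0 for degree < 2)
* network density  D = 2E / (N(N-1))
* modularity  Q = (1/2E) sum_ij [A_ij - k_i k_j / 2E] delta(c_i, c_j),
  maximised with the Louvain heuristic
* diameter: the longest unweighted shortest-path distance between any two
  nodes (computed on the largest component when disconnected)

All are unweighted: edge confidences do not enter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import networkx as nx

__all__ = [
    "Partition",
    "NetworkMetrics",
    "average_degree",
    "average_clustering",
    "density",
    "modularity",
    "louvain_maximize",
    "diameter",
    "compute_metrics",
]


@dataclass
class Partition:
    """Disjoint community assignment with contiguous ids from 0."""

    membership: dict[str, int]

    def __post_init__(self) -> None:
        ids = sorted(set(self.membership.values()))
        if ids and ids != list(range(len(ids))):
            # relabel to contiguous ids, ordered by smallest member node
            by_old: dict[int, list[str]] = {}
            for node, cid in self.membership.items():
                by_old.setdefault(cid, []).append(node)
            order = sorted(by_old, key=lambda cid: min(by_old[cid]))
            relabel = {old: new for new, old in enumerate(order)}
            self.membership = {n: relabel[c] for n, c in self.membership.items()}

    @classmethod
    def from_communities(cls, communities) -> "Partition":
        membership: dict[str, int] = {}
        for cid, comm in enumerate(sorted((sorted(c) for c in communities), key=lambda c: c[0])):
            for node in comm:
                if node in membership:
                    raise ValueError(f"node {node!r} assigned to two communities")
                membership[node] = cid
        return cls(membership=membership)

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values())) if self.membership else 0

    def communities(self) -> list[set[str]]:
        out: dict[int, set[str]] = {}
        for node, cid in self.membership.items():
            out.setdefault(cid, set()).add(node)
        return [out[c] for c in sorted(out)]


@dataclass
class NetworkMetrics:
    """The printed statistics of one network."""

    n_nodes: int
    n_edges: int
    average_degree: float
    average_clustering: float
    density: float
    modularity: float
    diameter: int
    partition: Partition | None = None
    clustering_per_node: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("partition")
        d.pop("clustering_per_node")
        d["n_communities"] = self.partition.n_communities if self.partition else None
        return d


def average_degree(net: nx.Graph) -> float:
    """AD = 2E/N; equals the mean of the per-node degrees."""
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("average degree of an empty graph is undefined")
    return 2.0 * net.number_of_edges() / n


def average_clustering(net: nx.Graph) -> tuple[float, dict[str, float]]:
    """Mean clustering coefficient over all N nodes, with per-node values.

    ``C_i = 2 * triangles(i) / (k_i (k_i - 1))``, 0 for nodes of degree
    below 2; the mean runs over every node, isolated ones included.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("clustering of an empty graph is undefined")
    per_node = nx.clustering(net)
    return sum(per_node.values()) / len(per_node), dict(per_node)


def density(net: nx.Graph) -> float:
    """D = 2E / (N(N-1))."""
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("density requires at least two nodes")
    return 2.0 * net.number_of_edges() / (n * (n - 1))


def modularity(net: nx.Graph, partition: Partition) -> float:
    """Newman-Girvan modularity of a partition.

    Q = (1/2E) sum over ordered node pairs of
    [A_ij - k_i k_j / 2E] delta(c_i, c_j), with A the unweighted
    adjacency indicator.
    """
    if net.number_of_edges() == 0:
        raise ValueError("modularity requires at least one edge")
    uncovered = set(net.nodes) - set(partition.membership)
    if uncovered:
        raise ValueError(f"partition does not cover nodes: {sorted(uncovered)[:10]}")
    comms = [c & set(net.nodes) for c in partition.communities()]
    comms = [c for c in comms if c]
    return float(nx.community.modularity(net, comms, weight=None))


def louvain_maximize(net: nx.Graph, rng_seed: int = 0) -> tuple[Partition, float]:
    """Louvain modularity maximisation (two-phase greedy heuristic).

    Node visit order is shuffled deterministically by ``rng_seed`` so
    repeated runs return identical partitions.
    """
    if net.number_of_edges() == 0:
        raise ValueError("Louvain requires at least one edge")
    communities = nx.community.louvain_communities(net, weight=None, seed=rng_seed)
    partition = Partition.from_communities(communities)
    return partition, modularity(net, partition)


def diameter(net: nx.Graph) -> int:
    """Longest shortest-path distance; on the largest component if disconnected."""
    if net.number_of_nodes() == 0:
        raise ValueError("diameter of an empty graph is undefined")
    if net.number_of_nodes() == 1:
        return 0
    if nx.is_connected(net):
        return int(nx.diameter(net))
    warnings.warn(
        "graph is disconnected; diameter computed on the largest component",
        stacklevel=2,
    )
    largest = max(nx.connected_components(net), key=len)
    if len(largest) == 1:
        return 0
    return int(nx.diameter(net.subgraph(largest)))


def compute_metrics(net: nx.Graph, rng_seed: int = 0) -> NetworkMetrics:
    """All five statistics of a network in one pass."""
    ca, per_node = average_clustering(net)
    if net.number_of_edges() > 0:
        partition, q = louvain_maximize(net, rng_seed=rng_seed)
    else:
        partition, q = None, 0.0
    return NetworkMetrics(
        n_nodes=net.number_of_nodes(),
        n_edges=net.number_of_edges(),
        average_degree=average_degree(net),
        average_clustering=ca,
        density=density(net),
        modularity=q,
        diameter=diameter(net),
        partition=partition,
        clustering_per_node=per_node,
    )
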