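"""Condition-specific network construction.

Each experimental case's network is built in three steps against a
reference interactome:

1. filter the reference to the tissue universe (induced subgraph on the
   proteins detected in the tissue);
2. add the condition proteins (stimulating cytokines) and their first
   neighbours in the reference, closing over all reference edges among the
   retained nodes;
3. enrich to a single connected component by repeatedly merging the two
   closest components along an unweighted shortest path of the reference,
   so that score propagation can reach every node.

All steps are deterministic: ties between component pairs are broken by
(distance, lexicographically smallest endpoint pair), and among tied
shortest paths the lexicographically smallest interior-node sequence is
used.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "BuildReport",
    "filter_by_universe",
    "add_condition_neighbourhood",
    "enrich_connect",
    "build_case_network",
]


@dataclass
class BuildReport:
    """Counts describing one case-network build."""

    n_universe_kept: int = 0
    n_condition_added: int = 0
    n_neighbours_added: int = 0
    n_bridge_nodes_added: int = 0
    final_n_nodes: int = 0
    final_n_edges: int = 0
    connected: bool = False
    # one entry per component merge: endpoints, reference distance, interior path
    merges: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _induced(reference: nx.Graph, nodes, name: str | None = None) -> nx.Graph:
    # built node-by-node in sorted order so graph iteration (and with it
    # every downstream reduction and heuristic) is independent of set
    # iteration order / hash randomization
    ordered = sorted(set(nodes))
    member = set(ordered)
    sub = nx.Graph()
    if name is not None:
        sub.graph["name"] = name
    sub.add_nodes_from(ordered)
    for u in ordered:
        for v in sorted(reference.adj[u]):
            if u < v and v in member:
                sub.add_edge(u, v, **reference.edges[u, v])
    return sub


def filter_by_universe(reference: nx.Graph, universe: set[str]) -> nx.Graph:
    """Induced subgraph of ``reference`` on the tissue universe.

    Raises
    ------
    ValueError
        If no universe protein occurs in the reference; the message lists
        the first few unmatched identifiers to aid diagnosis.
    """
    kept = set(reference.nodes) & set(universe)
    if not kept:
        unmatched = sorted(universe)[:10]
        raise ValueError(
            "universe does not intersect the reference interactome; "
            f"first unmatched identifiers: {unmatched}"
        )
    return _induced(reference, kept, name=reference.graph.get("name"))


def add_condition_neighbourhood(
    net: nx.Graph, reference: nx.Graph, condition_proteins: set[str]
) -> nx.Graph:
    """Add condition proteins and their reference first neighbours to ``net``.

    Condition proteins absent from the reference are warned about and
    skipped.  The result is the reference-induced subgraph on the enlarged
    node set, so every known interaction among the retained proteins is
    kept.
    """
    present = {p for p in condition_proteins if p in reference}
    missing = set(condition_proteins) - present
    if missing:
        warnings.warn(
            f"condition proteins absent from reference, skipped: {sorted(missing)}",
            stacklevel=2,
        )
    nodes = set(net.nodes) | present
    for p in present:
        nodes |= set(reference.neighbors(p))
    return _induced(reference, nodes, name=net.graph.get("name"))


def _lexicographic_shortest_path(reference: nx.Graph, source: str, target: str) -> list[str]:
    """Lexicographically smallest shortest path from source to target.

    Greedy over a reverse-BFS distance map: at each step move to the
    smallest neighbour that is one hop closer to the target.
    """
    dist_to_target = nx.single_source_shortest_path_length(reference, target)
    if source not in dist_to_target:
        raise nx.NetworkXNoPath(f"no path {source} -> {target}")
    path = [source]
    current = source
    while current != target:
        remaining = dist_to_target[current]
        nxt = min(
            n for n in reference.neighbors(current) if dist_to_target.get(n, -1) == remaining - 1
        )
        path.append(nxt)
        current = nxt
    return path


def _closest_pair_between(
    reference: nx.Graph, comp_a: set[str], comp_b: set[str]
) -> tuple[int, tuple[str, str]] | None:
    """Minimal reference distance between two components and its best endpoint pair.

    Returns ``None`` when the reference offers no path.  Among pairs at the
    minimal distance the lexicographically smallest sorted endpoint pair is
    chosen.
    """
    best: tuple[int, tuple[str, str]] | None = None
    for a in comp_a:
        dist = nx.single_source_shortest_path_length(reference, a)
        for b in comp_b:
            d = dist.get(b)
            if d is None:
                continue
            key = (d, tuple(sorted((a, b))))
            if best is None or key < best:
                best = key
    return best


def enrich_connect(net: nx.Graph, reference: nx.Graph) -> tuple[nx.Graph, BuildReport]:
    """Connect ``net`` into a single component via reference shortest paths.

    While more than one connected component remains, the pair of components
    whose closest node pair is at minimal unweighted reference distance is
    merged by adding the interior nodes of one shortest path between that
    node pair, then closing over reference edges.  Deterministic
    tie-breaking: component pairs ordered by (distance, smallest endpoint
    pair); among tied paths the lexicographically smallest interior
    sequence.

    If the reference itself does not connect the nodes, the best-effort
    partial result is returned with ``connected=False`` and a warning.
    """
    stray = set(net.nodes) - set(reference.nodes)
    if stray:
        raise ValueError(f"nodes absent from reference: {sorted(stray)[:10]}")

    nodes = set(net.nodes)
    current = _induced(reference, nodes, name=net.graph.get("name"))
    n_added = 0
    report = BuildReport()

    while True:
        comps = [set(c) for c in nx.connected_components(current)]
        if len(comps) <= 1:
            report.connected = True
            break
        comps.sort(key=lambda c: min(c))
        best = None  # (distance, endpoint_pair, i, j)
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                pair = _closest_pair_between(reference, comps[i], comps[j])
                if pair is None:
                    continue
                key = (pair[0], pair[1])
                if best is None or key < best[:2]:
                    best = (pair[0], pair[1], i, j)
        if best is None:
            warnings.warn(
                "reference interactome does not connect the node set; "
                f"returning {len(comps)} components",
                stacklevel=2,
            )
            report.connected = False
            break
        d, (a, b), _, _ = best
        path = _lexicographic_shortest_path(reference, a, b)
        interior = [n for n in path[1:-1] if n not in nodes]
        report.merges.append(
            {
                "endpoints": (a, b),
                "distance": d,
                "path": list(path),
                "nodes_before": sorted(nodes),
                "added": list(interior),
            }
        )
        nodes.update(interior)
        n_added += len(interior)
        current = _induced(reference, nodes, name=net.graph.get("name"))

    report.n_bridge_nodes_added = n_added
    report.final_n_nodes = current.number_of_nodes()
    report.final_n_edges = current.number_of_edges()
    return current, report


def build_case_network(
    reference: nx.Graph,
    universe: set[str],
    condition_proteins: set[str] | None = None,
) -> tuple[nx.Graph, BuildReport]:
    """Full case-network build: filter, add condition neighbourhood, connect."""
    condition_proteins = condition_proteins or set()
    filtered = filter_by_universe(reference, universe)
    n_universe_kept = filtered.number_of_nodes()

    before = set(filtered.nodes)
    with_condition = add_condition_neighbourhood(filtered, reference, condition_proteins)
    added = set(with_condition.nodes) - before
    n_condition_added = len(added & set(condition_proteins))
    n_neighbours_added = len(added - set(condition_proteins))

    connected_net, report = enrich_connect(with_condition, reference)
    report.n_universe_kept = n_universe_kept
    report.n_condition_added = n_condition_added
    report.n_neighbours_added = n_neighbours_added
    logger.info(
        "built %s: %d nodes, %d edges (universe %d, +%d condition, +%d neighbours, +%d bridges)",
        reference.graph.get("name", "network"),
        report.final_n_nodes,
        report.final_n_edges,
        n_universe_kept,
        n_condition_added,
        n_neighbours_added,
        report.n_bridge_nodes_added,
    )
    return connected_net, report
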