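"""Topology metrics, centralities, ego subnetworks and network comparisons.

Reported metrics follow the common co-occurrence-network conventions:
average degree is 2E/N; weighted degree is the mean over nodes of the summed
absolute edge correlations; the clustering coefficient is the mean local
(unweighted) clustering with nodes of degree < 2 contributing 0; the
diameter is the longest shortest path within the largest connected
component (the networks are typically disconnected); modularity is Newman
modularity of the best partition found by seeded Louvain with restarts,
using |r| as the edge weight. "Connectivity" is reported as the number of
connected components.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np

from tickmicro.diversity import venn_sets
from tickmicro.tables_io import CooccurrenceNetwork

__all__ = [
    "TopologyReport",
    "topology_report",
    "louvain_partition",
    "eigenvector_centrality",
    "ego_subnetwork",
    "focal_degree",
    "compare_node_sets",
]


@dataclass
class TopologyReport:
    """One row of a topology table (nodes, edges, modularity, ...)."""

    name: str
    n_nodes: int
    n_edges: int
    n_pos: int
    n_neg: int
    modularity: float
    diameter: int | float
    avg_degree: float
    weighted_degree: float
    clustering_coeff: float
    n_components: int

    def __post_init__(self) -> None:
        if self.n_nodes:
            assert self.n_pos + self.n_neg == self.n_edges
            assert abs(self.avg_degree - 2 * self.n_edges / self.n_nodes) < 1e-12

    def to_dict(self) -> dict:
        return asdict(self)


def _abs_weight_graph(g: nx.Graph) -> nx.Graph:
    h = nx.Graph()
    h.add_nodes_from(g.nodes)
    for u, v, d in g.edges(data=True):
        h.add_edge(u, v, weight=abs(float(d.get("weight", 1.0))))
    return h


def louvain_partition(
    net: CooccurrenceNetwork, seed: int = 0, restarts: int = 10
) -> tuple[dict, float]:
    """Best-of-``restarts`` seeded Louvain partition on |r| weights.

    Louvain is order-dependent; restarts with consecutive seeds keep the
    partition with the highest Newman modularity. Returns (node -> module id,
    modularity). Modularity of an empty graph is NaN.
    """
    g = _abs_weight_graph(net.graph)
    if g.number_of_edges() == 0:
        return {n: 0 for n in g.nodes}, float("nan")
    best_q, best_comms = -np.inf, None
    for k in range(restarts):
        comms = nx.community.louvain_communities(g, weight="weight", seed=seed + k)
        q = nx.community.modularity(g, comms, weight="weight")
        if q > best_q:
            best_q, best_comms = q, comms
    ordered = sorted(best_comms, key=lambda c: sorted(c)[0])
    partition = {n: i for i, c in enumerate(ordered) for n in c}
    return partition, float(best_q)


def topology_report(net: CooccurrenceNetwork, seed: int = 0, name: str | None = None) -> TopologyReport:
    """Standard topology metrics for one network (one table row)."""
    g = net.graph
    if g.number_of_nodes() == 0:
        return TopologyReport(
            name=name or net.name, n_nodes=0, n_edges=0, n_pos=0, n_neg=0,
            modularity=float("nan"), diameter=float("nan"), avg_degree=float("nan"),
            weighted_degree=float("nan"), clustering_coeff=float("nan"), n_components=0,
        )
    n_pos = sum(1 for _, _, d in g.edges(data=True) if float(d.get("weight", 1.0)) >= 0)
    n_neg = g.number_of_edges() - n_pos
    _, q = louvain_partition(net, seed=seed)
    components = list(nx.connected_components(g))
    largest = max(components, key=lambda c: (len(c), sorted(c)[0]))
    diameter = nx.diameter(g.subgraph(largest)) if len(largest) > 1 else 0
    wdeg = np.array(
        [sum(abs(float(d.get("weight", 1.0))) for _, _, d in g.edges(n, data=True)) for n in g.nodes]
    )
    return TopologyReport(
        name=name or net.name,
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        n_pos=n_pos,
        n_neg=n_neg,
        modularity=q,
        diameter=diameter,
        avg_degree=2 * g.number_of_edges() / g.number_of_nodes(),
        weighted_degree=float(wdeg.mean()),
        clustering_coeff=nx.average_clustering(g),
        n_components=len(components),
    )


def eigenvector_centrality(net: CooccurrenceNetwork) -> dict[str, float]:
    """Principal-eigenvector scores on the |r|-weighted adjacency.

    Computed per connected component (the dominant eigenvector of a
    disconnected graph is supported on one component only); scores are
    normalized so the global maximum is 1. Isolated nodes score 0.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        raise ValueError("eigenvector centrality needs at least one edge")
    scores: dict[str, float] = {n: 0.0 for n in g.nodes}
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        if len(comp) == 1:
            continue
        sub = g.subgraph(comp)
        a = np.abs(nx.to_numpy_array(sub, nodelist=comp, weight="weight"))
        vals, vecs = np.linalg.eigh(a)
        vec = np.abs(vecs[:, -1])
        for node, s in zip(comp, vec):
            scores[node] = float(s)
    top = max(scores.values())
    if top > 0:
        scores = {n: s / top for n, s in scores.items()}
    return scores


def ego_subnetwork(
    net: CooccurrenceNetwork, focal: str, order: int = 1
) -> CooccurrenceNetwork:
    """Induced subgraph on the focal taxon and its neighbors within ``order``."""
    if focal not in net.graph:
        raise KeyError(f"focal taxon {focal!r} not in network")
    ego = nx.ego_graph(net.graph, focal, radius=order)
    induced = net.graph.subgraph(ego.nodes).copy()
    return CooccurrenceNetwork(
        induced, threshold_r=net.threshold_r, alpha=net.alpha,
        name=f"{net.name}_ego_{focal}" if net.name else f"ego_{focal}",
    )


def focal_degree(net: CooccurrenceNetwork, focal: str) -> int:
    """Number of distinct first-order neighbors of the focal taxon."""
    if focal not in net.graph:
        raise KeyError(f"focal taxon {focal!r} not in network")
    return int(net.graph.degree(focal))


def compare_node_sets(nets: dict[str, CooccurrenceNetwork]) -> dict:
    """Venn partition of node sets across named networks."""
    if len(nets) < 2:
        raise ValueError("need at least two networks to compare")
    return venn_sets({name: set(n.graph.nodes) for name, n in nets.items()})
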