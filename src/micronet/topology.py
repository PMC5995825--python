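"""Module detection and whole-network topological indices.

Communities are found by fast-greedy (Clauset-Newman-Moore) modularity
maximization on the sign-blind, unweighted graph. The six summary indices
are modularity (MD), average clustering coefficient (CC), average path
length (APL, mean over connected ordered pairs), network diameter (ND, the
longest shortest path among connected pairs), average degree (AD = 2E/N)
and graph density (GD = 2E/(N(N-1))).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .correlation import CoNetwork

__all__ = ["ModulePartition", "NetworkIndices", "detect_modules", "network_indices"]

INDEX_NAMES = ("MD", "CC", "APL", "ND", "AD", "GD")


@dataclass
class ModulePartition:
    membership: dict  # node -> module id (e.g. "M1")
    modularity: float

    @property
    def module_ids(self) -> list:
        return sorted(set(self.membership.values()))

    def members(self, module_id) -> list:
        return sorted(n for n, m in self.membership.items() if m == module_id)

    def sizes(self) -> dict:
        sizes: dict = {}
        for m in self.membership.values():
            sizes[m] = sizes.get(m, 0) + 1
        return sizes

    def as_sets(self) -> list[set]:
        return [set(self.members(m)) for m in self.module_ids]


@dataclass
class NetworkIndices:
    md: float
    cc: float
    apl: float
    nd: float
    ad: float
    gd: float
    n_nodes: int
    n_edges: int

    def as_dict(self) -> dict:
        return {
            "MD": self.md, "CC": self.cc, "APL": self.apl, "ND": self.nd,
            "AD": self.ad, "GD": self.gd,
            "n_nodes": self.n_nodes, "n_edges": self.n_edges,
        }

    def __getitem__(self, name: str) -> float:
        return self.as_dict()[name]


def _as_graph(network) -> nx.Graph:
    return network.graph if isinstance(network, CoNetwork) else network


def detect_modules(network: CoNetwork | nx.Graph) -> ModulePartition:
    """Fast-greedy modularity maximization (Clauset-Newman-Moore).

    Edge signs and weights are ignored. Nodes are processed in a canonical
    sorted order so the result is deterministic for a given edge set. Module
    ids are assigned M1, M2, ... in decreasing size order.
    """
    g = _as_graph(network)
    if g.number_of_nodes() == 0:
        raise ValueError("cannot detect modules in an empty graph")
    if g.number_of_edges() == 0:
        communities = [{n} for n in sorted(g.nodes())]
    else:
        communities = [set(c) for c in nx.community.greedy_modularity_communities(g)]
    communities.sort(key=lambda c: (-len(c), sorted(c)[0]))
    membership = {}
    for idx, comm in enumerate(communities, start=1):
        for node in comm:
            membership[node] = f"M{idx}"
    q = nx.community.modularity(g, communities) if g.number_of_edges() else 0.0
    return ModulePartition(membership=membership, modularity=float(q))


def modularity_of(network: CoNetwork | nx.Graph, partition: ModulePartition) -> float:
    """Newman's Q recomputed from an explicit partition (sign-blind, unweighted)."""
    g = _as_graph(network)
    return float(nx.community.modularity(g, partition.as_sets()))


def path_length_stats(g: nx.Graph) -> tuple[float, float]:
    """(APL, ND) over connected ordered pairs; (nan, nan) if no such pair."""
    total = 0
    count = 0
    diameter = 0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        for d in lengths.values():
            if d > 0:
                total += d
                count += 1
                if d > diameter:
                    diameter = d
    if count == 0:
        return float("nan"), float("nan")
    return total / count, float(diameter)


def average_clustering(g: nx.Graph, cc_mode: str = "exclude_low_degree") -> float:
    """Mean local clustering coefficient.

    ``cc_mode="exclude_low_degree"`` (default) averages over nodes of degree
    >= 2 only, the igraph average-local-transitivity convention;
    ``"count_zeros"`` includes degree-<2 nodes as 0.
    """
    if cc_mode == "count_zeros":
        return float(nx.average_clustering(g))
    if cc_mode != "exclude_low_degree":
        raise ValueError(f"unknown cc_mode {cc_mode!r}")
    eligible = [n for n, d in g.degree() if d >= 2]
    if not eligible:
        return 0.0
    local = nx.clustering(g, nodes=eligible)
    return float(sum(local.values()) / len(eligible))


def network_indices(
    network: CoNetwork | nx.Graph,
    partition: ModulePartition | None = None,
    cc_mode: str = "exclude_low_degree",
) -> NetworkIndices:
    """Compute the six topological indices of a co-occurrence network.

    CC is the mean local clustering coefficient over nodes of degree >= 2
    (``cc_mode`` switches to counting them as 0); APL averages
    shortest-path lengths over connected ordered pairs only (disconnected
    pairs are excluded, not infinite).
    """
    g = _as_graph(network)
    n = g.number_of_nodes()
    e = g.number_of_edges()
    if n == 0:
        raise ValueError("indices undefined for an empty graph")
    if partition is None:
        partition = detect_modules(g)
    cc = average_clustering(g, cc_mode)
    apl, nd = path_length_stats(g)
    ad = 2.0 * e / n
    gd = 2.0 * e / (n * (n - 1)) if n > 1 else float("nan")
    return NetworkIndices(
        md=partition.modularity, cc=float(cc), apl=apl, nd=nd,
        ad=ad, gd=gd, n_nodes=n, n_edges=e,
    )


def closed_form_density(n_nodes: int, n_edges: int) -> float:
    """GD = 2E / (N (N-1))."""
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def closed_form_average_degree(n_nodes: int, n_edges: int) -> float:
    """AD = 2E / N."""
    return 2.0 * n_edges / n_nodes
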