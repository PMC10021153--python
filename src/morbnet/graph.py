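"""Weighted undirected disease network and its node/network attributes.

Edges carry the symmetrized age-adjusted odds ratio as their weight.
For path-based measures an OR weight is turned into a distance, by
default ``distance = 1 / OR`` so that stronger associations mean
shorter paths.  Shortest paths use Dijkstra; betweenness uses Brandes'
dependency accumulation; closeness uses the Wasserman-Faust component
correction so disconnected networks (an isolated disease is a real
occurrence) have a well-defined convention:

* isolated node: closeness 0, betweenness 0;
* closeness of node v: ``(r-1)/sum(d(v,u))`` over the ``r-1`` reachable
  nodes, scaled by ``(r-1)/(n-1)``;
* betweenness normalized by ``(n-1)(n-2)/2`` (undirected);
* diameter: largest finite shortest-path distance, i.e. the diameter of
  the largest connected component (0 for an edgeless network);
* density: ``2E / (n(n-1))``.
"""

from __future__ import annotations

import heapq
import itertools
import json
import math
from dataclasses import dataclass, field
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd

from .association import EdgeRecord
from .codebook import CODES, DiseaseCode

__all__ = [
    "DiseaseNetwork",
    "NodeCentrality",
    "NetworkAttributes",
    "build_network",
    "degree",
    "shortest_paths",
    "closeness",
    "betweenness",
    "diameter",
    "density",
    "centrality_table",
    "network_attributes",
    "write_graphml",
]

INF = math.inf


@dataclass
class DiseaseNetwork:
    """Weighted undirected network over the full disease node set.

    All nodes of the codebook are present even when isolated.  At most
    one edge per unordered pair; no self-loops.  ``node_prevalence``
    carries the weighted prevalence used as node size.
    """

    nodes: tuple[str, ...]
    edges: dict[frozenset, float]
    node_prevalence: dict[str, float] = field(default_factory=dict)
    distance_transform: str = "reciprocal"

    def __post_init__(self) -> None:
        if self.distance_transform not in ("reciprocal", "inverse_log"):
            raise ValueError(f"unknown distance transform {self.distance_transform!r}")
        for pair, w in self.edges.items():
            if len(pair) != 2:
                raise ValueError("self-loops are not allowed")
            if not set(pair) <= set(self.nodes):
                raise KeyError(f"edge endpoints {set(pair)} outside the node set")
            if not (w > 0):
                raise ValueError(f"edge weight must be positive, got {w}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, node: str) -> dict[str, float]:
        """Adjacent nodes with edge weights."""
        if node not in self.nodes:
            raise KeyError(f"unknown node {node!r}")
        out = {}
        for pair, w in self.edges.items():
            if node in pair:
                (other,) = pair - {node}
                out[other] = w
        return out

    def edge_distance(self, weight: float) -> float:
        """Transform an OR weight into a path distance."""
        if self.distance_transform == "reciprocal":
            return 1.0 / weight
        d = math.log(weight)
        if d <= 0:
            raise ValueError(
                f"inverse_log transform undefined for weight {weight} <= 1")
        return 1.0 / d

    def adjacency(self) -> dict[str, dict[str, float]]:
        """Node -> {neighbor: transformed distance} adjacency map."""
        adj: dict[str, dict[str, float]] = {v: {} for v in self.nodes}
        for pair, w in self.edges.items():
            a, b = tuple(pair)
            d = self.edge_distance(w)
            adj[a][b] = d
            adj[b][a] = d
        return adj


def build_network(prevalences: pd.DataFrame | dict | None,
                  edges: list[EdgeRecord],
                  nodes: tuple[str, ...] = CODES,
                  distance_transform: str = "reciprocal",
                  included_only: bool = True) -> DiseaseNetwork:
    """Assemble the disease network from prevalences and edge records.

    Keeps all codebook nodes (isolates included).  Duplicate unordered
    pairs are deduplicated when their weights agree and raise when they
    conflict.  ``included_only=True`` (default) keeps only edges flagged
    ``included``.
    """
    prev: dict[str, float] = {}
    if isinstance(prevalences, pd.DataFrame):
        prev = dict(zip(prevalences["disease"], prevalences["prev_weighted"]))
    elif isinstance(prevalences, dict):
        prev = dict(prevalences)

    edge_map: dict[frozenset, float] = {}
    for e in edges:
        if included_only and not e.included:
            continue
        key = frozenset((e.node_a, e.node_b))
        if len(key) != 2:
            raise ValueError(f"self-loop on {e.node_a}")
        if key in edge_map and not math.isclose(edge_map[key], e.weight,
                                                rel_tol=1e-12, abs_tol=1e-12):
            raise ValueError(
                f"conflicting weights for edge {set(key)}: {edge_map[key]} vs {e.weight}")
        edge_map[key] = float(e.weight)
    return DiseaseNetwork(tuple(nodes), edge_map, prev, distance_transform)


def degree(network: DiseaseNetwork, node: str) -> int:
    """Number of incident edges (for an undirected network the in/out
    tie counts collapse to this single incidence count)."""
    return len(network.neighbors(node))


def shortest_paths(network: DiseaseNetwork, source: str) -> dict[str, float]:
    """Dijkstra distances from ``source``; unreachable nodes map to inf."""
    adj = network.adjacency()
    if source not in adj:
        raise KeyError(f"unknown node {source!r}")
    dist = {v: INF for v in network.nodes}
    dist[source] = 0.0
    heap = [(0.0, source)]
    done = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        for v, w in adj[u].items():
            nd = d + w
            if nd < dist[v] - 1e-12:
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    return dist


def closeness(network: DiseaseNetwork, node: str) -> float:
    """Component-corrected (Wasserman-Faust) closeness centrality.

    ``(r-1)/sum(d)`` over the r-1 reachable nodes, scaled by
    ``(r-1)/(n-1)``; 0 for an isolated node.
    """
    dist = shortest_paths(network, node)
    reach = [d for v, d in dist.items() if v != node and math.isfinite(d)]
    r_minus_1 = len(reach)
    if r_minus_1 == 0:
        return 0.0
    total = sum(reach)
    n = network.n_nodes
    return (r_minus_1 / total) * (r_minus_1 / (n - 1))


def _brandes_single_source(adj: dict[str, dict[str, float]], s: str,
                           bc: dict[str, float]) -> None:
    """One source of Brandes' algorithm (weighted, Dijkstra variant)."""
    dist = {v: INF for v in adj}
    sigma = {v: 0.0 for v in adj}
    pred: dict[str, list[str]] = {v: [] for v in adj}
    dist[s] = 0.0
    sigma[s] = 1.0
    stack: list[str] = []
    seen = set()
    heap = [(0.0, s)]
    while heap:
        d, u = heapq.heappop(heap)
        if u in seen:
            continue
        seen.add(u)
        stack.append(u)
        for v, w in adj[u].items():
            nd = d + w
            if nd < dist[v] - 1e-12:
                dist[v] = nd
                sigma[v] = sigma[u]
                pred[v] = [u]
                heapq.heappush(heap, (nd, v))
            elif abs(nd - dist[v]) <= 1e-12 and v not in seen:
                sigma[v] += sigma[u]
                pred[v].append(u)
    delta = {v: 0.0 for v in adj}
    for u in reversed(stack):
        for p in pred[u]:
            delta[p] += sigma[p] / sigma[u] * (1.0 + delta[u])
        if u != s:
            bc[u] += delta[u]


def betweenness(network: DiseaseNetwork, node: str | None = None,
                normalized: bool = True) -> float | dict[str, float]:
    """Brandes betweenness: pair-dependencies over weighted geodesics.

    Each unordered pair (s, t) contributes ``sigma_st(v)/sigma_st``.
    Normalization (default) divides by ``(n-1)(n-2)/2``.  With
    ``node=None`` the full node -> value map is returned.
    """
    adj = network.adjacency()
    bc = {v: 0.0 for v in network.nodes}
    for s in network.nodes:
        _brandes_single_source(adj, s, bc)
    # undirected: every pair counted from both endpoints
    for v in bc:
        bc[v] /= 2.0
    n = network.n_nodes
    if normalized and n > 2:
        scale = 2.0 / ((n - 1) * (n - 2))
        for v in bc:
            bc[v] *= scale
    if node is None:
        return bc
    if node not in bc:
        raise KeyError(f"unknown node {node!r}")
    return bc[node]


def diameter(network: DiseaseNetwork) -> float:
    """Largest finite shortest-path distance (largest component); 0 if
    the network has no edges."""
    best = 0.0
    for s in network.nodes:
        dist = shortest_paths(network, s)
        finite = [d for d in dist.values() if math.isfinite(d)]
        if finite:
            best = max(best, max(finite))
    return best


def density(network: DiseaseNetwork) -> float:
    """Realized over potential edges: ``2E / (n(n-1))``."""
    n = network.n_nodes
    if n < 2:
        raise ValueError("density undefined for fewer than 2 nodes")
    return 2.0 * network.n_edges / (n * (n - 1))


@dataclass(frozen=True)
class NodeCentrality:
    disease: str
    degree: int
    closeness: float
    betweenness: float


@dataclass(frozen=True)
class NetworkAttributes:
    n_nodes: int
    n_edges: int
    diameter: float
    density: float
    distance_transform: str


def centrality_table(network: DiseaseNetwork) -> pd.DataFrame:
    """Per-node degree/closeness/betweenness, raw and x100 ("in %").

    Rows in codebook order; columns ``disease, prevalence, degree,
    closeness_raw, closeness_pct, betweenness_raw, betweenness_pct``.
    """
    bc = betweenness(network, node=None, normalized=True)
    rows = []
    for v in network.nodes:
        cl = closeness(network, v)
        rows.append({
            "disease": v,
            "prevalence": network.node_prevalence.get(v, np.nan),
            "degree": degree(network, v),
            "closeness_raw": cl,
            "closeness_pct": 100.0 * cl,
            "betweenness_raw": bc[v],
            "betweenness_pct": 100.0 * bc[v],
        })
    return pd.DataFrame(rows)


def network_attributes(network: DiseaseNetwork) -> NetworkAttributes:
    """Network-level attribute block: nodes, edges, diameter, density."""
    return NetworkAttributes(
        n_nodes=network.n_nodes,
        n_edges=network.n_edges,
        diameter=diameter(network),
        density=density(network),
        distance_transform=network.distance_transform,
    )


def write_graphml(network: DiseaseNetwork, path) -> None:
    """Export the network as GraphML (node attr = prevalence, edge attr
    = odds ratio)."""
    ns = "http://graphml.graphdrawing.org/xmlns"
    ET.register_namespace("", ns)
    root = ET.Element(f"{{{ns}}}graphml")
    for key_id, attr, dom in (("prevalence", "prevalence", "node"),
                              ("weight", "odds_ratio", "edge")):
        key = ET.SubElement(root, f"{{{ns}}}key", id=key_id)
        key.set("for", dom)
        key.set("attr.name", attr)
        key.set("attr.type", "double")
    graph = ET.SubElement(root, f"{{{ns}}}graph", id="disease_network",
                          edgedefault="undirected")
    for v in network.nodes:
        node = ET.SubElement(graph, f"{{{ns}}}node", id=v)
        if v in network.node_prevalence:
            data = ET.SubElement(node, f"{{{ns}}}data", key="prevalence")
            data.text = repr(float(network.node_prevalence[v]))
    for i, (pair, w) in enumerate(sorted(network.edges.items(),
                                         key=lambda kv: sorted(kv[0]))):
        a, b = sorted(pair)
        edge = ET.SubElement(graph, f"{{{ns}}}edge", id=f"e{i}", source=a, target=b)
        data = ET.SubElement(edge, f"{{{ns}}}data", key="weight")
        data.text = repr(float(w))
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="unicode")
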