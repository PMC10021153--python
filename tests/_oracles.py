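"""Independent brute-force oracles for the graph metrics.

Everything here works by exhaustive enumeration of simple paths, with
no shared code with :mod:`morbnet.graph`, so the package's Dijkstra /
Brandes implementations can be checked against it on small graphs.
"""

from __future__ import annotations

import itertools
import math

TIE_TOL = 1e-12


def enumerate_simple_paths(adj: dict, s, t):
    """Yield (path, length) for every simple s-t path (exhaustive DFS)."""
    def dfs(node, visited, length, path):
        if node == t:
            yield list(path), length
            return
        for nxt, w in adj[node].items():
            if nxt not in visited:
                visited.add(nxt)
                path.append(nxt)
                yield from dfs(nxt, visited, length + w, path)
                path.pop()
                visited.remove(nxt)
    yield from dfs(s, {s}, 0.0, [s])


def brute_force_metrics(nodes, dist_edges: dict) -> dict:
    """All-pairs geodesics by exhaustive enumeration.

    ``dist_edges`` maps ``frozenset({a, b})`` to the edge *distance*
    (already transformed).  Returns distances, raw and normalized
    betweenness, component-corrected closeness, and diameter.
    """
    nodes = list(nodes)
    adj = {v: {} for v in nodes}
    for pair, d in dist_edges.items():
        a, b = tuple(pair)
        adj[a][b] = d
        adj[b][a] = d

    dist = {(s, t): math.inf for s in nodes for t in nodes}
    for v in nodes:
        dist[(v, v)] = 0.0
    bet_raw = {v: 0.0 for v in nodes}

    for s, t in itertools.combinations(nodes, 2):
        paths = list(enumerate_simple_paths(adj, s, t))
        if not paths:
            continue
        best = min(length for _, length in paths)
        dist[(s, t)] = dist[(t, s)] = best
        geodesics = [p for p, length in paths if length <= best + TIE_TOL]
        sigma = len(geodesics)
        for path in geodesics:
            for v in path[1:-1]:
                bet_raw[v] += 1.0 / sigma

    n = len(nodes)
    scale = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 0.0
    bet_norm = {v: b * scale for v, b in bet_raw.items()}

    closeness = {}
    for v in nodes:
        reach = [dist[(v, u)] for u in nodes if u != v and math.isfinite(dist[(v, u)])]
        if not reach:
            closeness[v] = 0.0
        else:
            r1 = len(reach)
            closeness[v] = (r1 / sum(reach)) * (r1 / (n - 1))

    finite = [d for d in dist.values() if math.isfinite(d)]
    diameter = max(finite) if finite else 0.0
    return {"dist": dist, "betweenness_raw": bet_raw,
            "betweenness": bet_norm, "closeness": closeness,
            "diameter": diameter}


def random_graph(rng, n_nodes=8, p_edge=0.45, w_lo=1.2, w_hi=5.0):
    """Random weighted graph: OR-style weights, node names N0..N{n-1}."""
    nodes = tuple(f"N{i}" for i in range(n_nodes))
    edges = {}
    for a, b in itertools.combinations(nodes, 2):
        if rng.random() < p_edge:
            edges[frozenset((a, b))] = float(rng.uniform(w_lo, w_hi))
    return nodes, edges
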