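"""Independent brute-force oracles for the network measures.

Everything here is deliberately naive — exhaustive path enumeration,
O(n^3) triple counting, direct textbook formulas — and shares no code with
the implementation it checks.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np

from trustnet.layers import TrustLayer


def random_layer(
    rng: np.random.Generator,
    n: int = 8,
    p: float = 0.3,
    weights=(0.5, 1.0),
    weight_cap: float = 1.0,
    label: str = "random",
) -> TrustLayer:
    """Erdos-Renyi-style random weighted digraph on string node ids."""
    ids = [f"n{i}" for i in range(n)]
    g = nx.DiGraph()
    g.add_nodes_from(ids)
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                w = float(weights[int(rng.integers(len(weights)))])
                g.add_edge(ids[i], ids[j], weight=w)
    return TrustLayer(label=label, graph=g, weight_cap=weight_cap)


def _all_paths(succ: dict, s, t, visited: set) -> list[list]:
    """Every simple directed path s -> t, by plain DFS."""
    if s == t:
        return [[t]]
    paths = []
    for v in succ[s]:
        if v not in visited:
            for rest in _all_paths(succ, v, t, visited | {v}):
                paths.append([s] + rest)
    return paths


def betweenness_enumeration(layer: TrustLayer) -> dict:
    """Unnormalized betweenness by enumerating *all* simple paths for every
    ordered pair and keeping the shortest ones."""
    g = layer.graph
    nodes = list(g.nodes)
    succ = {v: list(g.successors(v)) for v in nodes}
    bc = dict.fromkeys(nodes, 0.0)
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            paths = _all_paths(succ, s, t, {s})
            if not paths:
                continue
            d = min(len(p) for p in paths)
            geodesics = [p for p in paths if len(p) == d]
            for p in geodesics:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(geodesics)
    return bc


def clustering_triples(layer: TrustLayer) -> float:
    """Mean local clustering on the undirected projection by explicit
    neighbor-pair checking."""
    g = layer.graph
    nodes = list(g.nodes)
    und = {v: set() for v in nodes}
    for u, v in g.edges():
        und[u].add(v)
        und[v].add(u)
    total = 0.0
    for v in nodes:
        nv = sorted(und[v])
        k = len(nv)
        if k < 2:
            continue
        closed = 0
        pairs = 0
        for i in range(k):
            for j in range(i + 1, k):
                pairs += 1
                if nv[j] in und[nv[i]]:
                    closed += 1
        total += closed / pairs
    return total / len(nodes)


def assortativity_formula(layer: TrustLayer) -> float | None:
    """Weighted Pearson of endpoint weighted in-degrees, straight from the
    definition with numpy weighted moments."""
    g = layer.graph
    if g.number_of_edges() < 2:
        return None
    s_in = {v: 0.0 for v in g.nodes}
    for _, v, w in g.edges(data="weight"):
        s_in[v] += w
    x, y, w = [], [], []
    for u, v, wt in g.edges(data="weight"):
        x.append(s_in[u])
        y.append(s_in[v])
        w.append(wt)
    x, y, w = np.asarray(x), np.asarray(y), np.asarray(w)
    mx, my = np.average(x, weights=w), np.average(y, weights=w)
    vx = np.average((x - mx) ** 2, weights=w)
    vy = np.average((y - my) ** 2, weights=w)
    if vx <= 1e-15 or vy <= 1e-15:
        return None
    cov = np.average((x - mx) * (y - my), weights=w)
    return float(cov / math.sqrt(vx * vy))


def reciprocity_lookup(layer: TrustLayer) -> float | None:
    edges = set(layer.graph.edges())
    if not edges:
        return None
    return sum((v, u) in edges for u, v in edges) / len(edges)


def centralization_formula(layer: TrustLayer) -> float:
    g = layer.graph
    n = g.number_of_nodes()
    s_in = {v: 0.0 for v in g.nodes}
    for _, v, w in g.edges(data="weight"):
        s_in[v] += w
    c_max = max(s_in.values())
    num = sum(c_max - c for c in s_in.values())
    return min(1.0, max(0.0, num / ((n - 1) ** 2 * layer.weight_cap)))
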