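"""Individual- and network-level measures for trust network layers.

Individual level: in-degree (how often a partner is trusted), weighted
in-degree (the summed strength of agreement received) and betweenness
centrality (how often a node sits on shortest directed paths between other
pairs — the "gatekeepers").

Network level: edge count, mean and population standard deviation of the
weighted in-degree over the full node universe (isolates included),
clustering coefficient, weighted assortativity, Freeman centralization
about the (weighted) in-degree, and reciprocity.

Conventions, chosen once and applied to every layer:

* Betweenness uses directed, *unweighted* geodesics with fractional
  shortest-path sharing (Brandes accumulation).  The layer weights encode
  agreement strength — a similarity, not a traversal cost — so they are not
  inverted into distances.
* The clustering coefficient is the mean local coefficient on the
  undirected, unweighted projection; nodes with projected degree < 2
  contribute 0.
* Weighted assortativity is the Pearson correlation, across directed
  edges and weighted by edge weight, between the source's and the target's
  weighted in-degree.
* Freeman centralization is normalized by the theoretical in-star maximum
  ``(n-1)^2 * w_cap`` where ``w_cap`` is the layer's maximum admissible
  edge weight; an optional observed-max normalization is available.
* A statistic that is undefined (zero variance, no edges) is returned as
  ``None``, never silently coerced to 0.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

from .layers import TrustLayer

_MEASURE_NAMES = (
    "n_edges",
    "w_in_mean",
    "w_in_std",
    "clustering",
    "assortativity",
    "centralization",
    "reciprocity",
)


@dataclass(frozen=True)
class MeasureTable:
    """The network-level statistic battery for one layer."""

    label: str
    n_nodes: int
    n_edges: int
    w_in_mean: float
    w_in_std: float
    clustering: float | None
    assortativity: float | None
    centralization: float | None
    reciprocity: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in _MEASURE_NAMES}

    @staticmethod
    def measure_names() -> tuple[str, ...]:
        return _MEASURE_NAMES


def in_degree(layer: TrustLayer, node) -> int:
    """Number of incoming nominations (edges received)."""
    if node not in layer.graph:
        raise KeyError(f"node {node!r} not in layer {layer.label!r}")
    return layer.graph.in_degree(node)


def weighted_in_degree(layer: TrustLayer, node) -> float:
    """Sum of incoming edge weights — the total strength of agreement a
    partner receives on this layer's question.  Zero for isolates."""
    if node not in layer.graph:
        raise KeyError(f"node {node!r} not in layer {layer.label!r}")
    return sum(w for _, _, w in layer.graph.in_edges(node, data="weight"))


def all_weighted_in_degrees(layer: TrustLayer) -> dict:
    s_in = {v: 0.0 for v in layer.graph.nodes}
    for _, v, w in layer.graph.edges(data="weight"):
        s_in[v] += w
    return s_in


def betweenness(layer: TrustLayer, normalized: bool = False) -> dict:
    """Betweenness centrality on directed, unweighted geodesics.

    For every ordered pair (s, t) with s -> t reachable, each intermediate
    node v receives the fraction of shortest s-t paths passing through v
    (Brandes' dependency accumulation).  With ``normalized`` the counts are
    divided by (n-1)(n-2), the number of ordered pairs a node can mediate.
    """
    g = layer.graph
    nodes = list(g.nodes)
    succ = {v: list(g.successors(v)) for v in nodes}
    bc = dict.fromkeys(nodes, 0.0)

    for s in nodes:
        # single-source shortest paths (BFS) with path counts
        dist = {s: 0}
        sigma = dict.fromkeys(nodes, 0.0)
        sigma[s] = 1.0
        preds: dict = {v: [] for v in nodes}
        order: list = []
        queue = deque([s])
        while queue:
            v = queue.popleft()
            order.append(v)
            for w in succ[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        # back-propagate dependencies
        delta = dict.fromkeys(order, 0.0)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]

    if normalized:
        n = len(nodes)
        scale = (n - 1) * (n - 2)
        if scale > 0:
            bc = {v: b / scale for v, b in bc.items()}
    return bc


def clustering_coefficient(layer: TrustLayer) -> float:
    """Mean local clustering coefficient on the undirected, unweighted
    projection ("clumpiness"); nodes with projected degree < 2 contribute 0."""
    g = layer.graph
    if g.number_of_nodes() == 0:
        raise ValueError("clustering coefficient undefined on an empty node set")
    neigh: dict[object, set] = {v: set() for v in g.nodes}
    for u, v in g.edges():
        if u != v:
            neigh[u].add(v)
            neigh[v].add(u)
    total = 0.0
    for v, nv in neigh.items():
        k = len(nv)
        if k < 2:
            continue
        links = 0
        for u in nv:
            links += len(neigh[u] & nv)
        total += links / (k * (k - 1))  # each triangle edge counted twice
    return total / g.number_of_nodes()


def weighted_assortativity(layer: TrustLayer) -> float | None:
    """Edge-weight-weighted Pearson correlation, over directed edges, of the
    source's weighted in-degree against the target's weighted in-degree.

    Positive when highly-trusted nodes tend to nominate other
    highly-trusted nodes; ``None`` when fewer than two edges exist or a
    marginal has zero variance.
    """
    g = layer.graph
    if g.number_of_edges() < 2:
        return None
    s_in = all_weighted_in_degrees(layer)
    sw = sx = sy = sxx = syy = sxy = 0.0
    for u, v, w in g.edges(data="weight"):
        x, y = s_in[u], s_in[v]
        sw += w
        sx += w * x
        sy += w * y
        sxx += w * x * x
        syy += w * y * y
        sxy += w * x * y
    mx, my = sx / sw, sy / sw
    vx = sxx / sw - mx * mx
    vy = syy / sw - my * my
    if vx <= 1e-15 or vy <= 1e-15:
        return None
    return (sxy / sw - mx * my) / math.sqrt(vx * vy)


def reciprocity(layer: TrustLayer) -> float | None:
    """Fraction of directed edges whose reverse edge also exists (presence
    only; weights ignored).  ``None`` for an edgeless layer."""
    g = layer.graph
    m = g.number_of_edges()
    if m == 0:
        return None
    mutual = sum(1 for u, v in g.edges() if g.has_edge(v, u))
    return mutual / m


def freeman_in_centralization(
    layer: TrustLayer,
    weighted: bool = True,
    normalization: str = "theoretical",
) -> float:
    """Freeman centralization about the (weighted) in-degree.

    ``sum_i (c_max - c_i) / D``: 1 when all trust focuses on a single node
    (a perfect in-star at the maximal edge weight), 0 when incoming trust is
    evenly spread.  ``D`` is the in-star maximum ``(n-1)^2 * w_cap`` under
    the default "theoretical" normalization, or ``(n-1) * c_max`` under
    "observed_max".  Result clamped to [0, 1].
    """
    g = layer.graph
    n = g.number_of_nodes()
    if n < 3:
        raise ValueError(f"centralization needs >= 3 nodes, layer has {n}")
    if weighted:
        c = all_weighted_in_degrees(layer)
        cap = layer.weight_cap
    else:
        c = {v: float(g.in_degree(v)) for v in g.nodes}
        cap = 1.0
    c_max = max(c.values())
    dispersion = sum(c_max - ci for ci in c.values())
    if normalization == "theoretical":
        denom = (n - 1) * (n - 1) * cap
    elif normalization == "observed_max":
        if c_max == 0:
            return 0.0
        denom = (n - 1) * c_max
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return min(1.0, max(0.0, dispersion / denom))


def measure_table(layer: TrustLayer) -> MeasureTable:
    """Assemble the full network-level battery for one layer.

    The weighted in-degree mean and standard deviation are taken over the
    complete node universe (isolates included); the standard deviation is
    the population form.  Undefined statistics stay ``None``.
    """
    g = layer.graph
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("cannot measure a layer with an empty node set")
    s_in = all_weighted_in_degrees(layer)
    vals = list(s_in.values())
    mean = sum(vals) / n
    std = math.sqrt(sum((v - mean) ** 2 for v in vals) / n)
    return MeasureTable(
        label=layer.label,
        n_nodes=n,
        n_edges=g.number_of_edges(),
        w_in_mean=mean,
        w_in_std=std,
        clustering=clustering_coefficient(layer),
        assortativity=weighted_assortativity(layer),
        centralization=freeman_in_centralization(layer) if n >= 3 else None,
        reciprocity=reciprocity(layer),
    )


def node_measure_frame(layer: TrustLayer):
    """Per-node in-degree, weighted in-degree and (unnormalized) betweenness
    as a pandas DataFrame indexed by node."""
    import pandas as pd

    s_in = all_weighted_in_degrees(layer)
    bc = betweenness(layer)
    nodes = list(layer.graph.nodes)
    return pd.DataFrame(
        {
            "in_degree": [layer.graph.in_degree(v) for v in nodes],
            "weighted_in_degree": [s_in[v] for v in nodes],
            "betweenness": [bc[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
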