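"""Construction of the trust, combined-trust and collaboration network layers.

Each survey question maps to one weighted directed graph over a shared node
universe.  For a trust dimension, agreement strength becomes edge weight:
"agree" adds an edge of weight 0.5 from the respondent to the named partner,
"strongly agree" an edge of weight 1.0, and the neutral or disagreeing
responses add no edge at all — absence of trust is not coded as distrust.
The combined-trust layer averages the seven per-dimension edge weights
(absent counted as zero) per dyad.  The collaboration layer carries the
ordinal collaboration intensity 1..5 as the weight; the lowest level,
"no interaction at all", yields no edge.

All layers built from the same records share one node set (the full
universe of roster members, respondents and nominees), so isolates are
retained and network-level statistics are comparable across layers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .survey import N_DIMENSIONS, Roster, SurveyRecord, node_universe

DIMENSION_LABELS = tuple(f"trust_{d}" for d in range(1, N_DIMENSIONS + 1))
COMBINED_LABEL = "combined"
COLLABORATION_LABEL = "collaboration"
ALL_LABELS = DIMENSION_LABELS + (COMBINED_LABEL, COLLABORATION_LABEL)

#: Likert rating -> coded response on the symmetric -1..+1 scale.
_LIKERT_CODE = {1: -1.0, 2: -0.5, 3: 0.0, 4: 0.5, 5: 1.0}
#: Likert rating -> trust edge weight (None = no edge).
_LIKERT_WEIGHT = {1: None, 2: None, 3: None, 4: 0.5, 5: 1.0}


@dataclass
class TrustLayer:
    """A weighted directed network for one survey question (or the combined
    layer), over the full shared node universe.

    ``weight_cap`` is the maximum weight a single edge can carry in this
    layer (1.0 for trust and combined, 5.0 for collaboration); it sets the
    normalization of Freeman centralization.
    """

    label: str
    graph: nx.DiGraph
    weight_cap: float = 1.0

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weights(self) -> list[float]:
        """Edge weights in edge-iteration order."""
        return [w for _, _, w in self.graph.edges(data="weight")]


def code_likert(rating: int) -> float:
    """Map a 5-point agreement rating to the symmetric -1..+1 coding
    (1 -> -1, 2 -> -0.5, 3 -> 0, 4 -> 0.5, 5 -> 1)."""
    try:
        return _LIKERT_CODE[rating]
    except KeyError:
        raise ValueError(f"Likert rating must be in 1..5, got {rating!r}") from None


def likert_to_edge_weight(rating: int) -> float | None:
    """Trust edge weight for a rating: agree -> 0.5, strongly agree -> 1.0,
    neutral/disagree/strongly disagree -> None (no edge)."""
    try:
        return _LIKERT_WEIGHT[rating]
    except KeyError:
        raise ValueError(f"Likert rating must be in 1..5, got {rating!r}") from None


def _empty_graph(universe: Iterable[str]) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(sorted(universe))
    return g


def _resolve_universe(
    records: Sequence[SurveyRecord], universe: Iterable[str] | None
) -> frozenset[str]:
    if universe is None:
        return node_universe(None, records)
    universe = frozenset(universe)
    needed = node_universe(None, records)
    if not needed <= universe:
        raise ValueError(
            f"universe is missing surveyed node(s): {sorted(needed - universe)}"
        )
    return universe


def build_dimension_layer(
    records: Sequence[SurveyRecord],
    dim: int,
    universe: Iterable[str] | None = None,
) -> TrustLayer:
    """Build the directed network for one trust dimension (1..7)."""
    if dim not in range(1, N_DIMENSIONS + 1):
        raise ValueError(f"trust dimension must be in 1..{N_DIMENSIONS}, got {dim}")
    g = _empty_graph(_resolve_universe(records, universe))
    for rec in records:
        for alter, ratings in zip(rec.alters, rec.trust):
            w = likert_to_edge_weight(ratings[dim - 1])
            if w is not None:
                g.add_edge(rec.respondent_id, alter, weight=w)
    return TrustLayer(label=f"trust_{dim}", graph=g, weight_cap=1.0)


def build_combined_layer(
    records: Sequence[SurveyRecord],
    universe: Iterable[str] | None = None,
) -> TrustLayer:
    """Build the combined-trust network: per dyad, the mean over the seven
    dimensions of the per-dimension edge weight with absent edges counted as
    zero.  A dyad appears iff at least one dimension produced an edge, so the
    combined edge set is the union of the seven dimension edge sets and every
    weight is a positive multiple of 1/14."""
    g = _empty_graph(_resolve_universe(records, universe))
    for rec in records:
        for alter, ratings in zip(rec.alters, rec.trust):
            total = sum(likert_to_edge_weight(r) or 0.0 for r in ratings)
            if total > 0:
                g.add_edge(rec.respondent_id, alter, weight=total / N_DIMENSIONS)
    return TrustLayer(label=COMBINED_LABEL, graph=g, weight_cap=1.0)


def build_collaboration_layer(
    records: Sequence[SurveyRecord],
    universe: Iterable[str] | None = None,
) -> TrustLayer:
    """Build the collaboration network: ordinal intensity 1..5 becomes the
    edge weight; level 0 ("no interaction at all") adds no edge."""
    g = _empty_graph(_resolve_universe(records, universe))
    for rec in records:
        for alter, collab in zip(rec.alters, rec.collaboration):
            if collab not in range(0, 6):
                raise ValueError(
                    f"collaboration rating must be in 0..5, got {collab!r}"
                )
            if collab > 0:
                g.add_edge(rec.respondent_id, alter, weight=float(collab))
    return TrustLayer(label=COLLABORATION_LABEL, graph=g, weight_cap=5.0)


def build_all_layers(
    records: Sequence[SurveyRecord],
    roster: Roster | None = None,
    universe: Iterable[str] | None = None,
) -> dict[str, TrustLayer]:
    """All nine layers (seven trust dimensions, combined, collaboration)
    over one shared node universe."""
    if universe is None:
        universe = node_universe(roster, records)
    layers = {
        f"trust_{d}": build_dimension_layer(records, d, universe)
        for d in range(1, N_DIMENSIONS + 1)
    }
    layers[COMBINED_LABEL] = build_combined_layer(records, universe)
    layers[COLLABORATION_LABEL] = build_collaboration_layer(records, universe)
    return layers


def write_edgelist(layer: TrustLayer, path: str | Path) -> Path:
    """Write ``source,target,weight`` CSV rows (full float precision)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("source,target,weight\n")
        for u, v, w in sorted(layer.graph.edges(data="weight")):
            fh.write(f"{u},{v},{w!r}\n")
    return path


def read_edgelist(
    path: str | Path,
    label: str = "unnamed",
    universe: Iterable[str] | None = None,
    weight_cap: float = 1.0,
) -> TrustLayer:
    """Read an edge-list CSV written by :func:`write_edgelist`.

    Isolates are only recovered if `universe` is given (an edge list cannot
    represent them); edge sets and weights round-trip exactly.
    """
    path = Path(path)
    g = nx.DiGraph()
    if universe is not None:
        g.add_nodes_from(sorted(universe))
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().strip()
        if header != "source,target,weight":
            raise ValueError(f"{path.name}: unexpected edge-list header {header!r}")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            u, v, w = line.split(",")
            g.add_edge(u, v, weight=float(w))
    return TrustLayer(label=label, graph=g, weight_cap=weight_cap)


def write_graphml(layer: TrustLayer, path: str | Path) -> Path:
    """GraphML export (preserves isolates) for interoperability with
    standard graph tools."""
    path = Path(path)
    nx.write_graphml(layer.graph, path)
    return path
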