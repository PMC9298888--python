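"""Individual- and network-level measures against independent oracles."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trustnet import (
    TrustLayer,
    betweenness,
    build_dimension_layer,
    clustering_coefficient,
    freeman_in_centralization,
    measure_table,
    node_measure_frame,
    reciprocity,
    weighted_assortativity,
    weighted_in_degree,
)
from oracles import (
    assortativity_formula,
    betweenness_enumeration,
    centralization_formula,
    clustering_triples,
    random_layer,
    reciprocity_lookup,
)


def layer_from_edges(edges, nodes=(), cap=1.0, label="toy"):
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return TrustLayer(label=label, graph=g, weight_cap=cap)


def in_star(n=6, w=1.0):
    return layer_from_edges([(f"s{i}", "hub", w) for i in range(1, n)])


def ring(n=6, w=1.0):
    return layer_from_edges(
        [(f"v{i}", f"v{(i + 1) % n}", w) for i in range(n)]
    )


class TestWeightedInDegree:
    def test_two_edge_sum(self):
        layer = layer_from_edges([("A", "B", 0.5), ("C", "B", 1.0)])
        assert weighted_in_degree(layer, "B") == 1.5
        assert weighted_in_degree(layer, "A") == 0.0

    def test_isolate_is_zero(self):
        layer = layer_from_edges([("A", "B", 1.0)], nodes=["Z"])
        assert weighted_in_degree(layer, "Z") == 0.0

    def test_unknown_node_raises(self):
        with pytest.raises(KeyError):
            weighted_in_degree(layer_from_edges([("A", "B", 1.0)]), "Q")

    def test_conservation(self, rng):
        """Sum of in-degrees equals E; sum of weighted in-degrees equals
        the total edge weight."""
        layer = random_layer(rng, n=12, p=0.25)
        s = sum(weighted_in_degree(layer, v) for v in layer.nodes)
        assert s == pytest.approx(sum(layer.weights()))
        assert (
            sum(layer.graph.in_degree(v) for v in layer.nodes) == layer.n_edges
        )


class TestBetweenness:
    def test_directed_path_midpoint(self):
        layer = layer_from_edges([("A", "B", 1.0), ("B", "C", 1.0)])
        assert betweenness(layer) == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_in_star_has_no_through_paths(self):
        assert set(betweenness(in_star()).values()) == {0.0}

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            layer = random_layer(rng, n=8, p=0.3)
            got = betweenness(layer)
            want = betweenness_enumeration(layer)
            for v in layer.nodes:
                assert got[v] == pytest.approx(want[v], abs=1e-10)

    def test_matches_networkx(self, rng):
        layer = random_layer(rng, n=15, p=0.2)
        want = nx.betweenness_centrality(layer.graph, normalized=False)
        got = betweenness(layer)
        for v in layer.nodes:
            assert got[v] == pytest.approx(want[v], abs=1e-9)


@given(st.integers(2, 8), st.sets(st.tuples(st.integers(0, 7), st.integers(0, 7))))
@settings(max_examples=120, deadline=None, derandomize=True)
def test_betweenness_enumeration_property(n, raw_edges):
    """On every small digraph, Brandes-style counting agrees with exhaustive
    shortest-path enumeration."""
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    g.add_edges_from(
        (u % n, v % n, {"weight": 1.0}) for u, v in raw_edges if u % n != v % n
    )
    layer = TrustLayer("hyp", g)
    got = betweenness(layer)
    want = betweenness_enumeration(layer)
    for v in g.nodes:
        assert got[v] == pytest.approx(want[v], abs=1e-10)


class TestClustering:
    def test_mutual_triangle_is_one(self):
        edges = [
            (u, v, 1.0)
            for u in "ABC"
            for v in "ABC"
            if u != v
        ]
        assert clustering_coefficient(layer_from_edges(edges)) == 1.0

    def test_path_is_zero(self):
        layer = layer_from_edges([("A", "B", 1.0), ("B", "C", 1.0)])
        assert clustering_coefficient(layer) == 0.0

    def test_empty_node_set_raises(self):
        with pytest.raises(ValueError):
            clustering_coefficient(TrustLayer("e", nx.DiGraph()))

    def test_triangle_free_projection_is_zero(self):
        bipartite = layer_from_edges(
            [(f"a{i}", f"b{j}", 1.0) for i in range(3) for j in range(3)]
        )
        assert clustering_coefficient(bipartite) == 0.0

    def test_matches_triple_enumeration(self, rng):
        for _ in range(10):
            layer = random_layer(rng, n=10, p=0.3)
            assert clustering_coefficient(layer) == pytest.approx(
                clustering_triples(layer), abs=1e-12
            )

    def test_matches_networkx_projection(self, rng):
        layer = random_layer(rng, n=12, p=0.3)
        und = nx.Graph(layer.graph.to_undirected())
        want = sum(nx.clustering(und).values()) / und.number_of_nodes()
        assert clustering_coefficient(layer) == pytest.approx(want, abs=1e-12)


class TestAssortativity:
    def test_in_star_undefined(self):
        assert weighted_assortativity(in_star()) is None

    def test_single_edge_undefined(self):
        assert weighted_assortativity(layer_from_edges([("A", "B", 1.0)])) is None

    def test_four_edge_hand_value(self):
        # s_in: A=0.5, B=1.5, C=0, D=1; edge samples (x=s_in[src], y=s_in[tgt])
        layer = layer_from_edges(
            [("A", "B", 1.0), ("C", "B", 0.5), ("B", "D", 1.0), ("D", "A", 0.5)]
        )
        x = np.array([0.5, 0.0, 1.5, 1.0])
        y = np.array([1.5, 1.5, 1.0, 0.5])
        w = np.array([1.0, 0.5, 1.0, 0.5])
        mx, my = np.average(x, weights=w), np.average(y, weights=w)
        hand = np.average((x - mx) * (y - my), weights=w) / math.sqrt(
            np.average((x - mx) ** 2, weights=w)
            * np.average((y - my) ** 2, weights=w)
        )
        assert weighted_assortativity(layer) == pytest.approx(hand, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        for _ in range(10):
            layer = random_layer(rng, n=15, p=0.25)
            want = assortativity_formula(layer)
            got = weighted_assortativity(layer)
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want, abs=1e-10)
                assert -1.0 - 1e-12 <= got <= 1.0 + 1e-12


class TestReciprocity:
    def test_mutual_dyad_is_one(self):
        layer = layer_from_edges([("A", "B", 1.0), ("B", "A", 0.5)])
        assert reciprocity(layer) == 1.0

    def test_one_way_edge_is_zero(self):
        assert reciprocity(layer_from_edges([("A", "B", 1.0)])) == 0.0

    def test_edgeless_undefined(self):
        assert reciprocity(layer_from_edges([], nodes="AB")) is None

    def test_matches_set_lookup_and_ignores_weights(self, rng):
        layer = random_layer(rng, n=12, p=0.3)
        want = reciprocity_lookup(layer)
        assert reciprocity(layer) == pytest.approx(want)
        rescaled = layer_from_edges(
            [(u, v, w * 3.7) for u, v, w in layer.graph.edges(data="weight")],
            nodes=layer.nodes,
            cap=layer.weight_cap * 3.7,
        )
        assert reciprocity(rescaled) == pytest.approx(want)


class TestCentralization:
    def test_in_star_is_one(self):
        for n in (3, 6, 10):
            assert freeman_in_centralization(in_star(n)) == pytest.approx(1.0)

    def test_ring_is_zero(self):
        assert freeman_in_centralization(ring()) == 0.0

    def test_too_few_nodes_raises(self):
        with pytest.raises(ValueError):
            freeman_in_centralization(layer_from_edges([("A", "B", 1.0)]))

    def test_weight_cap_normalizes_collaboration_scale(self):
        # a collaboration in-star at maximal weight 5 is maximally central
        layer = layer_from_edges(
            [(f"s{i}", "hub", 5.0) for i in range(1, 6)], cap=5.0
        )
        assert freeman_in_centralization(layer) == pytest.approx(1.0)

    def test_matches_formula(self, rng):
        for _ in range(10):
            layer = random_layer(rng, n=15, p=0.2)
            assert freeman_in_centralization(layer) == pytest.approx(
                centralization_formula(layer), abs=1e-12
            )

    def test_monotone_when_feeding_the_hub(self, rng):
        """Adding an incoming edge to the current maximum never lowers
        centralization."""
        layer = random_layer(rng, n=10, p=0.25)
        s_in = {
            v: sum(w for _, _, w in layer.graph.in_edges(v, data="weight"))
            for v in layer.nodes
        }
        hub = max(s_in, key=lambda v: (s_in[v], str(v)))
        before = freeman_in_centralization(layer)
        for u in layer.nodes:
            if u != hub and not layer.graph.has_edge(u, hub):
                layer.graph.add_edge(u, hub, weight=1.0)
                break
        assert freeman_in_centralization(layer) >= before - 1e-12


class TestMeasureTable:
    def test_mutual_dyad_in_five_node_universe(self):
        layer = layer_from_edges(
            [("A", "B", 1.0), ("B", "A", 1.0)], nodes=list("ABCDE")
        )
        t = measure_table(layer)
        assert t.n_edges == 2
        assert t.reciprocity == 1.0
        assert t.clustering == 0.0
        assert t.w_in_mean == pytest.approx(0.4)

    def test_empty_layer(self):
        t = measure_table(layer_from_edges([], nodes=list("ABC")))
        assert t.n_edges == 0
        assert t.w_in_mean == 0.0
        assert t.reciprocity is None
        assert t.assortativity is None

    def test_cells_equal_standalone_operations(self, fixtures):
        roster, records = fixtures["table_shape"]
        layer = build_dimension_layer(records, 5)
        t = measure_table(layer)
        assert t.clustering == clustering_coefficient(layer)
        assert t.assortativity == weighted_assortativity(layer)
        assert t.reciprocity == reciprocity(layer)
        assert t.centralization == freeman_in_centralization(layer)
        vals = [weighted_in_degree(layer, v) for v in layer.nodes]
        assert t.w_in_mean == pytest.approx(np.mean(vals))
        assert t.w_in_std == pytest.approx(np.std(vals))  # population form


def test_node_measure_frame_shape(fixtures):
    _, records = fixtures["in_star"]
    layer = build_dimension_layer(records, 1)
    df = node_measure_frame(layer)
    assert list(df.columns) == ["in_degree", "weighted_in_degree", "betweenness"]
    assert df.loc["H", "in_degree"] == 4
    assert df.loc["H", "weighted_in_degree"] == 4.0
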