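"""Topology and co-expression features against enumeration oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

import ppimcl as pm
from ppimcl import features as ft
from ppimcl.expression import NormalizedExpression


@pytest.fixture
def cycle4():
    return pm.ProteinGraph.from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])


@pytest.fixture
def star():
    return pm.ProteinGraph.from_edges([("hub", "l1"), ("hub", "l2"), ("hub", "l3")])


def _model_from_rows(rows: dict[str, list[float]]) -> pm.CoexpressionModel:
    N = NormalizedExpression(
        {p: np.asarray(v, dtype=float) for p, v in rows.items()},
        m=len(next(iter(rows.values()))) if rows else 0,
    )
    # e_avg=0 so any positive pairwise score counts as co-expressed
    return pm.CoexpressionModel(N=N, e_avg=0.0)


class TestConnect:
    def test_path_distance_two(self, path3):
        assert ft.connect(path3, "a", "c", 2) == 1
        assert ft.connect(path3, "a", "c", 1) == 0

    def test_self_is_never_connected(self, triangle):
        for n in (1, 2, 5):
            assert ft.connect(triangle, "a", "a", n) == 0

    def test_cycle_both_modes(self, cycle4):
        assert ft.connect(cycle4, "a", "c", 2, mode="at_most") == 1
        assert ft.connect(cycle4, "a", "c", 2, mode="exact") == 1
        assert ft.connect(cycle4, "a", "b", 2, mode="exact") == 0  # d=1

    def test_unknown_vertex_raises(self, triangle):
        with pytest.raises(KeyError):
            ft.connect(triangle, "a", "nope", 2)


class TestPathNum:
    def test_cycle_has_two_paths(self, cycle4):
        assert ft.path_num(cycle4, "a", "c", 2) == 2  # a-b-c and a-d-c

    def test_path_has_one(self, path3):
        assert ft.path_num(path3, "a", "c", 2) == 1

    def test_adjacent_pair_at_two_is_zero(self, triangle):
        assert ft.path_num(triangle, "a", "b", 2) == 0


class TestRatios:
    def test_adjacent_to_all_members(self, star):
        assert ft.connect_ratio(star, "hub", {"l1", "l2", "l3"}, 2) == 1.0

    def test_different_component_is_zero(self):
        g = pm.ProteinGraph.from_edges([("a", "b"), ("x", "y")])
        assert ft.connect_ratio(g, "a", {"x", "y"}, 3) == 0.0
        assert ft.path_ratio(g, "a", {"x", "y"}, 3) == 0.0

    def test_star_direct_paths(self, star):
        assert ft.path_ratio(star, "hub", {"l1", "l2", "l3"}, 1) == 1.0

    def test_member_contributes_zero_for_itself(self, triangle):
        # v ∈ C: the self term is 0 but |C| still divides
        assert ft.connect_ratio(triangle, "a", {"a", "b", "c"}, 2) == pytest.approx(2 / 3)

    def test_empty_complex_raises(self, triangle):
        with pytest.raises(ValueError):
            ft.connect_ratio(triangle, "a", set(), 2)


class TestDensity:
    def test_triangle(self, triangle):
        assert ft.density(triangle, {"a", "b", "c"}, 2) == pytest.approx(6 / 9)

    def test_disconnected_pair_is_zero(self):
        g = pm.ProteinGraph.from_edges([("a", "x"), ("b", "y")])
        g = pm.ProteinGraph()
        for v in "ab":
            g.add_vertex(v)
        assert ft.density(g, {"a", "b"}, 2) == 0.0

    def test_clique4(self):
        g = pm.ProteinGraph.from_edges(
            [(u, v) for u, v in itertools.combinations("abcd", 2)]
        )
        assert ft.density(g, set("abcd"), 2) == pytest.approx(12 / 16)

    def test_too_small_raises(self, triangle):
        with pytest.raises(ValueError):
            ft.density(triangle, {"a"}, 2)

    def test_monotone_in_n_under_at_most(self):
        g = pm.ProteinGraph.from_edges(
            [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")]
        )
        C = set("abcde")
        vals = [ft.density(g, C, n) for n in (1, 2, 3, 4)]
        assert vals == sorted(vals)


class TestDensityDiff:
    def test_triangle_plus_pendant(self, triangle):
        g = pm.ProteinGraph.from_edges(
            [("a", "b"), ("b", "c"), ("a", "c"), ("a", "d")]
        )
        got = ft.density_diff(g, "d", {"a", "b", "c"}, 2)
        assert got == pytest.approx(12 / 16 - 6 / 9)

    def test_isolated_vertex_decreases_density(self, triangle):
        triangle.add_vertex("iso")
        assert ft.density_diff(triangle, "iso", {"a", "b", "c"}, 2) < 0

    def test_adjacent_to_whole_clique_non_negative(self):
        g = pm.ProteinGraph.from_edges(
            [(u, v) for u, v in itertools.combinations("abcd", 2)]
        )
        assert ft.density_diff(g, "d", {"a", "b", "c"}, 2) >= 0

    def test_member_raises(self, triangle):
        with pytest.raises(ValueError):
            ft.density_diff(triangle, "a", {"a", "b"}, 2)


class TestCoexpressionAggregates:
    def test_eco_complex_ordered_pairs_over_squared_size(self):
        model = _model_from_rows({"a": [1, 0.5], "b": [0.5, 1]})
        pair = model.eco("a", "b")
        assert ft.eco_complex({"a", "b"}, model) == pytest.approx(2 * pair / 4)

    def test_all_missing_expression_scores_zero(self):
        model = _model_from_rows({"x": [1.0, 1.0]})
        assert ft.eco_complex({"a", "b"}, model) == 0.0

    def test_protein_vs_singleton_complex(self):
        model = _model_from_rows({"a": [1, 0.5], "b": [0.5, 1]})
        assert ft.eco_protein_complex("a", {"b"}, model) == pytest.approx(
            model.eco("a", "b")
        )

    def test_co_ratio_all_pairs_coexpressed(self):
        model = _model_from_rows(
            {"a": [1, 0.9], "b": [0.9, 1], "c": [1, 1]}
        )
        assert ft.co_ratio({"a", "b", "c"}, model) == pytest.approx(6 / 9)

    def test_co_pro_num_and_ratio(self):
        model = _model_from_rows(
            {"v": [1, 0.9], "m1": [1, 1], "m2": [0.9, 1]}
        )
        # m3/m4 have no expression rows -> Co = 0 against v
        C = {"m1", "m2", "m3", "m4"}
        assert ft.co_pro_num("v", C, model) == 2
        assert ft.co_pro_ratio("v", C, model) == pytest.approx(0.5)

    def test_co_diff_positive_when_newcomer_matches_everyone(self):
        # members are mutually dissimilar; v matches all of them decently
        rows = {
            "m1": [1.0, 0.05, 0.6],
            "m2": [0.05, 1.0, 0.6],
            "v": [0.6, 0.6, 0.6],
        }
        model = _model_from_rows(rows)
        assert ft.co_diff("v", {"m1", "m2"}, model) > 0


class TestFeatureVector:
    def test_isolated_vertex_forced_zeros(self, triangle):
        triangle.add_vertex("iso")
        model = _model_from_rows({})
        vec = ft.feature_vector(triangle, "iso", {"a", "b", "c"}, model)
        assert vec[0] == 0.0 and vec[1] == 0.0
        assert vec[2] <= 0.0  # DenDiff cannot be positive for an isolate
        assert vec[3] == 0.0 and vec[5] == 0.0 and vec[6] == 0.0

    def test_order_matches_component_functions(self, synthetic_dataset, synthetic_model):
        _, g, truth, _ = synthetic_dataset
        C = set(truth[0])
        v = next(u for u in g.vertices if u not in C)
        vec = ft.feature_vector(g, v, C, synthetic_model)
        assert vec[3] == pytest.approx(ft.eco_protein_complex(v, C, synthetic_model))
        assert vec[2] == pytest.approx(ft.density_diff(g, v, C, 2))
        assert vec.shape == (7,)

    def test_member_must_be_stripped_first(self, triangle):
        model = _model_from_rows({})
        with pytest.raises(ValueError):
            ft.feature_vector(triangle, "a", {"a", "b"}, model)

    def test_strongly_tied_protein_all_graph_features_positive(self, cycle4):
        # d is adjacent to a and c and two hops from b (two shortest paths)
        model = _model_from_rows({})
        vec = ft.feature_vector(cycle4, "d", {"a", "b", "c"}, model)
        assert vec[0] == 1.0 and vec[1] > 0 and vec[2] > 0


def _random_graph(rng, n_max=30, p=0.15):
    n = int(rng.integers(4, n_max + 1))
    g = pm.ProteinGraph()
    for i in range(n):
        g.add_vertex(f"v{i}")
    for a, b in itertools.combinations(range(n), 2):
        if rng.random() < p:
            g.add_edge(f"v{a}", f"v{b}")
    return g


def _oracle_counts(G, u, v, n):
    """Shortest-path length and count via networkx enumeration."""
    try:
        d = nx.shortest_path_length(G, u, v)
    except nx.NetworkXNoPath:
        return None, 0
    if d != n:
        return d, 0
    return d, sum(1 for _ in nx.all_shortest_paths(G, u, v))


@pytest.mark.parametrize("n", [2, 3])
def test_connect_and_path_num_match_bfs_enumeration_oracle(n):
    rng = np.random.default_rng(100 + n)
    for _ in range(25):
        g = _random_graph(rng)
        G = g.to_networkx()
        verts = g.vertices
        pairs = [
            (verts[int(rng.integers(len(verts)))], verts[int(rng.integers(len(verts)))])
            for _ in range(40)
        ]
        for u, v in pairs:
            if u == v:
                continue
            d, count = _oracle_counts(G, u, v, n)
            expected_connect = int(d is not None and 1 <= d <= n)
            assert ft.connect(g, u, v, n) == expected_connect
            assert ft.connect(g, u, v, n, mode="exact") == int(d == n)
            assert ft.path_num(g, u, v, n) == count


def test_density_matches_pairwise_oracle():
    rng = np.random.default_rng(200)
    for _ in range(15):
        g = _random_graph(rng, n_max=20)
        G = g.to_networkx()
        k = min(5, g.n_vertices)
        members = list(rng.choice(g.vertices, size=k, replace=False))
        C = set(members)
        lengths = dict(nx.all_pairs_shortest_path_length(G, cutoff=2))
        expected = sum(
            1
            for u in C
            for v in C
            if u != v and lengths.get(u, {}).get(v, 99) <= 2
        ) / len(C) ** 2
        assert ft.density(g, C, 2) == pytest.approx(expected)


def test_ratio_features_bounded(synthetic_dataset, synthetic_model):
    _, g, truth, _ = synthetic_dataset
    C = truth[2]
    for v in list(g.vertices)[:20]:
        if v in C:
            continue
        vec = ft.feature_vector(g, v, C, synthetic_model)
        assert 0.0 <= vec[0] <= 1.0  # ConnectRatio
        assert 0.0 <= vec[6] <= 1.0  # CoProRatio
        assert vec[5] <= len(C)  # CoProNum
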