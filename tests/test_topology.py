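import math

import numpy as np
import pytest

import oracles
from nettop.graph_io import Network
from nettop.topology import (
    FEATURE_ORDER,
    ModuleAssignment,
    barycenter,
    betweenness,
    closeness,
    clustering_coefficient,
    compute_all,
    coreness,
    degree,
    detect_modules,
    eigenvector_centrality,
    k_step_markov,
    katz_index,
    proximity_prestige,
    shortest_paths,
    structural_holes,
    subgraph_centrality,
    within_module_zscore,
)


def complete(n):
    verts = [f"v{i}" for i in range(n)]
    return Network.from_edges(
        [(verts[i], verts[j]) for i in range(n) for j in range(i)]
    )


def path(n):
    return Network.from_edges([(f"v{i}", f"v{i+1}") for i in range(n - 1)])


class TestClosedForms:
    def test_degree(self, p3, k4):
        assert degree(p3) == {"a": 1, "b": 2, "c": 1}
        assert all(v == 3 for v in degree(k4).values())
        net = Network()
        net.add_vertex("solo")
        assert degree(net) == {"solo": 0}

    def test_degree_sum_is_twice_edges(self, triangle_pendant):
        assert sum(degree(triangle_pendant).values()) == 2 * triangle_pendant.n_edges

    def test_coreness(self, triangle_pendant, k4):
        assert coreness(triangle_pendant) == {"a": 2, "b": 2, "c": 2, "d": 1}
        assert all(v == 3 for v in coreness(k4).values())
        assert all(v == 1 for v in coreness(path(4)).values())

    def test_clustering(self, triangle, p3):
        assert all(v == 1.0 for v in clustering_coefficient(triangle).values())
        assert clustering_coefficient(p3)["b"] == 0.0
        # K4 minus one edge: a degree-3 vertex keeps 2 of 3 neighbor edges
        net = Network.from_edges(
            [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("c", "d")]
        )
        assert clustering_coefficient(net)["a"] == pytest.approx(2 / 3)

    def test_shortest_path_summary(self, p3):
        sp = shortest_paths(p3)
        assert sp.distance("a", "c") == 2
        assert sp.n_paths("a", "c") == 1
        assert sp.through_count("a", "c", "b") == 1
        # 4-cycle: two geodesics between opposite corners
        c4 = Network.from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        assert shortest_paths(c4).n_paths("a", "c") == 2
        disc = Network.from_edges([("a", "b")], vertices=["a", "b", "z"])
        assert math.isinf(shortest_paths(disc).distance("a", "z"))

    def test_betweenness_ordered_pairs(self, p3, triangle, star3):
        assert betweenness(p3)["b"] == 2.0  # (a,c) and (c,a)
        assert all(v == 0.0 for v in betweenness(triangle).values())
        assert betweenness(star3)["c"] == 6.0  # 6 ordered leaf pairs
        assert betweenness(star3, normalized=True)["c"] == 3.0

    def test_closeness(self, p3, k4):
        assert closeness(p3)["b"] == 2.0
        assert all(v == 3.0 for v in closeness(k4).values())
        disc = Network.from_edges([("a", "b")], vertices=["a", "b", "z"])
        assert closeness(disc)["z"] == 0.0

    def test_proximity_prestige(self, p3, k4):
        assert all(v == 1.0 for v in proximity_prestige(k4).values())
        assert proximity_prestige(p3)["a"] == pytest.approx(2 / 3)
        disc = Network.from_edges([("a", "b")], vertices=["a", "b", "z"])
        assert proximity_prestige(disc)["z"] == 0.0

    def test_barycenter(self, p3, k4):
        assert barycenter(p3)["b"] == pytest.approx(1 / 2)
        assert all(v == pytest.approx(1 / 3) for v in barycenter(k4).values())
        disc = Network.from_edges([("a", "b")], vertices=["a", "b", "z"])
        assert barycenter(disc)["z"] == 0.0

    def test_eigenvector(self, star3):
        ev = eigenvector_centrality(star3)
        assert ev["c"] == pytest.approx(1 / math.sqrt(2), abs=1e-8)
        assert ev["l1"] == pytest.approx(1 / math.sqrt(6), abs=1e-8)
        evk = eigenvector_centrality(complete(5))
        assert all(v == pytest.approx(1 / math.sqrt(5), abs=1e-8) for v in evk.values())
        edgeless = Network()
        edgeless.add_vertex("a")
        with pytest.raises(ValueError):
            eigenvector_centrality(edgeless)

    def test_katz(self):
        k2 = Network.from_edges([("a", "b")])
        assert katz_index(k2, alpha=0.5) == pytest.approx({"a": 1.0, "b": 1.0})
        with pytest.raises(ValueError, match="diverges"):
            katz_index(k2, alpha=1.5)
        disc = Network.from_edges([("a", "b")], vertices=["a", "b", "z"])
        assert katz_index(disc, alpha=0.5)["z"] == 0.0

    def test_subgraph(self, triangle):
        k2 = Network.from_edges([("a", "b")])
        assert subgraph_centrality(k2)["a"] == pytest.approx(math.cosh(1), abs=1e-12)
        assert subgraph_centrality(triangle)["a"] == pytest.approx(
            (math.e**2 + 2 / math.e) / 3, abs=1e-12
        )
        solo = Network()
        solo.add_vertex("a")
        assert subgraph_centrality(solo)["a"] == 1.0

    def test_modules(self, triangle):
        two_tri = Network.from_edges(
            [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")]
        )
        assert detect_modules(two_tri, "components").n_modules == 2
        assert detect_modules(triangle, "components").n_modules == 1
        with pytest.raises(ValueError):
            detect_modules(triangle, "nonsense")

    def test_greedy_modules_split_two_cliques(self):
        edges = [(f"a{i}", f"a{j}") for i in range(5) for j in range(i)]
        edges += [(f"b{i}", f"b{j}") for i in range(5) for j in range(i)]
        edges += [("a0", "b0")]
        mods = detect_modules(Network.from_edges(edges))
        assert mods.n_modules == 2
        assert len({mods.module_of[f"a{i}"] for i in range(5)}) == 1
        assert mods.module_of["a0"] != mods.module_of["b0"]

    def test_within_module_z(self, star3, triangle):
        one = ModuleAssignment({v: 0 for v in star3.vertices})
        z = within_module_zscore(star3, one)
        assert z["c"] == pytest.approx(1.5 / math.sqrt(0.75))  # ~1.732
        # constant within-degrees -> all zero
        zt = within_module_zscore(triangle, ModuleAssignment({v: 0 for v in triangle.vertices}))
        assert all(v == 0.0 for v in zt.values())
        with pytest.raises(ValueError):
            within_module_zscore(star3, ModuleAssignment({"c": 0}))

    def test_k_step_markov(self, star3):
        k2 = Network.from_edges([("a", "b")])
        for k in (0, 1, 5):
            assert k_step_markov(k2, k) == pytest.approx({"a": 0.5, "b": 0.5})
        res = k_step_markov(star3, 6)
        assert all(v == pytest.approx(0.25) for v in res.values())
        with pytest.raises(ValueError):
            k_step_markov(star3, -1)

    def test_structural_holes(self, triangle, star3):
        k2 = Network.from_edges([("a", "b")])
        assert structural_holes(k2)["a"] == pytest.approx(1.0)
        assert structural_holes(star3)["c"] == pytest.approx(1 / 3)
        assert structural_holes(triangle)["a"] == pytest.approx(1.125)
        solo = Network.from_edges([("a", "b")], vertices=["a", "b", "z"])
        assert structural_holes(solo)["z"] == 0.0


class TestOracleSweep:
    """Spot-check all measures against naive oracles on random small graphs
    (the exhaustive 50-seed sweep runs in the acceptance suite)."""

    @pytest.mark.parametrize("seed", range(8))
    def test_random_graph_matches_oracles(self, seed):
        net = oracles.random_connected_net(seed)
        g = oracles.to_nx(net)
        order = net.vertices
        assert betweenness(net) == pytest.approx(oracles.bf_betweenness(g), abs=1e-9)
        assert closeness(net) == pytest.approx(oracles.bf_closeness(g), abs=1e-9)
        assert coreness(net) == oracles.bf_coreness(g)
        assert structural_holes(net) == pytest.approx(oracles.bf_constraint(g), abs=1e-9)
        np.testing.assert_allclose(
            [subgraph_centrality(net)[v] for v in order],
            oracles.bf_subgraph_series(g, order),
            atol=1e-9,
        )
        alpha = 0.3 / max(np.linalg.eigvalsh(net.adjacency_matrix()))
        np.testing.assert_allclose(
            [katz_index(net, alpha=alpha)[v] for v in order],
            oracles.bf_katz(g, order, alpha),
            atol=1e-10,
        )
        np.testing.assert_allclose(
            [eigenvector_centrality(net, tol=1e-10)[v] for v in order],
            oracles.bf_eigenvector(g, order),
            atol=1e-8,
        )


class TestProperties:
    def test_relabeling_equivariance(self):
        net = oracles.random_connected_net(42)
        mapping = {v: f"X{v}" for v in net.vertices}
        relabeled = Network.from_edges(
            [(mapping[u], mapping[v]) for u, v, _ in net.edges()],
            vertices=[mapping[v] for v in net.vertices],
        )
        t1 = compute_all(net)
        t2 = compute_all(relabeled)
        np.testing.assert_allclose(t1.to_numpy(), t2.to_numpy(), atol=1e-8)

    def test_markov_probability_vector(self):
        for seed in range(5):
            net = oracles.random_connected_net(seed + 100)
            for k in (0, 1, 3, 7):
                vals = np.array(list(k_step_markov(net, k).values()))
                assert vals.min() >= 0
                assert vals.sum() == pytest.approx(1.0, abs=1e-12)

    def test_edge_addition_monotone(self):
        rng = np.random.default_rng(7)
        for seed in range(5):
            net = oracles.random_connected_net(seed + 200)
            verts = net.vertices
            pairs = [
                (u, v)
                for i, u in enumerate(verts)
                for v in verts[i + 1 :]
                if v not in net.neighbors(u)
            ]
            if not pairs:
                continue
            u, v = pairs[rng.integers(len(pairs))]
            before_deg, before_core = degree(net), coreness(net)
            bigger = Network.from_edges(
                list(net.edges()) + [(u, v, 1.0)], vertices=verts
            )
            after_deg, after_core = degree(bigger), coreness(bigger)
            for w in (u, v):
                assert after_deg[w] >= before_deg[w]
                assert after_core[w] >= before_core[w]

    def test_compute_all_shape_and_order(self, p3, k4):
        table = compute_all(p3)
        assert tuple(table.columns) == FEATURE_ORDER
        assert list(table["degree"]) == [1, 2, 1]
        assert np.isfinite(table.to_numpy()).all()
        assert (compute_all(k4)["betweenness"] == 0).all()

    def test_compute_all_deterministic(self):
        net = oracles.random_connected_net(11)
        t1, t2 = compute_all(net), compute_all(net)
        assert t1.equals(t2)
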