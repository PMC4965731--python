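"""Independent brute-force / closed-form oracles for the topological
measures, used only by the test suite.

Each oracle is deliberately naive (path enumeration, truncated series,
dense linear algebra, literal peeling) and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from nettop.graph_io import Network


def to_nx(net: Network) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(net.vertices)
    g.add_weighted_edges_from(net.edges())
    return g


def from_nx(g: nx.Graph) -> Network:
    return Network.from_edges(
        [(str(u), str(v)) for u, v in g.edges()], vertices=[str(v) for v in g.nodes()]
    )


def random_connected_net(seed: int, max_n: int = 8) -> Network:
    """Seeded random connected graph with up to max_n vertices."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, max_n + 1))
    p = float(rng.uniform(0.25, 0.8))
    for attempt in range(1000):
        g = nx.gnp_random_graph(n, p, seed=seed * 1000 + attempt)
        if nx.is_connected(g):
            return from_nx(g)
    raise RuntimeError("failed to sample a connected graph")


def bf_betweenness(g: nx.Graph) -> dict[str, float]:
    """Exhaustive geodesic enumeration, ordered-pair convention."""
    out = {}
    nodes = list(g.nodes())
    for v in nodes:
        total = 0.0
        for s in nodes:
            if s == v:
                continue
            for t in nodes:
                if t == s or t == v:
                    continue
                if not nx.has_path(g, s, t):
                    continue
                paths = list(nx.all_shortest_paths(g, s, t))
                through = sum(1 for p in paths if v in p[1:-1])
                total += through / len(paths)
        out[v] = total
    return out


def bf_closeness(g: nx.Graph) -> dict[str, float]:
    out = {}
    for v in g.nodes():
        dists = nx.single_source_shortest_path_length(g, v)
        out[v] = sum(1.0 / d for u, d in dists.items() if u != v)
    return out


def bf_coreness(g: nx.Graph) -> dict[str, int]:
    """Literal peeling: for each k remove degree<k vertices to a fixpoint;
    coreness = largest k the vertex survives."""
    out = {v: 0 for v in g.nodes()}
    max_deg = max((d for _, d in g.degree()), default=0)
    for k in range(max_deg + 1):
        h = g.copy()
        while True:
            drop = [v for v, d in h.degree() if d < k]
            if not drop:
                break
            h.remove_nodes_from(drop)
        for v in h.nodes():
            out[v] = k
    return out


def bf_proximity_prestige(g: nx.Graph) -> dict[str, float]:
    n = g.number_of_nodes()
    out = {}
    for v in g.nodes():
        dists = {u: d for u, d in nx.single_source_shortest_path_length(g, v).items() if u != v}
        i_v = len(dists)
        if i_v == 0 or n <= 1:
            out[v] = 0.0
        else:
            out[v] = (i_v / (n - 1)) / (sum(dists.values()) / i_v)
    return out


def bf_barycenter(g: nx.Graph) -> dict[str, float]:
    out = {}
    for v in g.nodes():
        total = sum(
            d for u, d in nx.single_source_shortest_path_length(g, v).items() if u != v
        )
        out[v] = 1.0 / total if total > 0 else 0.0
    return out


def bf_subgraph_series(g: nx.Graph, order: list[str], k_max: int = 30) -> np.ndarray:
    """Truncated series sum_{k<=k_max} (A^k)_vv / k!."""
    a = nx.to_numpy_array(g, nodelist=order, weight=None)
    n = len(order)
    term = np.eye(n)
    total = np.eye(n)
    fact = 1.0
    for k in range(1, k_max + 1):
        term = term @ a
        fact *= k
        total += term / fact
    return np.diag(total)


def bf_katz(g: nx.Graph, order: list[str], alpha: float) -> np.ndarray:
    """Explicit dense inverse ((I - alpha A^T)^-1 - I) 1."""
    a = nx.to_numpy_array(g, nodelist=order, weight=None)
    n = len(order)
    inv = np.linalg.inv(np.eye(n) - alpha * a.T)
    return (inv - np.eye(n)) @ np.ones(n)


def bf_eigenvector(g: nx.Graph, order: list[str]) -> np.ndarray:
    """Leading eigenvector by dense eigendecomposition, nonnegative, unit norm."""
    a = nx.to_numpy_array(g, nodelist=order, weight=None)
    lam, u = np.linalg.eigh(a)
    vec = np.abs(u[:, -1])
    return vec / np.linalg.norm(vec)


def bf_constraint(g: nx.Graph) -> dict[str, float]:
    """Burt aggregate constraint by direct triple loops (unit weights)."""
    out = {}
    for i in g.nodes():
        nbrs = list(g.neighbors(i))
        if not nbrs:
            out[i] = 0.0
            continue
        p = {q: 1.0 / len(nbrs) for q in nbrs}
        c = 0.0
        for j in nbrs:
            indirect = 0.0
            for q in nbrs:
                if q in (i, j):
                    continue
                q_nbrs = list(g.neighbors(q))
                if j in q_nbrs:
                    indirect += p[q] * (1.0 / len(q_nbrs))
            c += (p[j] + indirect) ** 2
        out[i] = c
    return out


def bf_within_module_z(g: nx.Graph, module_of: dict) -> dict[str, float]:
    k = {
        v: sum(1 for u in g.neighbors(v) if module_of[u] == module_of[v])
        for v in g.nodes()
    }
    out = {}
    modules = set(module_of.values())
    for m in modules:
        members = [v for v in g.nodes() if module_of[v] == m]
        ks = np.array([k[v] for v in members], dtype=float)
        sd = ks.std()
        for v in members:
            out[v] = float((k[v] - ks.mean()) / sd) if sd > 0 else 0.0
    return out
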