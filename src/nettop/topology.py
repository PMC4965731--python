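"""The thirteen per-vertex topological measures.

The feature vector groups into degree-based (degree, coreness, clustering
coefficient), shortest-path-based (betweenness, closeness, proximity
prestige, barycenter), eigenvector-based (eigenvector centrality, Katz
index), subgraph-based (subgraph centrality, within-module z-score),
random-walk (k-step Markov) and social-capital (Burt structural-hole
constraint) measures.

Conventions for disconnected input: unreachable pairs contribute 0 to
harmonic closeness, proximity prestige of an isolated vertex is 0, and the
barycenter score is the reciprocal of total geodesic distance within the
vertex's own component.  Geodesics always count edges (unit lengths);
weights enter only the random-walk transition matrix and the structural-hole
tie proportions.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import igraph as ig
import numpy as np
import pandas as pd

from .graph_io import Network

__all__ = [
    "FEATURE_ORDER",
    "TopologyConfig",
    "ShortestPathSummary",
    "ModuleAssignment",
    "degree",
    "coreness",
    "clustering_coefficient",
    "shortest_paths",
    "betweenness",
    "closeness",
    "proximity_prestige",
    "barycenter",
    "eigenvector_centrality",
    "katz_index",
    "subgraph_centrality",
    "detect_modules",
    "within_module_zscore",
    "k_step_markov",
    "structural_holes",
    "compute_all",
]

#: Fixed column order of every feature table the package produces.
FEATURE_ORDER = (
    "degree",
    "coreness",
    "clustering_coefficient",
    "betweenness",
    "closeness",
    "proximity_prestige",
    "barycenter",
    "eigenvector",
    "katz",
    "subgraph",
    "within_module_z",
    "k_step_markov",
    "structural_holes",
)


@dataclass(frozen=True)
class TopologyConfig:
    """Knobs for the measures that have free parameters.

    katz_alpha_fraction: Katz attenuation as a fraction of 1/lambda_max.
    markov_k: random-walk length (6 by default).
    markov_start: optional set of start vertices (default: all).
    modules_method: "greedy" modularity maximization or "components".
    """

    katz_alpha_fraction: float = 0.5
    markov_k: int = 6
    markov_start: frozenset[str] | None = None
    modules_method: str = "greedy"
    eigen_tol: float = 1e-9
    eigen_max_iter: int = 10000
    seed: int = 0


# ---------------------------------------------------------------------------
# shortest-path machinery


def _bfs(adj: list[list[int]], s: int) -> tuple[np.ndarray, np.ndarray, list[int], list[list[int]]]:
    """Single-source BFS returning distances, geodesic counts, the
    non-decreasing-distance visit order and shortest-path predecessors."""
    n = len(adj)
    dist = np.full(n, np.inf)
    sigma = np.zeros(n)
    preds: list[list[int]] = [[] for _ in range(n)]
    dist[s] = 0.0
    sigma[s] = 1.0
    order: list[int] = []
    queue = deque([s])
    while queue:
        u = queue.popleft()
        order.append(u)
        du = dist[u]
        for v in adj[u]:
            if dist[v] == np.inf:
                dist[v] = du + 1
                queue.append(v)
            if dist[v] == du + 1:
                sigma[v] += sigma[u]
                preds[v].append(u)
    return dist, sigma, order, preds


@dataclass
class ShortestPathSummary:
    """All-pairs geodesic distances and shortest-path counts.

    ``dist[i, j]`` is the number of edges on a shortest i-j path (inf when
    unreachable); ``count[i, j]`` the number of distinct shortest paths.
    Interior-path counts are derived on demand from the composition identity
    sigma_st(v) = sigma_sv * sigma_vt when v lies on an s-t geodesic.
    """

    vertices: Sequence[str]
    dist: np.ndarray
    count: np.ndarray
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {v: i for i, v in enumerate(self.vertices)}

    def distance(self, s: str, t: str) -> float:
        return float(self.dist[self._index[s], self._index[t]])

    def n_paths(self, s: str, t: str) -> float:
        return float(self.count[self._index[s], self._index[t]])

    def through_count(self, s: str, t: str, v: str) -> float:
        """Number of shortest s-t paths with v strictly interior."""
        i, j, k = self._index[s], self._index[t], self._index[v]
        if k == i or k == j or not np.isfinite(self.dist[i, j]):
            return 0.0
        if self.dist[i, k] + self.dist[k, j] == self.dist[i, j]:
            return float(self.count[i, k] * self.count[k, j])
        return 0.0


def shortest_paths(net: Network) -> ShortestPathSummary:
    adj = net.adjacency_lists()
    n = net.n_vertices
    dist = np.empty((n, n))
    count = np.empty((n, n))
    for s in range(n):
        d, sigma, _, _ = _bfs(adj, s)
        dist[s] = d
        count[s] = sigma
    return ShortestPathSummary(net.vertices, dist, count)


# ---------------------------------------------------------------------------
# degree-based measures


def degree(net: Network) -> dict[str, int]:
    """Number of connections of each vertex."""
    return {v: net.degree(v) for v in net.vertices}


def coreness(net: Network) -> dict[str, int]:
    """Largest k such that the vertex survives iterative k-core peeling.

    Batagelj-Zaversnik bucket peeling, O(V + E).
    """
    adj = net.adjacency_lists()
    n = len(adj)
    deg = [len(a) for a in adj]
    if n == 0:
        return {}
    max_deg = max(deg)
    buckets: list[list[int]] = [[] for _ in range(max_deg + 1)]
    for v, d in enumerate(deg):
        buckets[d].append(v)
    core = [0] * n
    seen = [False] * n
    k = 0
    for d in range(max_deg + 1):
        stack = buckets[d]
        while stack:
            v = stack.pop()
            if seen[v] or deg[v] > d:
                # stale bucket entry; vertex lives in a later bucket
                continue
            seen[v] = True
            k = max(k, deg[v])
            core[v] = k
            for u in adj[v]:
                if not seen[u] and deg[u] > deg[v]:
                    deg[u] -= 1
                    buckets[deg[u]].append(u)
    return {net.vertices[v]: core[v] for v in range(n)}


def clustering_coefficient(net: Network) -> dict[str, float]:
    """Fraction of realized edges among each vertex's neighbors (0 if deg < 2)."""
    adj = [set(a) for a in net.adjacency_lists()]
    out: dict[str, float] = {}
    for i, v in enumerate(net.vertices):
        nbrs = adj[i]
        d = len(nbrs)
        if d < 2:
            out[v] = 0.0
            continue
        links = sum(len(adj[u] & nbrs) for u in nbrs) // 2
        out[v] = links / (d * (d - 1) / 2)
    return out


# ---------------------------------------------------------------------------
# shortest-path-based measures


def betweenness(net: Network, normalized: bool = False) -> dict[str, float]:
    """Sum over ordered vertex pairs (s, t) of the fraction of s-t geodesics
    on which the vertex is strictly interior.

    Each unordered pair contributes twice; ``normalized`` halves the result.
    Brandes' dependency accumulation, O(V*E).
    """
    adj = net.adjacency_lists()
    n = len(adj)
    bc = np.zeros(n)
    for s in range(n):
        _, sigma, order, preds = _bfs(adj, s)
        delta = np.zeros(n)
        for w in reversed(order):
            coeff = (1.0 + delta[w]) / sigma[w]
            for u in preds[w]:
                delta[u] += sigma[u] * coeff
            if w != s:
                bc[w] += delta[w]
    if normalized:
        bc /= 2.0
    return {net.vertices[i]: float(bc[i]) for i in range(n)}


def closeness(net: Network) -> dict[str, float]:
    """Harmonic closeness: sum of reciprocal geodesic distances, with
    unreachable vertices contributing 0."""
    adj = net.adjacency_lists()
    out: dict[str, float] = {}
    for i, v in enumerate(net.vertices):
        d, _, _, _ = _bfs(adj, i)
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        inv[i] = 0.0
        inv[~np.isfinite(inv)] = 0.0
        out[v] = float(inv.sum())
    return out


def _reach_stats(net: Network) -> tuple[np.ndarray, np.ndarray]:
    """Per vertex: number of other reachable vertices, and total geodesic
    distance to them."""
    adj = net.adjacency_lists()
    n = len(adj)
    reach = np.zeros(n)
    total = np.zeros(n)
    for i in range(n):
        d, _, _, _ = _bfs(adj, i)
        finite = np.isfinite(d)
        reach[i] = finite.sum() - 1
        total[i] = d[finite].sum()
    return reach, total


def proximity_prestige(net: Network) -> dict[str, float]:
    """Fraction of vertices able to reach v, divided by their mean distance.

    P_P(v) = (I_v / (|V|-1)) / (sum of distances / I_v); 0 when no vertex
    reaches v.  Lies in [0, 1], reaching 1 only when every other vertex is
    adjacent.
    """
    n = net.n_vertices
    reach, total = _reach_stats(net)
    out: dict[str, float] = {}
    for i, v in enumerate(net.vertices):
        if n <= 1 or reach[i] == 0:
            out[v] = 0.0
        else:
            out[v] = float((reach[i] / (n - 1)) / (total[i] / reach[i]))
    return out


def barycenter(net: Network) -> dict[str, float]:
    """Reciprocal of the total geodesic distance to the other vertices of
    the vertex's component; 0 for isolated vertices."""
    _, total = _reach_stats(net)
    return {
        v: (1.0 / float(total[i]) if total[i] > 0 else 0.0)
        for i, v in enumerate(net.vertices)
    }


# ---------------------------------------------------------------------------
# eigenvector-based measures


def eigenvector_centrality(
    net: Network, tol: float = 1e-9, max_iter: int = 10000
) -> dict[str, float]:
    """Entries of the Perron eigenvector of the adjacency matrix, unit
    Euclidean norm.

    Power iteration on A + I — same leading eigenvector, but immune to the
    +/-lambda oscillation on bipartite graphs.  Convergence is judged by the
    residual ||A x - lambda x||_inf against A itself.
    """
    if net.n_edges == 0:
        raise ValueError("eigenvector centrality undefined on an edgeless graph")
    from scipy.sparse import csr_array

    a = csr_array(net.adjacency_matrix())
    n = a.shape[0]
    x = np.full(n, 1.0 / math.sqrt(n))
    for _ in range(max_iter):
        y = a @ x + x  # (A + I) x
        y /= np.linalg.norm(y)
        x = y
        ax = a @ x
        lam = float(x @ ax)
        residual = float(np.max(np.abs(ax - lam * x)))
        if residual <= tol:
            x = np.abs(x)  # Perron vector is sign-free up to a global flip
            return {net.vertices[i]: float(x[i]) for i in range(n)}
    raise RuntimeError(
        f"power iteration did not converge in {max_iter} iterations "
        f"(residual {residual:.3e} > tol {tol:.1e})"
    )


def _lambda_max(a: np.ndarray) -> float:
    if not a.any():
        return 0.0
    return float(np.linalg.eigvalsh(a)[-1])


def katz_index(
    net: Network,
    alpha: float | None = None,
    alpha_fraction: float = 0.5,
    _lam: float | None = None,
) -> dict[str, float]:
    """Katz status index ((I - alpha*A^T)^-1 - I) 1, by direct linear solve.

    alpha defaults to ``alpha_fraction / lambda_max``; the series diverges
    for alpha >= 1/lambda_max and such values are rejected.
    """
    a = net.adjacency_matrix()
    lam = _lambda_max(a) if _lam is None else _lam
    if alpha is None:
        alpha = alpha_fraction / lam if lam > 0 else alpha_fraction
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    if lam > 0 and alpha >= 1.0 / lam:
        raise ValueError(
            f"alpha={alpha:.6g} >= 1/lambda_max={1.0 / lam:.6g}: Katz series diverges"
        )
    from scipy.sparse import csc_array, eye_array
    from scipy.sparse.linalg import spsolve

    n = a.shape[0]
    system = csc_array(eye_array(n) - alpha * csc_array(a.T))
    y = spsolve(system, np.ones(n))
    katz = y - 1.0
    katz[np.abs(katz) < 1e-15] = 0.0
    return {net.vertices[i]: float(katz[i]) for i in range(n)}


def subgraph_centrality(
    net: Network, _eig: tuple[np.ndarray, np.ndarray] | None = None
) -> dict[str, float]:
    """Diagonal of exp(A): sum_k (A^k)_vv / k!, weighting each closed walk
    by the reciprocal factorial of its length.

    Evaluated through the symmetric eigendecomposition
    sum_j u_j(v)^2 e^{lambda_j}.
    """
    lam, u = np.linalg.eigh(net.adjacency_matrix()) if _eig is None else _eig
    sc = (u**2) @ np.exp(lam)
    return {net.vertices[i]: float(sc[i]) for i in range(net.n_vertices)}


# ---------------------------------------------------------------------------
# module structure


@dataclass(frozen=True)
class ModuleAssignment:
    """Total map vertex -> contiguous integer module id."""

    module_of: Mapping[str, int]

    @property
    def n_modules(self) -> int:
        return len(set(self.module_of.values())) if self.module_of else 0

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for v, m in self.module_of.items():
            out.setdefault(m, []).append(v)
        return out


def _components(net: Network) -> list[int]:
    adj = net.adjacency_lists()
    n = len(adj)
    comp = [-1] * n
    c = 0
    for s in range(n):
        if comp[s] != -1:
            continue
        queue = deque([s])
        comp[s] = c
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if comp[v] == -1:
                    comp[v] = c
                    queue.append(v)
        c += 1
    return comp


def detect_modules(net: Network, method: str = "greedy") -> ModuleAssignment:
    """Partition vertices into modules.

    "greedy" runs deterministic agglomerative (fast-greedy) modularity
    maximization; "components" uses connected components.
    """
    n = net.n_vertices
    if method == "components":
        comp = _components(net)
        return ModuleAssignment({net.vertices[i]: comp[i] for i in range(n)})
    if method != "greedy":
        raise ValueError(f"unknown module detection method {method!r}")
    edges = [(net.index_of(u), net.index_of(v)) for u, v, _ in net.edges()]
    if not edges:
        return ModuleAssignment({v: i for i, v in enumerate(net.vertices)})
    g = ig.Graph(n=n, edges=edges)
    membership = g.community_fastgreedy().as_clustering().membership
    # renumber module ids in first-seen vertex order for determinism
    remap: dict[int, int] = {}
    module_of: dict[str, int] = {}
    for i, v in enumerate(net.vertices):
        m = membership[i]
        if m not in remap:
            remap[m] = len(remap)
        module_of[v] = remap[m]
    return ModuleAssignment(module_of)


def within_module_zscore(
    net: Network, modules: ModuleAssignment
) -> dict[str, float]:
    """Within-module degree, standardized against the vertex's module:
    z_i = (k_i - mean_k) / sd_k with the population standard deviation;
    z = 0 when the module's within-degrees are constant."""
    missing = [v for v in net.vertices if v not in modules.module_of]
    if missing:
        raise ValueError(f"module assignment missing {len(missing)} vertices")
    k_within = {
        v: sum(1 for u in net.neighbors(v) if modules.module_of[u] == modules.module_of[v])
        for v in net.vertices
    }
    out: dict[str, float] = {}
    for m, members in modules.members().items():
        ks = np.array([k_within[v] for v in members], dtype=float)
        mu = ks.mean()
        sd = ks.std()  # population sd
        for v, k in zip(members, ks):
            out[v] = float((k - mu) / sd) if sd > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# random-walk and social-capital measures


def _transition_matrix(net: Network) -> np.ndarray:
    """Row-stochastic transition matrix from edge weights; a vertex with no
    neighbors is absorbing (stays put), so total probability is conserved."""
    t = net.adjacency_matrix(weighted=True)
    strength = t.sum(axis=1)
    for i in range(t.shape[0]):
        if strength[i] > 0:
            t[i] /= strength[i]
        else:
            t[i, i] = 1.0
    return t


def k_step_markov(
    net: Network, k: int = 6, start: frozenset[str] | set[str] | None = None
) -> dict[str, float]:
    """Probability that a k-step random walk from a uniform start over the
    root set occupies each vertex; the output sums to 1."""
    if k < 0:
        raise ValueError(f"walk length must be nonnegative, got {k}")
    n = net.n_vertices
    p0 = np.zeros(n)
    if start:
        idx = [net.index_of(v) for v in start]
        if not idx:
            raise ValueError("start set matches no vertices")
        p0[idx] = 1.0 / len(idx)
    else:
        p0[:] = 1.0 / n
    t = _transition_matrix(net)
    p = p0
    for _ in range(k):
        p = p @ t
    return {net.vertices[i]: float(p[i]) for i in range(n)}


def structural_holes(net: Network) -> dict[str, float]:
    """Burt's aggregate constraint.

    C_i = sum over neighbors j of (p_ij + sum_{q != i,j} p_iq p_qj)^2 where
    p_ij is i's proportional tie strength w_ij / sum_q w_iq.  High constraint
    means the vertex's contacts are mutually connected (no brokerage); an
    isolated vertex scores 0.
    """
    p = _transition_matrix(net)
    # absorbing self-entries added for degree-0 rows must not leak in here
    np.fill_diagonal(p, 0.0)
    m = p + p @ p
    a = net.adjacency_matrix()
    c = ((m * a) ** 2).sum(axis=1)  # restrict to actual neighbors j
    return {net.vertices[i]: float(c[i]) for i in range(net.n_vertices)}


# ---------------------------------------------------------------------------
# the full feature table


def compute_all(net: Network, config: TopologyConfig | None = None) -> pd.DataFrame:
    """All thirteen measures for every vertex, columns in FEATURE_ORDER.

    Deterministic given the network and configuration.  Eigenvector
    centrality requires at least one edge.
    """
    cfg = config or TopologyConfig()
    modules = detect_modules(net, cfg.modules_method)
    # one BFS sweep feeds all four shortest-path measures
    adj = net.adjacency_lists()
    n = len(adj)
    bc = np.zeros(n)
    inv_sum = np.zeros(n)
    reach = np.zeros(n)
    total = np.zeros(n)
    for s in range(n):
        d, sigma, order, preds = _bfs(adj, s)
        delta = np.zeros(n)
        for w in reversed(order):
            coeff = (1.0 + delta[w]) / sigma[w]
            for u in preds[w]:
                delta[u] += sigma[u] * coeff
            if w != s:
                bc[w] += delta[w]
        finite = np.isfinite(d)
        reach[s] = finite.sum() - 1
        total[s] = d[finite].sum()
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        inv[s] = 0.0
        inv[~np.isfinite(inv)] = 0.0
        inv_sum[s] = inv.sum()
    verts = net.vertices
    pp = {
        v: (
            float((reach[i] / (n - 1)) / (total[i] / reach[i]))
            if n > 1 and reach[i] > 0
            else 0.0
        )
        for i, v in enumerate(verts)
    }
    # one eigendecomposition feeds subgraph centrality and the Katz bound
    eig = np.linalg.eigh(net.adjacency_matrix())
    lam_max = float(eig[0][-1]) if net.n_edges else 0.0
    columns = {
        "degree": degree(net),
        "coreness": coreness(net),
        "clustering_coefficient": clustering_coefficient(net),
        "betweenness": {v: float(bc[i]) for i, v in enumerate(verts)},
        "closeness": {v: float(inv_sum[i]) for i, v in enumerate(verts)},
        "proximity_prestige": pp,
        "barycenter": {
            v: (1.0 / float(total[i]) if total[i] > 0 else 0.0)
            for i, v in enumerate(verts)
        },
        "eigenvector": eigenvector_centrality(
            net, tol=cfg.eigen_tol, max_iter=cfg.eigen_max_iter
        ),
        "katz": katz_index(net, alpha_fraction=cfg.katz_alpha_fraction, _lam=lam_max),
        "subgraph": subgraph_centrality(net, _eig=eig),
        "within_module_z": within_module_zscore(net, modules),
        "k_step_markov": k_step_markov(net, k=cfg.markov_k, start=cfg.markov_start),
        "structural_holes": structural_holes(net),
    }
    table = pd.DataFrame(
        {name: [columns[name][v] for v in net.vertices] for name in FEATURE_ORDER},
        index=pd.Index(net.vertices, name="vertex"),
        dtype=float,
    )
    return table
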