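"""Synthetic study generator: scale-free networks with planted disease genes.

Real disease-gene studies pair a genome-scale interaction network with a
small curated signature (a few percent of vertices).  This module emulates
that setting: a preferential-attachment graph gives the heavy-tailed degree
structure typical of protein networks, and the positive class is planted by
thresholding a latent score that is a weighted sum of standardized
topological features plus Gaussian noise.  Labeling the top quantile (rather
than sampling Bernoulli draws) makes the positive count exact, so tests
built on these fixtures are not flaky.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph_io import GeneSet, Network
from .resampling import LabeledDataset, label_dataset
from .topology import FEATURE_ORDER, TopologyConfig, compute_all

__all__ = ["SyntheticSpec", "generate_network", "plant_labels", "generate_study"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic study.

    n_vertices: network size (>= 10).
    edges_per_new_vertex: preferential-attachment parameter m; each arriving
        vertex connects to m distinct existing vertices.
    positive_fraction: share of vertices labeled positive, in (0, 0.5);
        default 0.04 mirrors the few-percent scale of curated signatures.
    effect_weights: feature name -> coefficient of the latent labeling score.
    noise_sd: standard deviation of the latent Gaussian noise (features are
        standardized, so 1.0 equals one feature standard deviation).
    """

    n_vertices: int = 1000
    edges_per_new_vertex: int = 2
    positive_fraction: float = 0.04
    effect_weights: dict[str, float] = field(
        default_factory=lambda: {"degree": 1.0, "structural_holes": 1.0}
    )
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vertices < 10:
            raise ValueError("n_vertices must be >= 10")
        if not 0 < self.positive_fraction < 0.5:
            raise ValueError("positive_fraction must lie in (0, 0.5)")
        if not 1 <= self.edges_per_new_vertex < self.n_vertices:
            raise ValueError("edges_per_new_vertex must be in [1, n_vertices)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        unknown = set(self.effect_weights) - set(FEATURE_ORDER)
        if unknown:
            raise ValueError(f"unknown feature name(s) in effect_weights: {sorted(unknown)}")


def _vertex_id(i: int, n: int) -> str:
    width = max(4, len(str(n)))
    return f"g{i + 1:0{width}d}"


def generate_network(spec: SyntheticSpec) -> Network:
    """Connected preferential-attachment graph, deterministic given the seed.

    Construction: a complete seed graph on m vertices, then each new vertex
    attaches to m distinct targets drawn proportionally to current degree.
    Total edges: C(m, 2) + (n - m) * m.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_vertices, spec.edges_per_new_vertex
    net = Network()
    ids = [_vertex_id(i, n) for i in range(n)]
    repeated: list[int] = []  # vertex index repeated once per degree unit
    for i in range(m):
        for j in range(i):
            net.add_edge(ids[i], ids[j])
            repeated += [i, j]
    if m == 1:
        net.add_vertex(ids[0])
        repeated = [0]
    for v in range(m, n):
        targets: set[int] = set()
        while len(targets) < m:
            targets.add(repeated[rng.integers(len(repeated))])
        for t in sorted(targets):
            net.add_edge(ids[v], ids[t])
            repeated.append(t)
        repeated += [v] * m
    return net


def plant_labels(
    net: Network, spec: SyntheticSpec, table: pd.DataFrame | None = None
) -> GeneSet:
    """Label the top positive_fraction of a latent topological score.

    latent = sum_f w_f * z_f + Normal(0, noise_sd); the top
    ceil(positive_fraction * n) vertices are the positives, ties broken by
    vertex order.
    """
    if table is None:
        table = compute_all(net, TopologyConfig(seed=spec.seed))
    rng = np.random.default_rng(spec.seed + 1)
    n = len(table)
    latent = rng.normal(0.0, spec.noise_sd, size=n)
    for feat, w in spec.effect_weights.items():
        col = table[feat].to_numpy(dtype=float)
        sd = col.std()
        z = (col - col.mean()) / sd if sd > 0 else np.zeros(n)
        latent += w * z
    n_pos = int(np.ceil(spec.positive_fraction * n))
    top = np.argsort(-latent, kind="stable")[:n_pos]
    return GeneSet(table.index[top])


def generate_study(
    spec: SyntheticSpec,
) -> tuple[Network, GeneSet, pd.DataFrame, LabeledDataset]:
    """Network, planted signature, feature table and labeled dataset in one
    call; every artifact is a pure function of the spec."""
    net = generate_network(spec)
    table = compute_all(net, TopologyConfig(seed=spec.seed))
    signature = plant_labels(net, spec, table=table)
    data = label_dataset(table, signature)
    return net, signature, table, data
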