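"""Readers and writers for networks, gene sets, and feature tables.

Networks are simple undirected graphs over string vertex identifiers.
Self-loops are dropped (with a logged count) and parallel edges collapsed
keeping the maximum weight, because every downstream topological measure
assumes a simple graph.  Vertex order is first-seen order and is preserved
through every matrix the package builds.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger("nettop")

__all__ = [
    "Network",
    "GeneSet",
    "read_edge_list",
    "read_sif",
    "read_graphml",
    "read_gene_set",
    "read_feature_table",
    "write_feature_table",
]


class Network:
    """Simple undirected graph with optional nonnegative edge weights.

    Vertices are string identifiers kept in first-seen order; all adjacency
    matrices and feature tables are indexed by that order.
    """

    def __init__(self) -> None:
        self.vertices: list[str] = []
        self._index: dict[str, int] = {}
        self._adj: list[dict[int, float]] = []
        self.dropped_loops: int = 0

    # -- construction -------------------------------------------------

    def add_vertex(self, v: str) -> int:
        i = self._index.get(v)
        if i is None:
            i = len(self.vertices)
            self._index[v] = i
            self.vertices.append(v)
            self._adj.append({})
        return i

    def add_edge(self, u: str, v: str, weight: float = 1.0) -> bool:
        """Add an undirected edge; returns False for a (dropped) self-loop.

        A duplicate edge is collapsed, keeping the maximum weight.
        """
        if weight < 0:
            raise ValueError(f"negative edge weight {weight!r} on ({u}, {v})")
        i, j = self.add_vertex(u), self.add_vertex(v)
        if i == j:
            self.dropped_loops += 1
            return False
        w = max(self._adj[i].get(j, float("-inf")), weight)
        self._adj[i][j] = w
        self._adj[j][i] = w
        return True

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str] | tuple[str, str, float]],
        vertices: Iterable[str] = (),
    ) -> "Network":
        net = cls()
        for v in vertices:
            net.add_vertex(v)
        for e in edges:
            net.add_edge(*e)
        return net

    # -- queries ------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj) // 2

    def __contains__(self, v: str) -> bool:
        return v in self._index

    def index_of(self, v: str) -> int:
        return self._index[v]

    def degree(self, v: str) -> int:
        return len(self._adj[self._index[v]])

    def neighbors(self, v: str) -> list[str]:
        return [self.vertices[j] for j in self._adj[self._index[v]]]

    def adjacency_lists(self) -> list[list[int]]:
        """Neighbor indices per vertex index (unweighted view)."""
        return [list(nbrs) for nbrs in self._adj]

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for i, nbrs in enumerate(self._adj):
            for j, w in nbrs.items():
                if i < j:
                    yield self.vertices[i], self.vertices[j], w

    def adjacency_matrix(self, weighted: bool = False) -> np.ndarray:
        """Dense adjacency matrix A in vertex order; A[i, j] = weight or 0/1."""
        n = self.n_vertices
        a = np.zeros((n, n))
        for i, nbrs in enumerate(self._adj):
            for j, w in nbrs.items():
                a[i, j] = w if weighted else 1.0
        return a

    def __repr__(self) -> str:  # pragma: no cover
        return f"Network(n_vertices={self.n_vertices}, n_edges={self.n_edges})"


class GeneSet(frozenset):
    """Set of gene identifiers used as the positive-class label source."""

    @classmethod
    def from_lines(cls, lines: Iterable[str]) -> "GeneSet":
        ids = {s.strip() for s in lines}
        ids.discard("")
        return cls(ids)


def _parse_error(path, lineno: int, line: str, why: str) -> ValueError:
    return ValueError(f"{path}:{lineno}: {why}: {line!r}")


def read_edge_list(
    path, delimiter: str | None = None, weighted: bool = False
) -> Network:
    """Read a whitespace- or delimiter-separated edge list.

    Lines starting with ``#`` are comments.  Each data line needs at least
    two fields (source, target) and, with ``weighted``, a numeric third.
    """
    net = Network()
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter)
            if len(fields) < 2:
                raise _parse_error(path, lineno, line, "expected at least 2 fields")
            w = 1.0
            if weighted:
                if len(fields) < 3:
                    raise _parse_error(path, lineno, line, "missing weight field")
                try:
                    w = float(fields[2])
                except ValueError:
                    raise _parse_error(path, lineno, line, "non-numeric weight")
            net.add_edge(fields[0], fields[1], w)
            n_lines += 1
    if n_lines == 0:
        raise ValueError(f"{path}: no edges found")
    if net.dropped_loops:
        logger.info("dropped %d self-loop(s) reading %s", net.dropped_loops, path)
    return net


def read_sif(path) -> Network:
    """Read a simple-interaction-format file: ``source relation target...``.

    The relation column is ignored; a line may list several targets.
    """
    net = Network()
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) == 1:
                net.add_vertex(fields[0])
            elif len(fields) >= 3:
                for target in fields[2:]:
                    net.add_edge(fields[0], target)
            else:
                raise _parse_error(
                    path, lineno, line, "expected 1 or >=3 whitespace fields"
                )
            n_lines += 1
    if n_lines == 0:
        raise ValueError(f"{path}: empty SIF file")
    if net.dropped_loops:
        logger.info("dropped %d self-loop(s) reading %s", net.dropped_loops, path)
    return net


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def read_graphml(path) -> Network:
    """Read a GraphML document as an undirected network.

    A directed graph is coerced to undirected with a logged warning
    (reciprocal arcs collapse onto one edge).  An edge-weight attribute
    named ``weight``, if declared, is honored.
    """
    tree = ET.parse(path)
    root = tree.getroot()
    weight_keys: set[str] = set()
    for el in root.iter():
        if (
            _localname(el.tag) == "key"
            and el.get("for") == "edge"
            and el.get("attr.name") == "weight"
        ):
            weight_keys.add(el.get("id", ""))
    net = Network()
    saw_graph = False
    for graph in root.iter():
        if _localname(graph.tag) != "graph":
            continue
        saw_graph = True
        if graph.get("edgedefault", "undirected") == "directed":
            logger.warning("%s: directed GraphML coerced to undirected", path)
        for el in graph:
            name = _localname(el.tag)
            if name == "node":
                net.add_vertex(el.get("id"))
            elif name == "edge":
                w = 1.0
                for data in el:
                    if _localname(data.tag) == "data" and data.get("key") in weight_keys:
                        w = float(data.text)
                net.add_edge(el.get("source"), el.get("target"), w)
    if not saw_graph:
        raise ValueError(f"{path}: no <graph> element found")
    if net.dropped_loops:
        logger.info("dropped %d self-loop(s) reading %s", net.dropped_loops, path)
    return net


def read_gene_set(path) -> GeneSet:
    """Read one gene identifier per line; blanks skipped, whitespace trimmed."""
    with open(path) as fh:
        genes = GeneSet.from_lines(fh)
    if not genes:
        raise ValueError(f"{path}: no gene identifiers found")
    return genes


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a vertices x features table as TSV (index column = vertex id).

    Values survive a round-trip through :func:`read_feature_table` to at
    least 12 significant digits.
    """
    if table.empty:
        raise ValueError("refusing to write an empty feature table")
    table.to_csv(path, sep="\t", index_label="vertex")


def read_feature_table(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_feature_table`."""
    df = pd.read_csv(path, sep="\t", index_col="vertex")
    df.index = df.index.astype(str)
    return df
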