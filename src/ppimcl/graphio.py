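"""PPI network I/O and construction of the weighted flow matrix.

A protein--protein interaction (PPI) network is an undirected simple graph
whose vertices are protein identifiers.  Edges are weighted by the Jaccard
coefficient of the endpoint neighbourhoods,

    A(i, j) = |N(v_i) ∩ N(v_j)| / |N(v_i) ∪ N(v_j)|   for (v_i, v_j) ∈ E,

the diagonal carries the strongest incident similarity of each vertex, and
column normalisation of A yields the initial flow matrix of the Markov
Cluster Algorithm (each column is the transition distribution of a random
walk step out of that vertex).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkParseError",
    "ProteinGraph",
    "load_network",
    "write_network",
    "build_adjacency",
    "build_flow_matrix",
    "is_column_stochastic",
    "read_complexes",
    "write_complexes",
]


class NetworkParseError(ValueError):
    """Raised when an input file cannot be parsed; the message names the line."""


class ProteinGraph:
    """Undirected simple graph of protein IDs.

    Self-loops and duplicate edges are never stored.  Vertex order is
    first-appearance order, which fixes the row/column ordering of every
    matrix derived from the graph (deterministic output depends on it).
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "ProteinGraph":
        g = cls()
        for u, v in edges:
            g.add_edge(u, v)
        return g

    def add_vertex(self, v: str) -> None:
        self._g.add_node(v)

    def add_edge(self, u: str, v: str) -> None:
        """Add vertices in encounter order; silently drop self-loops."""
        self._g.add_node(u)
        self._g.add_node(v)
        if u != v:
            self._g.add_edge(u, v)

    # -- queries ----------------------------------------------------------
    @property
    def vertices(self) -> list[str]:
        return list(self._g.nodes)

    @property
    def n_vertices(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self._g.edges}

    def neighbors(self, v: str) -> set[str]:
        return set(self._g.adj[v])

    def degree(self, v: str) -> int:
        return self._g.degree[v]

    def has_vertex(self, v: str) -> bool:
        return v in self._g

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def to_networkx(self) -> nx.Graph:
        return self._g

    def __contains__(self, v: str) -> bool:
        return v in self._g

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ProteinGraph({self.n_vertices} vertices, {self.n_edges} edges)"


def load_network(path: str | Path) -> ProteinGraph:
    """Read a 2+-column whitespace/TAB edge list into a :class:`ProteinGraph`.

    The first two tokens of each line are protein IDs; extra columns are
    ignored.  Lines starting with ``#`` and blank lines are skipped.
    Self-interactions and repeated interactions (in either orientation)
    are collapsed.

    Raises
    ------
    NetworkParseError
        If a non-comment line has fewer than two tokens.
    OSError
        If the file cannot be read.
    """
    g = ProteinGraph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise NetworkParseError(
                    f"{path}: line {lineno}: expected at least 2 columns, got {len(tokens)}"
                )
            g.add_edge(tokens[0], tokens[1])
    return g


def write_network(g: ProteinGraph, path: str | Path) -> None:
    """Write the edge set, smaller ID first per edge, sorted lexicographically."""
    lines = sorted(tuple(sorted(e)) for e in g.edges)
    with open(path, "w") as fh:
        for u, v in lines:
            fh.write(f"{u}\t{v}\n")


def build_adjacency(g: ProteinGraph, floor: float = 0.01) -> sp.csc_matrix:
    """Jaccard-weighted adjacency matrix over the graph's vertex order.

    For each edge the weight is the Jaccard coefficient of the endpoint
    neighbour sets, floored at ``floor`` (leaf/peripheral edges otherwise get
    weight 0, which disconnects the random walk; ``floor=0`` reproduces the
    literal coefficient).  The diagonal entry of each vertex is the maximum
    off-diagonal entry of its row (0 for isolated vertices; those columns are
    repaired in :func:`build_flow_matrix`).
    """
    if g.n_vertices < 1:
        raise ValueError("graph must have at least one vertex")
    if not 0.0 <= floor < 1.0:
        raise ValueError(f"floor must be in [0, 1), got {floor}")
    vertices = g.vertices
    index = {v: i for i, v in enumerate(vertices)}
    nbrs = {v: g.neighbors(v) for v in vertices}

    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    row_max = np.zeros(g.n_vertices)
    for e in g.edges:
        u, v = tuple(e)
        i, j = index[u], index[v]
        inter = len(nbrs[u] & nbrs[v])
        union = len(nbrs[u] | nbrs[v])
        w = max(inter / union, floor)
        rows.extend((i, j))
        cols.extend((j, i))
        data.extend((w, w))
        row_max[i] = max(row_max[i], w)
        row_max[j] = max(row_max[j], w)
    # diagonal: strongest incident similarity of the vertex
    for i in range(g.n_vertices):
        if row_max[i] > 0.0:
            rows.append(i)
            cols.append(i)
            data.append(row_max[i])
    n = g.n_vertices
    return sp.csc_matrix((data, (rows, cols)), shape=(n, n))


def build_flow_matrix(A: sp.spmatrix) -> sp.csc_matrix:
    """Column-normalise an adjacency matrix into the initial MCL flow matrix.

    A zero column (fully isolated vertex with ``floor=0``) is replaced by a
    unit column concentrated on the diagonal, so the vertex forms a singleton
    attractor and is discarded later by the minimum complex-size rule.
    """
    A = sp.csc_matrix(A, copy=True)
    if A.shape[0] != A.shape[1]:
        raise ValueError("adjacency matrix must be square")
    colsums = np.asarray(A.sum(axis=0)).ravel()
    zero_cols = np.flatnonzero(colsums == 0.0)
    if zero_cols.size:
        fix = sp.csc_matrix(
            (np.ones(zero_cols.size), (zero_cols, zero_cols)), shape=A.shape
        )
        A = (A + fix).tocsc()
        colsums[zero_cols] = 1.0
    M = A.multiply(1.0 / colsums).tocsc()
    M.sort_indices()
    return M


def is_column_stochastic(M: sp.spmatrix, tol: float = 1e-9) -> bool:
    """True iff every column sums to 1 within ``tol`` and all entries are >= 0."""
    M = sp.csc_matrix(M)
    if M.nnz and M.data.min() < 0:
        return False
    colsums = np.asarray(M.sum(axis=0)).ravel()
    return bool(np.all(np.abs(colsums - 1.0) <= tol))


# -- complex catalogues ----------------------------------------------------
# Candidate and benchmark complexes share one dialect: one complex per line,
# whitespace-separated protein IDs.


def read_complexes(path: str | Path) -> list[set[str]]:
    complexes: list[set[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            complexes.append(set(line.split()))
    return complexes


def write_complexes(complexes: Sequence[set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in complexes:
            fh.write(" ".join(sorted(c)) + "\n")
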