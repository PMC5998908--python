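"""Markov Cluster Algorithm (MCL) on a column-stochastic flow matrix.

One MCL iteration is Expand (matrix squaring, spreading flow along walks),
Inflate (entrywise power with exponent r followed by column renormalisation,
sharpening strong flow), and Prune (zeroing per-column entries below a
mean-minus-variance threshold, then renormalising).  Iteration stops when the
matrix change falls below a tolerance; columns then concentrate on attractor
vertices and vertices sharing an attractor form one cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .graphio import is_column_stochastic

logger = logging.getLogger(__name__)

__all__ = [
    "MclParams",
    "ClusterPartition",
    "expand",
    "inflate",
    "prune",
    "run_mcl",
    "extract_clusters",
]


@dataclass(frozen=True)
class MclParams:
    """Parameters of the Expand/Inflate/Prune loop.

    r : inflation exponent (> 1); larger r gives smaller, tighter clusters.
    w : prune-threshold multiplier (>= 0); the per-column threshold is
        mean minus w times the population variance over the column support.
    tol : convergence tolerance on the max-norm change per iteration.
    max_iter : iteration cap; hitting it logs a warning, never raises.
    """

    r: float = 2.0
    w: float = 1.0
    tol: float = 1e-6
    max_iter: int = 100

    def __post_init__(self) -> None:
        if self.r <= 1:
            raise ValueError(f"inflation exponent r must be > 1, got {self.r}")
        if self.w < 0:
            raise ValueError(f"prune multiplier w must be >= 0, got {self.w}")
        if self.tol <= 0:
            raise ValueError(f"tol must be > 0, got {self.tol}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")


@dataclass
class ClusterPartition:
    """Disjoint clusters covering all vertices, one attractor ID per cluster."""

    clusters: list[set[str]]
    attractors: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]


def _normalize_columns(M: sp.csc_matrix) -> sp.csc_matrix:
    colsums = np.asarray(M.sum(axis=0)).ravel()
    if np.any(colsums <= 0):
        raise ValueError("cannot normalize a matrix with a non-positive column sum")
    out = M.multiply(1.0 / colsums).tocsc()
    out.sort_indices()
    return out


def expand(M: sp.spmatrix) -> sp.csc_matrix:
    """Expansion step: the matrix square M @ M.

    The product of column-stochastic matrices is column-stochastic, so no
    renormalisation is needed.
    """
    M = sp.csc_matrix(M)
    out = (M @ M).tocsc()
    out.sort_indices()
    return out


def inflate(M: sp.spmatrix, r: float) -> sp.csc_matrix:
    """Inflation step: entrywise power r, then per-column renormalisation."""
    if r <= 1:
        raise ValueError(f"inflation exponent r must be > 1, got {r}")
    M = sp.csc_matrix(M)
    powered = M.power(r)
    return _normalize_columns(powered)


def prune(M: sp.spmatrix, w: float) -> sp.csc_matrix:
    """Pruning step: drop small per-column entries, then renormalise.

    For column j with support L_j = {k : M(k,j) > 0},

        avg(j) = mean of the support entries,
        thd(j) = avg(j) - w * population-variance of the support entries,

    entries strictly below thd(j) are zeroed.  The column maximum is always
    >= avg(j) >= thd(j), so a column can never be emptied.  thd(j) may be
    <= 0 for a high-variance column, in which case nothing is pruned there.
    """
    if w < 0:
        raise ValueError(f"prune multiplier w must be >= 0, got {w}")
    M = sp.csc_matrix(M, copy=True)
    M.eliminate_zeros()
    M.sort_indices()
    n = M.shape[1]
    data = M.data
    indptr = M.indptr
    keep = np.ones_like(data, dtype=bool)
    for j in range(n):
        lo, hi = indptr[j], indptr[j + 1]
        if hi == lo:
            continue
        col = data[lo:hi]
        avg = col.mean()
        var = np.mean((col - avg) ** 2)
        thd = avg - w * var
        assert col.max() >= thd - 1e-15, "pruning would empty a column"
        keep[lo:hi] = col >= thd
    M.data[~keep] = 0.0
    M.eliminate_zeros()
    return _normalize_columns(M)


def run_mcl(M0: sp.spmatrix, params: MclParams | None = None) -> tuple[sp.csc_matrix, int]:
    """Iterate [expand -> inflate -> prune] until convergence.

    Each iteration consumes the pruned, renormalised matrix of the previous
    one.  Convergence is max absolute entrywise change < ``params.tol``;
    at ``params.max_iter`` the current state is returned with a warning.

    Returns the converged flow matrix and the number of iterations run.
    """
    if params is None:
        params = MclParams()
    M = sp.csc_matrix(M0, copy=True)
    if not is_column_stochastic(M, tol=1e-7):
        raise ValueError("initial matrix is not column-stochastic")
    iterations = 0
    for iterations in range(1, params.max_iter + 1):
        M_next = prune(inflate(expand(M), params.r), params.w)
        assert is_column_stochastic(M_next, tol=1e-7)
        delta = abs(M_next - M)
        change = delta.max() if delta.nnz else 0.0
        M = M_next
        if change < params.tol:
            break
    else:  # pragma: no cover - depends on max_iter
        logger.warning(
            "MCL did not converge within %d iterations (last change %.3g)",
            params.max_iter,
            change,
        )
        return M, params.max_iter
    return M, iterations


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # lower index wins, for determinism
            if ra < rb:
                self.parent[rb] = ra
            else:
                self.parent[ra] = rb


def extract_clusters(M: sp.spmatrix, vertices: Sequence[str]) -> ClusterPartition:
    """Read the converged flow matrix into a vertex partition.

    Each column's argmax row is that vertex's attractor (ties broken toward
    the lowest row index, for determinism); vertices sharing an attractor —
    and attractors flowing to each other — are merged into one cluster.
    """
    M = sp.csc_matrix(M)
    M.sort_indices()
    n = M.shape[1]
    if len(vertices) != n:
        raise ValueError(f"{len(vertices)} vertex labels for a {n}-column matrix")
    uf = _UnionFind(n)
    for j in range(n):
        lo, hi = M.indptr[j], M.indptr[j + 1]
        if hi == lo:
            continue  # structurally impossible for a stochastic column
        col = M.data[lo:hi]
        rows = M.indices[lo:hi]
        attractor = rows[int(np.argmax(col))]  # first max = lowest index
        uf.union(j, int(attractor))

    groups: dict[int, list[int]] = {}
    for j in range(n):
        groups.setdefault(uf.find(j), []).append(j)
    clusters: list[set[str]] = []
    attractors: list[str] = []
    for root in sorted(groups):
        members = groups[root]
        clusters.append({vertices[i] for i in members})
        attractors.append(vertices[root])
    return ClusterPartition(clusters=clusters, attractors=attractors)
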