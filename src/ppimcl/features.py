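"""Complex-level and protein-vs-complex features (topology + co-expression).

Topology features are built on the n-connection relation: two distinct
vertices are n-connected when their shortest-path distance in the whole
network is at most n (default convention; an ``exact`` mode requiring
distance exactly n is also available).  PathNum counts shortest paths of
length exactly n.  Co-expression aggregates reuse the pairwise E_co and Co
scores of :mod:`ppimcl.expression`.

All |C| x |C| normalisations keep the printed squared denominator while the
diagonal (self pairs) contributes 0 — self-distance and self co-expression
are excluded by the contracts of ``connect`` and ``CoexpressionModel.eco``.

The seven-feature vector scored by the refinement stage is, in fixed order:
ConnectRatio(v,C,2), PathRatio(v,C,2), DenDiff(v,C,2), E_co(v,C),
CoDiff(v,C), CoProNum(v,C), CoProRatio(v,C).  Distances use n = 2 and the
whole network, not the complex-induced subgraph.
"""

from __future__ import annotations

from collections import deque
from typing import Iterable

import numpy as np

from .expression import CoexpressionModel
from .graphio import ProteinGraph

__all__ = [
    "FEATURE_NAMES",
    "connect",
    "path_num",
    "connect_ratio",
    "path_ratio",
    "density",
    "density_diff",
    "eco_complex",
    "eco_protein_complex",
    "co_ratio",
    "co_diff",
    "co_pro_num",
    "co_pro_ratio",
    "feature_vector",
]

FEATURE_NAMES = (
    "ConnectRatio",
    "PathRatio",
    "DenDiff",
    "EcoProteinComplex",
    "CoDiff",
    "CoProNum",
    "CoProRatio",
)


def _bfs(g: ProteinGraph, source: str, cutoff: int) -> dict[str, tuple[int, int]]:
    """Distances and shortest-path counts from ``source`` up to ``cutoff``.

    Returns {vertex: (distance, number of shortest paths)} for vertices at
    distance <= cutoff (the source itself included at distance 0).
    """
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        du = dist[u]
        if du == cutoff:
            continue
        for v in g.neighbors(u):
            if v not in dist:
                dist[v] = du + 1
                sigma[v] = sigma[u]
                queue.append(v)
            elif dist[v] == du + 1:
                sigma[v] += sigma[u]
    return {v: (d, sigma[v]) for v, d in dist.items()}


def _require_vertices(g: ProteinGraph, vertices: Iterable[str]) -> None:
    for v in vertices:
        if v not in g:
            raise KeyError(f"vertex {v!r} not in graph")


def connect(g: ProteinGraph, u: str, v: str, n: int, mode: str = "at_most") -> int:
    """n-connection indicator between two vertices.

    ``at_most`` (default): 1 iff 1 <= d(u,v) <= n; ``exact``: 1 iff
    d(u,v) = n.  A vertex is never connected to itself (distance 0 excluded).
    """
    _require_vertices(g, (u, v))
    if mode not in ("at_most", "exact"):
        raise ValueError(f"unknown mode {mode!r}")
    if u == v:
        return 0
    reach = _bfs(g, u, n)
    if v not in reach:
        return 0
    d = reach[v][0]
    return int(d == n) if mode == "exact" else int(1 <= d <= n)


def path_num(g: ProteinGraph, u: str, v: str, n: int) -> int:
    """Number of distinct shortest paths of length exactly n between u and v.

    0 when d(u, v) != n (including adjacent pairs queried at n >= 2).
    """
    _require_vertices(g, (u, v))
    if u == v:
        return 0
    reach = _bfs(g, u, n)
    if v not in reach:
        return 0
    d, count = reach[v]
    return count if d == n else 0


def connect_ratio(
    g: ProteinGraph, v: str, C: set[str], n: int, mode: str = "at_most"
) -> float:
    """Fraction of complex members n-connected to v (v itself contributes 0)."""
    if not C:
        raise ValueError("complex must be non-empty")
    _require_vertices(g, [v])
    _require_vertices(g, C)
    reach = _bfs(g, v, n)
    total = 0
    for u in C:
        if u == v or u not in reach:
            continue
        d = reach[u][0]
        hit = (d == n) if mode == "exact" else (1 <= d <= n)
        total += int(hit)
    return total / len(C)


def path_ratio(g: ProteinGraph, v: str, C: set[str], n: int) -> float:
    """Mean number of exactly-n-length shortest paths from v to complex members."""
    if not C:
        raise ValueError("complex must be non-empty")
    _require_vertices(g, [v])
    _require_vertices(g, C)
    reach = _bfs(g, v, n)
    total = 0
    for u in C:
        if u == v or u not in reach:
            continue
        d, count = reach[u]
        if d == n:
            total += count
    return total / len(C)


def density(g: ProteinGraph, C: set[str], n: int, mode: str = "at_most") -> float:
    """Den(C, n): ordered-pair n-connection count over |C|^2.

    The diagonal contributes 0 (no self-connection) while the denominator
    keeps the printed |C|^2 form, so a clique's density tops out at
    (|C|^2 - |C|) / |C|^2, not 1.
    """
    if len(C) < 2:
        raise ValueError(f"density needs |C| >= 2, got {len(C)}")
    _require_vertices(g, C)
    total = 0
    for u in C:
        reach = _bfs(g, u, n)
        for v in C:
            if v == u or v not in reach:
                continue
            d = reach[v][0]
            hit = (d == n) if mode == "exact" else (1 <= d <= n)
            total += int(hit)
    return total / (len(C) ** 2)


def density_diff(
    g: ProteinGraph, v: str, C: set[str], n: int, mode: str = "at_most"
) -> float:
    """DenDiff(v, C, n) = Den(C ∪ {v}, n) - Den(C, n)."""
    if v in C:
        raise ValueError(f"{v!r} is already a member of the complex")
    return density(g, C | {v}, n, mode=mode) - density(g, C, n, mode=mode)


def eco_complex(C: set[str], model: CoexpressionModel) -> float:
    """E_co(C): sum of pairwise E_co over ordered distinct pairs, over |C|^2."""
    if not C:
        raise ValueError("complex must be non-empty")
    members = sorted(C)
    total = 0.0
    for i, u in enumerate(members):
        for v in members[i + 1 :]:
            total += 2.0 * model.eco(u, v)  # ordered pairs: (u,v) and (v,u)
    return total / (len(C) ** 2)


def eco_protein_complex(v: str, C: set[str], model: CoexpressionModel) -> float:
    """E_co(v, C): mean pairwise E_co of v against complex members."""
    if not C:
        raise ValueError("complex must be non-empty")
    return sum(model.eco(v, u) for u in C) / len(C)


def co_ratio(C: set[str], model: CoexpressionModel) -> float:
    """CoRatio(C): ordered-distinct-pair Co count over |C|^2."""
    if not C:
        raise ValueError("complex must be non-empty")
    members = sorted(C)
    total = 0
    for i, u in enumerate(members):
        for v in members[i + 1 :]:
            total += 2 * model.co(u, v)
    return total / (len(C) ** 2)


def co_diff(v: str, C: set[str], model: CoexpressionModel) -> float:
    """CoDiff(v, C) = E_co(C ∪ {v}) - E_co(C)."""
    if v in C:
        raise ValueError(f"{v!r} is already a member of the complex")
    return eco_complex(C | {v}, model) - eco_complex(C, model)


def co_pro_num(v: str, C: set[str], model: CoexpressionModel) -> int:
    """CoProNum(v, C): number of complex members co-expressed with v."""
    if not C:
        raise ValueError("complex must be non-empty")
    return sum(model.co(v, u) for u in C)


def co_pro_ratio(v: str, C: set[str], model: CoexpressionModel) -> float:
    """CoProRatio(v, C) = CoProNum(v, C) / |C|."""
    return co_pro_num(v, C, model) / len(C)


def feature_vector(
    g: ProteinGraph,
    v: str,
    C: set[str],
    model: CoexpressionModel,
    n: int = 2,
) -> np.ndarray:
    """The seven features of v against C, in the fixed order of FEATURE_NAMES.

    ``v`` must be outside ``C``: addition candidates are scored directly and
    deletion candidates are scored against C with the member stripped first.
    """
    if v in C:
        raise ValueError("strip v from C before scoring (deletion candidates)")
    if not C:
        raise ValueError("complex must be non-empty")
    return np.array(
        [
            connect_ratio(g, v, C, n),
            path_ratio(g, v, C, n),
            density_diff(g, v, C, n),
            eco_protein_complex(v, C, model),
            co_diff(v, C, model),
            float(co_pro_num(v, C, model)),
            co_pro_ratio(v, C, model),
        ]
    )
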