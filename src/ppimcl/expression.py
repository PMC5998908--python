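"""Gene-expression time courses and pairwise co-expression scores.

Expression values are per-protein time courses over m intervals (the yeast
metabolic-cycle data used for reference has m = 36).  Each row is
max-normalised, T'_i(l) = T_i(l) / max_l T_i(l), and the co-expression of two
proteins is the log-ratio similarity

    E_co(v_i, v_j) = sum_l ln[ (T'_i(l) + T'_j(l)) / |T'_i(l) - T'_j(l)| ],

which is large when the two profiles rise and fall together.  A pair is
called co-expressed (Co = 1) when its E_co exceeds the network-wide average
E_co(avg).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .graphio import ProteinGraph

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionParseError",
    "ExpressionMatrix",
    "NormalizedExpression",
    "load_expression",
    "normalize",
    "pairwise_eco",
    "average_eco",
    "co_indicator",
    "CoexpressionModel",
]

#: lower clamp on |T'_i - T'_j| (and the both-near-zero skip threshold)
DEFAULT_DELTA = 1e-3


class ExpressionParseError(ValueError):
    """Raised on a malformed expression file; the message names the line."""


@dataclass
class ExpressionMatrix:
    """Map protein ID -> vector of m non-negative expression values."""

    values: dict[str, np.ndarray]
    m: int

    def __contains__(self, protein: str) -> bool:
        return protein in self.values

    def __getitem__(self, protein: str) -> np.ndarray:
        return self.values[protein]

    def __len__(self) -> int:
        return len(self.values)

    @property
    def proteins(self) -> list[str]:
        return list(self.values)


@dataclass
class NormalizedExpression(ExpressionMatrix):
    """Max-normalised expression; every non-degenerate row has maximum 1."""


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def load_expression(path: str | Path) -> ExpressionMatrix:
    """Read an ``ID<TAB>v1<TAB>...<TAB>vm`` TSV of expression time courses.

    A header line is detected (and skipped) when its second field is not
    numeric.  Duplicate IDs keep the first occurrence with a logged warning.
    Lines starting with ``#`` are ignored.

    Raises
    ------
    ExpressionParseError
        On ragged rows or non-numeric values, naming the line number.
    ValueError
        On negative expression values.
    """
    values: dict[str, np.ndarray] = {}
    m: int | None = None
    first_data_line = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split("\t") if "\t" in line else line.split()
            if first_data_line and len(tokens) >= 2 and not _is_number(tokens[1]):
                first_data_line = False  # header
                continue
            first_data_line = False
            if len(tokens) < 2:
                raise ExpressionParseError(
                    f"{path}: line {lineno}: expected an ID and >= 1 value"
                )
            pid = tokens[0]
            try:
                row = np.array([float(t) for t in tokens[1:]], dtype=float)
            except ValueError as exc:
                raise ExpressionParseError(
                    f"{path}: line {lineno}: non-numeric expression value"
                ) from exc
            if m is None:
                m = row.size
            elif row.size != m:
                raise ExpressionParseError(
                    f"{path}: line {lineno}: expected {m} values, got {row.size}"
                )
            if np.any(row < 0):
                raise ValueError(
                    f"{path}: line {lineno}: negative expression value for {pid}"
                )
            if pid in values:
                logger.warning("duplicate expression row for %s: keeping the first", pid)
                continue
            values[pid] = row
    return ExpressionMatrix(values=values, m=m or 0)


def normalize(T: ExpressionMatrix) -> NormalizedExpression:
    """Divide each row by its maximum; an all-zero row stays all-zero."""
    out: dict[str, np.ndarray] = {}
    for pid, row in T.values.items():
        peak = row.max() if row.size else 0.0
        out[pid] = row / peak if peak > 0 else row.copy()
    return NormalizedExpression(values=out, m=T.m)


def pairwise_eco(a: np.ndarray, b: np.ndarray, delta: float = DEFAULT_DELTA) -> float:
    """Co-expression E_co of two max-normalised rows.

    Per time point the term is ln((a_l + b_l) / |a_l - b_l|).  Identical
    values make the denominator 0, so |a_l - b_l| is clamped below at
    ``delta`` (identical profiles score very high but finite).  Time points
    where a_l + b_l < delta carry no signal and ln(0/0) is undefined, so they
    are skipped.  Symmetric in its arguments.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    s = a + b
    d = np.maximum(np.abs(a - b), delta)
    mask = s >= delta
    if not mask.any():
        return 0.0
    return float(np.sum(np.log(s[mask] / d[mask])))


def average_eco(
    g: ProteinGraph,
    N: NormalizedExpression,
    scope: str = "all_pairs",
    delta: float = DEFAULT_DELTA,
) -> float:
    """Network-wide average co-expression E_co(avg).

    ``scope='all_pairs'`` (default) averages over every unordered pair of
    network proteins that both have expression rows; ``scope='edges'``
    restricts to interacting pairs (a cheaper proxy on large networks).
    Proteins without expression data are excluded.
    """
    if scope not in ("all_pairs", "edges"):
        raise ValueError(f"unknown scope {scope!r}")
    if scope == "edges":
        pairs = [
            tuple(e) for e in g.edges if all(p in N for p in e)
        ]
    else:
        with_data = [v for v in g.vertices if v in N]
        pairs = list(itertools.combinations(with_data, 2))
    if not pairs:
        raise ValueError("no protein pair with expression data on both ends")
    total = 0.0
    for u, v in pairs:
        total += pairwise_eco(N[u], N[v], delta=delta)
    return total / len(pairs)


def co_indicator(
    a: np.ndarray | None,
    b: np.ndarray | None,
    e_avg: float,
    delta: float = DEFAULT_DELTA,
) -> int:
    """Co(v_i, v_j): 1 iff E_co(v_i, v_j) strictly exceeds E_co(avg).

    A pair with a missing expression row scores 0 (absence of evidence is
    neutral-low).
    """
    if a is None or b is None:
        return 0
    return int(pairwise_eco(a, b, delta=delta) > e_avg)


@dataclass
class CoexpressionModel:
    """Bundles normalised expression, E_co(avg) and cached pairwise scores.

    The feature and refinement stages repeatedly ask for E_co and Co of the
    same pairs; this memoises them and fixes e_avg once per network.
    """

    N: NormalizedExpression
    e_avg: float
    delta: float = DEFAULT_DELTA
    _cache: dict[frozenset[str], float] = field(default_factory=dict, repr=False)

    @classmethod
    def build(
        cls,
        g: ProteinGraph,
        T: ExpressionMatrix,
        scope: str = "all_pairs",
        delta: float = DEFAULT_DELTA,
    ) -> "CoexpressionModel":
        N = normalize(T)
        e_avg = average_eco(g, N, scope=scope, delta=delta)
        return cls(N=N, e_avg=e_avg, delta=delta)

    @classmethod
    def disabled(cls) -> "CoexpressionModel":
        """Topology-only stand-in: every E_co and Co is 0.

        Used when no expression file is given; all co-expression features
        vanish and filtering effectively acts on density alone.
        """
        return cls(N=NormalizedExpression(values={}, m=0), e_avg=np.inf)

    def eco(self, u: str, v: str) -> float:
        """Pairwise E_co; 0 when u == v or either row is missing."""
        if u == v or u not in self.N or v not in self.N:
            return 0.0
        key = frozenset((u, v))
        val = self._cache.get(key)
        if val is None:
            val = pairwise_eco(self.N[u], self.N[v], delta=self.delta)
            self._cache[key] = val
        return val

    def co(self, u: str, v: str) -> int:
        """Co indicator; 0 for self pairs or missing rows."""
        if u == v or u not in self.N or v not in self.N:
            return 0
        return int(self.eco(u, v) > self.e_avg)
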