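"""Clustering-wise evaluation of predicted complexes against a benchmark.

Two complementary measurement families are implemented.  The overlap score

    O(C_p, C_b) = |C_p ∩ C_b|^2 / (|C_p| * |C_b|)

declares a prediction and a benchmark complex matched when O >= omega
(default 0.2); counting matched predictions (Ncp) and matched benchmark
complexes (Ncb) gives Precision = Ncp/|P|, Recall = Ncb/|B| and their
harmonic mean, the F-Measure.  The second family builds the intersection-size
matrix T_{i,j} = |B_i ∩ P_j| and reports clustering-wise sensitivity Sn,
positive predictive value PPV and the geometric accuracy Acc = sqrt(Sn*PPV).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "EvalReport",
    "overlap_score",
    "match_counts",
    "precision_recall_f",
    "sn_ppv_acc",
    "evaluate",
]


@dataclass(frozen=True)
class EvalReport:
    """All assessment numbers for one (predicted, benchmark) pair."""

    n_predicted: int
    n_benchmark: int
    ncp: int
    ncb: int
    sn: float
    ppv: float
    acc: float
    precision: float
    recall: float
    f_measure: float
    omega: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def format_table(self) -> str:
        """Aligned text table in the column order of the reference tables."""
        headers = ["|P|", "Ncp", "Ncb", "Sn", "PPV", "Acc", "Precision", "Recall", "F-Measure"]
        values = [
            str(self.n_predicted),
            str(self.ncp),
            str(self.ncb),
            f"{self.sn:.4f}",
            f"{self.ppv:.4f}",
            f"{self.acc:.4f}",
            f"{self.precision:.4f}",
            f"{self.recall:.4f}",
            f"{self.f_measure:.4f}",
        ]
        widths = [max(len(h), len(v)) for h, v in zip(headers, values)]
        head = "  ".join(h.rjust(w) for h, w in zip(headers, widths))
        body = "  ".join(v.rjust(w) for v, w in zip(values, widths))
        return head + "\n" + body


def overlap_score(Cp: set[str], Cb: set[str]) -> float:
    """O(C_p, C_b) in [0, 1]; 1 iff the sets are identical, 0 iff disjoint."""
    if not Cp or not Cb:
        raise ValueError("overlap_score requires two non-empty complexes")
    inter = len(Cp & Cb)
    return inter * inter / (len(Cp) * len(Cb))


def match_counts(
    P: list[set[str]], B: list[set[str]], omega: float = 0.2
) -> tuple[int, int]:
    """(Ncp, Ncb): predictions matching >= 1 benchmark complex at threshold
    omega, and benchmark complexes matched by >= 1 prediction."""
    if not 0.0 < omega <= 1.0:
        raise ValueError(f"omega must be in (0, 1], got {omega}")
    ncp = sum(1 for Cp in P if any(overlap_score(Cp, Cb) >= omega for Cb in B))
    ncb = sum(1 for Cb in B if any(overlap_score(Cp, Cb) >= omega for Cp in P))
    return ncp, ncb


def precision_recall_f(
    ncp: int, n_predicted: int, ncb: int, n_benchmark: int
) -> tuple[float, float, float]:
    """Precision = Ncp/|P|, Recall = Ncb/|B|, F = their harmonic mean.

    F is defined as 0 when Precision + Recall = 0.
    """
    if n_predicted <= 0 or n_benchmark <= 0:
        raise ValueError("both complex sets must be non-empty")
    precision = ncp / n_predicted
    recall = ncb / n_benchmark
    denom = precision + recall
    f = 2.0 * precision * recall / denom if denom > 0 else 0.0
    return precision, recall, f


def sn_ppv_acc(P: list[set[str]], B: list[set[str]]) -> tuple[float, float, float]:
    """Clustering-wise Sn, PPV and Acc from the intersection matrix T.

    T_{i,j} = |B_i ∩ P_j|; Sn = sum_i max_j T_{i,j} / sum_i |B_i|;
    PPV = sum_j max_i T_{i,j} / sum_{i,j} T_{i,j}; Acc = sqrt(Sn * PPV).
    A prediction with no overlap against any benchmark complex contributes 0
    to both the PPV numerator and denominator.  If T is all zero, PPV is
    defined as 0 (logged).
    """
    if not P or not B:
        raise ValueError("both complex sets must be non-empty")
    T = np.array([[len(Cb & Cp) for Cp in P] for Cb in B], dtype=float)
    sn_denom = sum(len(Cb) for Cb in B)
    sn = float(T.max(axis=1).sum() / sn_denom) if sn_denom else 0.0
    t_total = float(T.sum())
    if t_total == 0.0:
        logger.warning("no overlap between predictions and benchmark; PPV set to 0")
        ppv = 0.0
    else:
        ppv = float(T.max(axis=0).sum() / t_total)
    acc = math.sqrt(sn * ppv)
    return sn, ppv, acc


def evaluate(
    P: list[set[str]],
    B: list[set[str]],
    omega: float = 0.2,
    min_benchmark_size: int | None = None,
) -> EvalReport:
    """Full report for a (predicted, benchmark) pair.

    ``min_benchmark_size`` optionally restricts the benchmark to complexes of
    at least that size before scoring (the curated yeast catalogue is often
    used both complete and restricted to >= 3 members).
    """
    if min_benchmark_size is not None:
        B = [Cb for Cb in B if len(Cb) >= min_benchmark_size]
    if not P or not B:
        raise ValueError("both complex sets must be non-empty")
    ncp, ncb = match_counts(P, B, omega)
    precision, recall, f = precision_recall_f(ncp, len(P), ncb, len(B))
    sn, ppv, acc = sn_ppv_acc(P, B)
    return EvalReport(
        n_predicted=len(P),
        n_benchmark=len(B),
        ncp=ncp,
        ncb=ncb,
        sn=sn,
        ppv=ppv,
        acc=acc,
        precision=precision,
        recall=recall,
        f_measure=f,
        omega=omega,
    )
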