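"""Filtering and modification of candidate complexes.

Candidates coming out of Markov clustering are triaged on three complex-level
features, Vector(C) = (Den(C,2), E_co(C), CoRatio(C)), each with an (upper,
lower) bound pair: any feature below its lower bound discards the complex,
all features at or above their upper bounds reserves it, anything in between
sends it to modification.

Modification scores individual proteins against a complex with a logistic
function of the seven features of :mod:`ppimcl.features`,

    L(v, C) = sum_i w_i * Feature_i(v, C),     P(v, C) = 1 / (1 + e^{-L}),

deleting the worst member while its P (scored against the complex without
it) falls below the delete threshold and adding the best external neighbour
while its P exceeds the add threshold.  The shipped weights were fitted on
randomly grown complexes labelled by whether an edit improved the best
overlap with the benchmark catalogue; ``fit_weights`` re-fits them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .expression import CoexpressionModel
from .features import co_ratio, density, eco_complex, feature_vector
from .graphio import ProteinGraph

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_WEIGHTS",
    "FilterBounds",
    "RefineParams",
    "logistic_score",
    "classify_complex",
    "complex_vector",
    "modify_complex",
    "refine_all",
    "generate_training_samples",
    "fit_weights",
]

#: weights of the seven-feature linear score, in FEATURE_NAMES order
DEFAULT_WEIGHTS = (0.01, 0.02, 0.01, 0.24, 0.36, 0.03, 0.33)


@dataclass(frozen=True)
class FilterBounds:
    """(upper, lower) triage bounds per complex-level feature."""

    den: tuple[float, float] = (0.18, 0.06)
    eco: tuple[float, float] = (80.0, 50.0)
    co_ratio: tuple[float, float] = (0.75, 0.20)

    def __post_init__(self) -> None:
        for name in ("den", "eco", "co_ratio"):
            upper, lower = getattr(self, name)
            if lower > upper:
                raise ValueError(f"{name}: lower bound {lower} > upper bound {upper}")


@dataclass(frozen=True)
class RefineParams:
    """Parameters of the modification sweep.

    The add threshold defaults to the strict 0.8 setting (precision of adding
    is far higher there than at 0.5); the delete threshold is the logistic
    decision boundary 0.5.  Complexes that shrink below ``min_size`` are
    dropped.
    """

    weights: tuple[float, ...] = DEFAULT_WEIGHTS
    add_threshold: float = 0.8
    delete_threshold: float = 0.5
    max_passes: int = 10
    min_size: int = 3

    def __post_init__(self) -> None:
        if len(self.weights) != 7:
            raise ValueError(f"expected 7 weights, got {len(self.weights)}")
        if self.max_passes < 1:
            raise ValueError("max_passes must be >= 1")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")


def logistic_score(features: np.ndarray, weights: np.ndarray | tuple[float, ...]) -> float:
    """P(v, C) = 1 / (1 + exp(-w . f)); strictly inside (0, 1)."""
    f = np.asarray(features, dtype=float)
    w = np.asarray(weights, dtype=float)
    if f.shape != w.shape:
        raise ValueError(f"feature/weight length mismatch: {f.shape} vs {w.shape}")
    L = float(np.dot(w, f))
    return float(1.0 / (1.0 + np.exp(-L)))


def complex_vector(
    C: set[str], g: ProteinGraph, model: CoexpressionModel
) -> tuple[float, float, float]:
    """Vector(C) = (Den(C,2), E_co(C), CoRatio(C)) used for triage."""
    return (density(g, C, 2), eco_complex(C, model), co_ratio(C, model))


def classify_complex(
    C: set[str],
    g: ProteinGraph,
    model: CoexpressionModel,
    bounds: FilterBounds | None = None,
) -> str:
    """Triage a candidate: ``'reserve'``, ``'discard'`` or ``'modify'``.

    Any feature strictly below its lower bound discards the complex; all
    features at or above their upper bounds reserve it; otherwise it is sent
    to modification.
    """
    if bounds is None:
        bounds = FilterBounds()
    vec = complex_vector(C, g, model)
    pairs = list(zip(vec, (bounds.den, bounds.eco, bounds.co_ratio)))
    if any(value < lower for value, (_, lower) in pairs):
        return "discard"
    if all(value >= upper for value, (upper, _) in pairs):
        return "reserve"
    return "modify"


def _external_neighbors(g: ProteinGraph, C: set[str]) -> set[str]:
    out: set[str] = set()
    for u in C:
        out |= g.neighbors(u)
    return out - C


def modify_complex(
    C: set[str],
    g: ProteinGraph,
    model: CoexpressionModel,
    params: RefineParams | None = None,
) -> set[str] | None:
    """Iteratively delete weak members and add strong neighbours.

    Each pass first scores every member v by P(v, C \\ {v}) and removes the
    lowest scorer if its P is below the delete threshold, then scores every
    external neighbour by P(v, C) and adds the highest scorer if its P
    exceeds the add threshold; one change of each kind per pass, lowest /
    highest scorer first for determinism.  Stops at a fixed point or after
    ``max_passes``.  Returns None if the complex shrinks below ``min_size``.
    """
    if params is None:
        params = RefineParams()
    C = set(C)
    w = np.asarray(params.weights)
    for _ in range(params.max_passes):
        changed = False
        # deletion sweep: remove the worst member if it scores below threshold
        if len(C) > 2:  # density needs >= 2 remaining members
            scored = []
            for v in sorted(C):
                f = feature_vector(g, v, C - {v}, model)
                scored.append((logistic_score(f, w), v))
            p_min, v_min = min(scored)
            if p_min < params.delete_threshold:
                C.remove(v_min)
                changed = True
                if len(C) < params.min_size:
                    return None
        # addition sweep: add the best external neighbour if it clears threshold
        candidates = sorted(_external_neighbors(g, C))
        if candidates:
            scored = []
            for v in candidates:
                f = feature_vector(g, v, C, model)
                scored.append((logistic_score(f, w), v))
            p_max, v_max = max(scored)
            if p_max > params.add_threshold:
                C.add(v_max)
                changed = True
        if not changed:
            break
    return C if len(C) >= params.min_size else None


def refine_all(
    complexes: list[set[str]],
    g: ProteinGraph,
    model: CoexpressionModel,
    bounds: FilterBounds | None = None,
    params: RefineParams | None = None,
) -> tuple[list[set[str]], dict[str, int]]:
    """Triage and modify a whole candidate set.

    Complexes below ``min_size`` are discarded up front; reserved complexes
    pass through unchanged, discarded ones are dropped, the rest go through
    :func:`modify_complex`.  Exact duplicates in the output are collapsed
    (first occurrence kept).  Returns the surviving complexes and a count of
    reserve/discard/modify decisions.
    """
    if bounds is None:
        bounds = FilterBounds()
    if params is None:
        params = RefineParams()
    counts = {"reserved": 0, "discarded": 0, "modified": 0, "too_small": 0}
    out: list[set[str]] = []
    seen: set[frozenset[str]] = set()

    def emit(C: set[str]) -> None:
        key = frozenset(C)
        if key not in seen:
            seen.add(key)
            out.append(C)

    for C in complexes:
        if len(C) < params.min_size:
            counts["too_small"] += 1
            continue
        verdict = classify_complex(C, g, model, bounds)
        if verdict == "discard":
            counts["discarded"] += 1
        elif verdict == "reserve":
            counts["reserved"] += 1
            emit(set(C))
        else:
            counts["modified"] += 1
            refined = modify_complex(C, g, model, params)
            if refined is not None:
                emit(refined)
    return out, counts


def _best_overlap(C: set[str], benchmark: list[set[str]]) -> float:
    from .evaluate import overlap_score

    if not C:
        return 0.0
    return max((overlap_score(C, b) for b in benchmark), default=0.0)


def generate_training_samples(
    g: ProteinGraph,
    model: CoexpressionModel,
    benchmark: list[set[str]],
    n_complexes: int = 100,
    size_range: tuple[int, int] = (3, 10),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Random add/delete candidates labelled by benchmark overlap improvement.

    Random connected complexes are grown from a random start vertex by
    repeated random neighbour addition, with size uniform in ``size_range``.
    Every external-neighbour addition and every member deletion is a sample:
    the label is positive iff the edit strictly increases the complex's best
    overlap score against the benchmark.  Fully deterministic under ``seed``.

    Returns (features, labels): an (n, 7) array and an (n,) 0/1 array.
    """
    if not benchmark:
        raise ValueError("benchmark must be non-empty (it defines the labels)")
    rng = np.random.default_rng(seed)
    vertices = [v for v in g.vertices if g.degree(v) > 0]
    X: list[np.ndarray] = []
    y: list[int] = []
    for _ in range(n_complexes):
        target = int(rng.integers(size_range[0], size_range[1] + 1))
        start = vertices[int(rng.integers(len(vertices)))]
        C = {start}
        while len(C) < target:
            frontier = sorted(_external_neighbors(g, C))
            if not frontier:
                break
            C.add(frontier[int(rng.integers(len(frontier)))])
        if len(C) < max(3, size_range[0]):
            continue
        base = _best_overlap(C, benchmark)
        for v in sorted(_external_neighbors(g, C)):
            X.append(feature_vector(g, v, C, model))
            y.append(int(_best_overlap(C | {v}, benchmark) > base))
        for v in sorted(C):
            X.append(feature_vector(g, v, C - {v}, model))
            y.append(int(_best_overlap(C - {v}, benchmark) > base))
    return np.array(X), np.array(y, dtype=int)


def fit_weights(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Maximum-likelihood logistic weights over the 7 raw features.

    The intercept is fixed at 0 to match the form of L(v, C).  Raises on
    single-class input.
    """
    from sklearn.linear_model import LogisticRegression

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit weights")
    clf = LogisticRegression(fit_intercept=False, C=np.inf, max_iter=1000)
    clf.fit(X, y)
    return clf.coef_.ravel()
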