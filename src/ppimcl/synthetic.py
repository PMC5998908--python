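"""Synthetic PPI networks with planted complexes and matching expression.

The generator emulates the two data modalities the pipeline consumes: a
planted-partition graph (each planted complex is an Erdős–Rényi block at
p_in, every other vertex pair is wired at p_out) and per-protein expression
time courses in which members of one complex share a noisy copy of a common
periodic latent signal — mimicking the co-expression of complex subunits
across the yeast metabolic cycle — while background proteins emit
independent noise.  Seeded runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expression import ExpressionMatrix
from .graphio import ProteinGraph

__all__ = ["SyntheticSpec", "simulate_network", "simulate_expression", "simulate_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of the synthetic benchmark.

    Defaults: 8 planted complexes of 4–10 proteins with intra-complex edge
    probability 0.85, 60 background proteins, background/inter edge
    probability 0.01, 36 expression intervals with a 3-period sinusoidal
    latent signal, per-protein amplitude uniform in [0.5, 1.5] and Gaussian
    noise of std 0.1.
    """

    n_complexes: int = 8
    size_range: tuple[int, int] = (4, 10)
    p_in: float = 0.85
    n_background: int = 60
    p_out: float = 0.01
    m: int = 36
    n_periods: int = 3
    amplitude_range: tuple[float, float] = (0.5, 1.5)
    noise_std: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError(f"need 0 <= p_out < p_in <= 1, got {self.p_out}, {self.p_in}")
        if self.m < 2:
            raise ValueError(f"need m >= 2 intervals, got {self.m}")
        if self.n_complexes < 1:
            raise ValueError("need at least one planted complex")
        if self.size_range[0] < 2 or self.size_range[1] < self.size_range[0]:
            raise ValueError(f"bad size range {self.size_range}")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")


def _protein_ids(spec: SyntheticSpec, rng: np.random.Generator) -> tuple[list[str], list[set[str]]]:
    sizes = rng.integers(spec.size_range[0], spec.size_range[1] + 1, size=spec.n_complexes)
    ids: list[str] = []
    truth: list[set[str]] = []
    k = 0
    for size in sizes:
        members = [f"P{k + i:04d}" for i in range(int(size))]
        k += int(size)
        ids.extend(members)
        truth.append(set(members))
    ids.extend(f"P{k + i:04d}" for i in range(spec.n_background))
    return ids, truth


def simulate_network(spec: SyntheticSpec) -> tuple[ProteinGraph, list[set[str]]]:
    """Planted-partition PPI network and its ground-truth complexes.

    Within-complex vertex pairs get an edge with probability p_in; every
    other pair (background–background, background–complex, cross-complex)
    with probability p_out.  All vertices are present in the returned graph
    even when isolated.
    """
    rng = np.random.default_rng(spec.seed)
    ids, truth = _protein_ids(spec, rng)
    membership = {}
    for ci, members in enumerate(truth):
        for v in members:
            membership[v] = ci
    g = ProteinGraph()
    for v in ids:
        g.add_vertex(v)
    n = len(ids)
    for i in range(n):
        u = ids[i]
        for j in range(i + 1, n):
            v = ids[j]
            same = membership.get(u) is not None and membership.get(u) == membership.get(v)
            p = spec.p_in if same else spec.p_out
            if rng.random() < p:
                g.add_edge(u, v)
    return g, truth


def simulate_expression(
    truth: list[set[str]],
    all_proteins: list[str],
    spec: SyntheticSpec,
) -> ExpressionMatrix:
    """Expression time courses matching the planted complex structure.

    Each complex draws one latent periodic course, 1 + sin(2*pi*n_periods*
    l/m + phase) with a random phase; members emit amplitude-scaled copies
    plus independent Gaussian noise.  Background proteins emit independent
    uniform noise on the same value range.  All values are clipped at 0 to
    keep expression non-negative.
    """
    # separate stream from the network so graph and expression noise are
    # independent but jointly reproducible
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    t = np.arange(spec.m)
    in_complex: dict[str, np.ndarray] = {}
    for members in truth:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        latent = 1.0 + np.sin(2.0 * np.pi * spec.n_periods * t / spec.m + phase)
        for v in sorted(members):
            in_complex[v] = latent
    lo, hi = spec.amplitude_range
    values: dict[str, np.ndarray] = {}
    for v in all_proteins:
        latent = in_complex.get(v)
        if latent is not None:
            amp = rng.uniform(lo, hi)
            row = amp * latent + rng.normal(0.0, spec.noise_std, size=spec.m)
        else:
            row = rng.uniform(0.0, 2.0, size=spec.m)
        values[v] = np.clip(row, 0.0, None)
    return ExpressionMatrix(values=values, m=spec.m)


def simulate_dataset(
    spec: SyntheticSpec,
) -> tuple[ProteinGraph, list[set[str]], ExpressionMatrix]:
    """Convenience: network, ground-truth complexes and expression together."""
    g, truth = simulate_network(spec)
    expr = simulate_expression(truth, g.vertices, spec)
    return g, truth, expr
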