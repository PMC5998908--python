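"""End-to-end orchestration: load -> weight -> MCL -> refine -> evaluate.

`run_pipeline` drives the whole detection chain from a `PipelineConfig`,
writes every intermediate artifact plus a JSON manifest with all parameters
and counts, and returns the final complexes (and an evaluation report when a
benchmark is given).  Reruns with the same config are byte-identical: no
stage uses randomness.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .evaluate import EvalReport, evaluate
from .expression import CoexpressionModel, load_expression
from .graphio import (
    ProteinGraph,
    build_adjacency,
    build_flow_matrix,
    load_network,
    read_complexes,
    write_complexes,
)
from .mcl import MclParams, extract_clusters, run_mcl
from .refine import FilterBounds, RefineParams, refine_all

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every knob of the detection chain, with the stock defaults.

    ``expression_path=None`` with ``allow_no_expression=True`` runs
    topology-only: all co-expression features are 0 and filtering acts on
    density alone (logged loudly).
    """

    network_path: str | None = None
    expression_path: str | None = None
    benchmark_path: str | None = None
    output_dir: str = "ppimcl_out"
    # edge weighting
    floor: float = 0.01
    # MCL
    r: float = 2.0
    w: float = 1.0
    tol: float = 1e-6
    max_iter: int = 100
    # filtering bounds (upper, lower)
    den_bounds: tuple[float, float] = (0.18, 0.06)
    eco_bounds: tuple[float, float] = (80.0, 50.0)
    co_ratio_bounds: tuple[float, float] = (0.75, 0.20)
    # modification
    weights: tuple[float, ...] = (0.01, 0.02, 0.01, 0.24, 0.36, 0.03, 0.33)
    add_threshold: float = 0.8
    delete_threshold: float = 0.5
    max_passes: int = 10
    min_size: int = 3
    # co-expression
    eco_scope: str = "all_pairs"
    allow_no_expression: bool = False
    # evaluation
    omega: float = 0.2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("den_bounds", "eco_bounds", "co_ratio_bounds", "weights"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def mcl_params(self) -> MclParams:
        return MclParams(r=self.r, w=self.w, tol=self.tol, max_iter=self.max_iter)

    def filter_bounds(self) -> FilterBounds:
        return FilterBounds(
            den=self.den_bounds, eco=self.eco_bounds, co_ratio=self.co_ratio_bounds
        )

    def refine_params(self) -> RefineParams:
        return RefineParams(
            weights=self.weights,
            add_threshold=self.add_threshold,
            delete_threshold=self.delete_threshold,
            max_passes=self.max_passes,
            min_size=self.min_size,
        )


@dataclass
class PipelineResult:
    clusters: list[set[str]]
    refined: list[set[str]]
    report: EvalReport | None
    counts: dict[str, int]
    iterations: int
    artifacts: dict[str, str] = field(default_factory=dict)


def _detect(
    g: ProteinGraph, model: CoexpressionModel, cfg: PipelineConfig
) -> tuple[list[set[str]], list[set[str]], dict[str, int], int]:
    A = build_adjacency(g, floor=cfg.floor)
    M0 = build_flow_matrix(A)
    M, iterations = run_mcl(M0, cfg.mcl_params())
    partition = extract_clusters(M, g.vertices)
    clusters = partition.clusters
    refined, counts = refine_all(
        clusters, g, model, cfg.filter_bounds(), cfg.refine_params()
    )
    return clusters, refined, counts, iterations


def detect_complexes(
    g: ProteinGraph, model: CoexpressionModel, cfg: PipelineConfig | None = None
) -> PipelineResult:
    """In-memory detection chain on an already-loaded graph and model."""
    cfg = cfg or PipelineConfig()
    clusters, refined, counts, iterations = _detect(g, model, cfg)
    return PipelineResult(
        clusters=clusters, refined=refined, report=None, counts=counts,
        iterations=iterations,
    )


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """File-driven run: read inputs, detect, write artifacts + manifest.

    Raises with the failing stage named in the message; a missing expression
    file is an error unless ``allow_no_expression`` is set.
    """
    if cfg.network_path is None:
        raise ValueError("stage load: network_path is required")
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        g = load_network(cfg.network_path)
    except OSError as exc:
        raise RuntimeError(f"stage load: cannot read network {cfg.network_path}") from exc

    if cfg.expression_path is not None:
        try:
            T = load_expression(cfg.expression_path)
        except OSError as exc:
            raise RuntimeError(
                f"stage expression: cannot read {cfg.expression_path}"
            ) from exc
        model = CoexpressionModel.build(g, T, scope=cfg.eco_scope)
    elif cfg.allow_no_expression:
        logger.warning(
            "no expression file: running TOPOLOGY-ONLY — all co-expression "
            "features are 0 and filtering acts on Den(C,2) alone"
        )
        model = CoexpressionModel.disabled()
    else:
        raise RuntimeError(
            "stage expression: expression_path is required (set "
            "allow_no_expression to run topology-only)"
        )

    clusters, refined, counts, iterations = _detect(g, model, cfg)

    artifacts: dict[str, str] = {}
    clusters_path = out / "clusters.txt"
    refined_path = out / "complexes.txt"
    write_complexes(clusters, clusters_path)
    write_complexes(refined, refined_path)
    artifacts["clusters"] = str(clusters_path)
    artifacts["complexes"] = str(refined_path)

    report: EvalReport | None = None
    if cfg.benchmark_path is not None:
        try:
            benchmark = read_complexes(cfg.benchmark_path)
        except OSError as exc:
            raise RuntimeError(
                f"stage evaluate: cannot read benchmark {cfg.benchmark_path}"
            ) from exc
        report = evaluate(refined, benchmark, omega=cfg.omega)
        report_path = out / "report.json"
        report_path.write_text(report.to_json(indent=2) + "\n")
        artifacts["report"] = str(report_path)

    manifest = {
        "ppimcl_version": __version__,
        "config": asdict(cfg),
        "n_vertices": g.n_vertices,
        "n_edges": g.n_edges,
        "mcl_iterations": iterations,
        "n_clusters": len(clusters),
        "n_complexes": len(refined),
        "refine_counts": counts,
        "artifacts": artifacts,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=list) + "\n")
    artifacts["manifest"] = str(manifest_path)

    return PipelineResult(
        clusters=clusters,
        refined=refined,
        report=report,
        counts=counts,
        iterations=iterations,
        artifacts=artifacts,
    )
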