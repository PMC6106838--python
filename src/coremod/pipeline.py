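"""End-to-end orchestration: detection and evaluation runs.

``detect`` is the library entry point (network in, predictions out);
``run_detection`` / ``run_evaluation`` add file I/O and logging around it for
the command-line interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .evaluation import MATCH_THRESHOLD, ComplexCatalog, EvaluationReport, evaluate
from .expansion import ModularityParams, generate_candidates
from .network import WeightedNetwork, load_network
from .postprocess import PredictionSet, merge_and_filter, write_complexes
from .seeding import classify

log = logging.getLogger("coremod")

__all__ = ["RunConfig", "detect", "run_detection", "run_evaluation"]


@dataclass(frozen=True)
class RunConfig:
    """Settings for a detection run; defaults are the recommended values."""

    network_path: str
    out_path: str
    delta: float | None = None  # None = auto (|E|/|V|)
    alpha: float = 1.0
    omega: float = 1.0
    min_size: int = 3
    match_threshold: float = MATCH_THRESHOLD
    fallback_next_best: bool = False
    default_weight: float = 1.0


def detect(
    net: WeightedNetwork,
    *,
    delta: float | None = None,
    alpha: float = 1.0,
    omega: float = 1.0,
    min_size: int = 3,
    fallback_next_best: bool = False,
) -> PredictionSet:
    """Run the full detection pipeline on an in-memory network.

    Stages: classify overlapping/seed nodes, grow one candidate cluster per
    seed under the local-modularity fitness, then merge/deduplicate at ω and
    drop complexes smaller than *min_size*.
    """
    params = (
        ModularityParams.for_network(net, alpha=alpha)
        if delta is None
        else ModularityParams(delta=delta, alpha=alpha)
    )
    classification = classify(net)
    log.info(
        "network: %d nodes, %d edges; overlapping: %d; seeds: %d; delta=%.4f",
        net.num_nodes,
        net.num_edges,
        len(classification.overlapping),
        len(classification.seeds),
        params.delta,
    )
    candidates = generate_candidates(
        net, classification.seeds, params, fallback_next_best=fallback_next_best
    )
    log.info("candidate clusters: %d", len(candidates))
    predictions = merge_and_filter(
        [c.members for c in candidates], omega=omega, min_size=min_size
    )
    log.info("final complexes: %d", len(predictions))
    return predictions


def run_detection(config: RunConfig) -> PredictionSet:
    """File-level detection: load the network, detect, write predictions."""
    net = load_network(config.network_path, default_weight=config.default_weight)
    predictions = detect(
        net,
        delta=config.delta,
        alpha=config.alpha,
        omega=config.omega,
        min_size=config.min_size,
        fallback_next_best=config.fallback_next_best,
    )
    if len(predictions) == 0:
        log.warning("no complexes of size >= %d predicted", config.min_size)
    write_complexes(predictions.complexes, config.out_path)
    return predictions


def run_evaluation(
    pred_path: str | Path,
    ref_path: str | Path,
    match_threshold: float = MATCH_THRESHOLD,
    named_ref: bool = False,
) -> EvaluationReport:
    """Score a prediction file against a reference catalog file."""
    ref = ComplexCatalog.load_reference(ref_path, named=named_ref)
    pred = ComplexCatalog.from_file(pred_path)
    return evaluate(ref, pred, match_threshold=match_threshold)
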