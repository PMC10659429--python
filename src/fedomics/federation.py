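"""Synchronous cross-silo federated training simulation.

One aggregation round: every client warm-starts from the current global
model, runs its local fit (with the FedProx proximal anchor when
``mu > 0``), the server aggregates the locals — unweighted element-wise
mean for gradient learners, tree pooling ("federated bagging") for
ensembles — and the aggregated global model is evaluated on a validation
set.  After ``R`` rounds the round whose global model maximized the
selection metric (ties to the earlier round) provides the final model.

The simulation is in-process and sequential; rounds are synchronous and
failure-free.  Wall-clock seconds per phase are recorded in the round log
so runtime accounting can be reported (never asserted — it is
hardware-bound).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .cohort import FeatureMatrix
from .learners import (
    GRADIENT_KINDS,
    LearnerConfig,
    ModelWeights,
    init_weights,
    local_fit,
    predict_scores,
    training_loss,
)
from .metrics import MetricReport, compute_report
from .partition import ClientPartition, validate_partition

__all__ = [
    "FederationConfig",
    "RoundLog",
    "FederationResult",
    "aggregate_mean",
    "aggregate_ensembles",
    "run_federation",
]


@dataclass(frozen=True)
class FederationConfig:
    """Definition of one federated training experiment."""

    n_clients: int
    strategy: str = "fedavg"  # {fedavg, fedprox}
    mu: float = 0.0
    rounds: int = 5
    learner: LearnerConfig = field(default_factory=lambda: LearnerConfig("logreg"))
    selection_metric: str = "auc_pr"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.strategy not in ("fedavg", "fedprox"):
            raise ValueError(f"unknown federation strategy {self.strategy!r}")
        if self.strategy == "fedavg" and self.mu != 0.0:
            raise ValueError("fedavg requires mu = 0 (use fedprox for mu > 0)")
        if self.strategy == "fedprox" and self.learner.kind not in GRADIENT_KINDS:
            raise ValueError(
                "fedprox is defined for gradient learners only "
                f"(got {self.learner.kind!r})"
            )
        if self.n_clients < 1:
            raise ValueError("n_clients must be >= 1")


@dataclass
class RoundLog:
    """Per-round trace: client losses, validation metrics, phase timings."""

    round_index: int  # 1-based
    client_losses: list[float]
    validation: MetricReport
    global_weights: ModelWeights
    fit_seconds: float
    aggregate_seconds: float
    evaluate_seconds: float


@dataclass
class FederationResult:
    best_weights: ModelWeights
    best_round: int  # 1-based
    final_weights: ModelWeights
    rounds: list[RoundLog]


def aggregate_mean(weights_list: list[ModelWeights]) -> ModelWeights:
    """Unweighted element-wise mean of gradient-learner weight vectors."""
    if not weights_list:
        raise ValueError("cannot aggregate an empty list of weights")
    head = weights_list[0]
    if head.learner_kind not in GRADIENT_KINDS:
        raise ValueError("aggregate_mean applies to gradient learners only")
    for w in weights_list[1:]:
        if not head.same_layout(w):
            raise ValueError("all weights must share learner kind and layout")
    stacked = np.stack([w.flat for w in weights_list])
    return head.with_flat(stacked.mean(axis=0))


def aggregate_ensembles(ensembles: list[ModelWeights]) -> ModelWeights:
    """Pool all clients' trees into one ensemble (federated bagging).

    The pooled prediction is the mean over all trees; tree order is
    deterministic (client index, then local tree index).
    """
    if not ensembles:
        raise ValueError("cannot aggregate an empty list of ensembles")
    head = ensembles[0]
    for w in ensembles:
        if w.learner_kind != "tree_ensemble":
            raise ValueError("aggregate_ensembles applies to tree ensembles only")
        if w.n_features != head.n_features:
            raise ValueError("all ensembles must share n_features")
    pooled = tuple(t for w in ensembles for t in w.trees)
    return ModelWeights("tree_ensemble", head.n_features, trees=pooled)


def _aggregate(weights_list: list[ModelWeights]) -> ModelWeights:
    if weights_list[0].learner_kind == "tree_ensemble":
        return aggregate_ensembles(weights_list)
    return aggregate_mean(weights_list)


def run_federation(
    train: FeatureMatrix,
    partition: ClientPartition,
    val: FeatureMatrix,
    config: FederationConfig,
) -> FederationResult:
    """Simulate ``config.rounds`` synchronous aggregation rounds.

    ``train`` holds all clients' samples; ``partition`` assigns them to
    silos.  Every round each client local-fits from the current global
    model (which is also the FedProx anchor), the server aggregates, and
    the global model is scored on ``val``.  Returns the best global model
    by ``selection_metric`` (ties to the earlier round), the final-round
    model, and the full round log.
    """
    report = validate_partition(partition, train)
    if report:
        raise ValueError("invalid client partition: " + "; ".join(report))
    if val.n_samples == 0 or val.n_cases == 0 or val.n_controls == 0:
        raise ValueError("validation set needs at least one case and one control")

    silos = [train.subset_by_ids(list(ids)) for ids in partition.members]
    global_weights = init_weights(config.learner, train.n_features, config.seed)
    mu = config.mu if config.strategy == "fedprox" else 0.0

    logs: list[RoundLog] = []
    for r in range(1, config.rounds + 1):
        t0 = time.perf_counter()
        locals_: list[ModelWeights] = []
        losses: list[float] = []
        for ci, silo in enumerate(silos):
            fit_seed = int(
                np.random.SeedSequence([config.seed, r, ci]).generate_state(1)[0]
                % (2**31 - 1)
            )
            w = local_fit(
                config.learner,
                silo,
                start=global_weights,
                mu=mu,
                anchor=global_weights,
                seed=fit_seed,
            )
            locals_.append(w)
            if config.learner.kind in GRADIENT_KINDS:
                losses.append(
                    training_loss(
                        config.learner,
                        w,
                        silo.values,
                        silo.labels.astype(float),
                        mu,
                        global_weights,
                    )
                )
            else:
                losses.append(float("nan"))
        t1 = time.perf_counter()
        global_weights = _aggregate(locals_)
        t2 = time.perf_counter()
        scores = predict_scores(global_weights, val)
        report_val = compute_report(val.labels, scores)
        t3 = time.perf_counter()
        logs.append(
            RoundLog(
                round_index=r,
                client_losses=losses,
                validation=report_val,
                global_weights=global_weights,
                fit_seconds=t1 - t0,
                aggregate_seconds=t2 - t1,
                evaluate_seconds=t3 - t2,
            )
        )

    metric_values = [getattr(log.validation, config.selection_metric) for log in logs]
    best_round = int(np.argmax(metric_values)) + 1  # argmax ties -> earliest
    return FederationResult(
        best_weights=logs[best_round - 1].global_weights,
        best_round=best_round,
        final_weights=logs[-1].global_weights,
        rounds=logs,
    )
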