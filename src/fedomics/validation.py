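"""Fast self-check suites runnable without the full test harness.

Each suite exercises a core invariant of the pipeline — aggregation
algebra, metric oracles, partition validity, the single-client federation
reduction — and reports pass/fail with its runtime.  The CLI exposes them
via ``fedomics validate``.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .cohort import CohortSpec, generate_cohort
from .federation import FederationConfig, aggregate_mean, run_federation
from .learners import LearnerConfig, init_weights, local_fit
from .metrics import auc_pr, log_loss, roc_auc, threshold_metrics
from .partition import split_clients, validate_partition

__all__ = ["SuiteResult", "run_all_suites"]


@dataclass
class SuiteResult:
    name: str
    passed: bool
    detail: str
    seconds: float


def _suite_aggregation(rng: np.random.Generator) -> str:
    cfg = LearnerConfig("logreg")
    for _ in range(200):
        n_feat = int(rng.integers(1, 20))
        k = int(rng.integers(1, 6))
        ws = []
        base = init_weights(cfg, n_feat, 0)
        for _ in range(k):
            ws.append(base.with_flat(rng.normal(size=n_feat + 1)))
        mean = aggregate_mean(ws)
        expect = np.mean([w.flat for w in ws], axis=0)
        assert np.allclose(mean.flat, expect, atol=1e-12), "mean mismatch"
        perm = [ws[i] for i in rng.permutation(k)]
        assert np.abs(aggregate_mean(perm).flat - mean.flat).max() < 1e-12, (
            "permutation variance"
        )
        fixed = aggregate_mean([ws[0]] * k)
        assert np.allclose(fixed.flat, ws[0].flat, atol=1e-15), "fixed point"
    return "200 random weight sets: mean, fixed point, permutation invariance"


def _suite_metrics(rng: np.random.Generator) -> str:
    for _ in range(200):
        n = int(rng.integers(4, 40))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = rng.choice(np.linspace(0.05, 0.95, 7), size=n)
        # pairwise ROC oracle
        pos, neg = scores[labels == 1], scores[labels == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert abs(roc_auc(labels, scores) - wins / (len(pos) * len(neg))) < 1e-12
        assert 0.0 <= auc_pr(labels, scores) <= 1.0
        tm = threshold_metrics(labels, scores, 0.5)
        assert all(np.isfinite(v) for v in tm.values())
        assert log_loss(labels, scores) >= 0.0
    return "200 random instances vs pair-counting oracle + range checks"


def _suite_partitions(rng: np.random.Generator) -> str:
    spec = CohortSpec(n_cases=40, n_controls=80, n_snp=5, n_expr=5, n_clin=2, seed=7)
    fm, _ = generate_cohort(spec)
    checked = 0
    for strategy in ("uniform_stratified", "uniform_random", "linear_random"):
        for n in (1, 2, 3, 5):
            try:
                part = split_clients(fm, n, strategy, int(rng.integers(1 << 30)))
            except Exception:
                continue
            assert validate_partition(part, fm) == []
            assert sum(part.sizes) == fm.n_samples
            checked += 1
    assert checked >= 8, "too few feasible partitions checked"
    return f"{checked} partitions: disjoint, covering, class-present"


def _suite_single_client_reduction(rng: np.random.Generator) -> str:
    spec = CohortSpec(n_cases=30, n_controls=60, n_snp=8, n_expr=10, n_clin=2, seed=11)
    fm, _ = generate_cohort(spec)
    learner = LearnerConfig("logreg", local_epochs=5)
    part = split_clients(fm, 1, "uniform_stratified", 0)
    fed = FederationConfig(n_clients=1, rounds=3, learner=learner, seed=3)
    res = run_federation(fm, part, fm, fed)
    central = init_weights(learner, fm.n_features, 3)
    for _ in range(3):
        central = local_fit(learner, fm, central)
    assert np.allclose(res.final_weights.flat, central.flat, atol=1e-10)
    return "N=1 federation == central training to 1e-10"


def run_all_suites(seed: int = 0, broken_mean_hook: bool = False) -> list[SuiteResult]:
    """Run every invariant suite; ``broken_mean_hook`` deliberately breaks
    the aggregation suite (test hook for the failure path)."""
    suites = [
        ("aggregation_algebra", _suite_aggregation),
        ("metric_oracles", _suite_metrics),
        ("partition_invariants", _suite_partitions),
        ("single_client_reduction", _suite_single_client_reduction),
    ]
    results = []
    for name, fn in suites:
        rng = np.random.default_rng(seed)
        t0 = time.perf_counter()
        try:
            if broken_mean_hook and name == "aggregation_algebra":
                raise AssertionError("injected broken mean (test hook)")
            detail = fn(rng)
            results.append(
                SuiteResult(name, True, detail, time.perf_counter() - t0)
            )
        except AssertionError as exc:
            results.append(
                SuiteResult(name, False, str(exc), time.perf_counter() - t0)
            )
    return results
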