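"""Cross-validation folds, train/validation splits, and client silo
assignment for the simulated cross-silo federation.

Three named split strategies distribute the training samples over N
disjoint client silos:

``uniform_stratified``
    label and size homogeneity — per-class shuffle, equal per-class quota
    per client, surplus to the last client.
``uniform_random``
    size homogeneity but label heterogeneity — global shuffle, ``C // N``
    samples per client, surplus to the last client.
``linear_random``
    label and size heterogeneity — client ``i`` (1-based) receives
    ``i * c`` samples with ``c = C // (N * (N + 1) / 2)``, surplus to the
    last client, so silo sizes grow linearly and sum to ``C``.

Every produced partition is validated: silos must be pairwise disjoint,
cover the input exactly, and contain at least one case and one control
each (the minimum for a local learner to train at all).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import FeatureMatrix

__all__ = [
    "FoldAssignment",
    "ClientPartition",
    "PartitionError",
    "STRATEGIES",
    "stratified_kfold",
    "stratified_train_val_split",
    "split_clients",
    "validate_partition",
]

STRATEGIES = ("uniform_stratified", "uniform_random", "linear_random")


class PartitionError(ValueError):
    """Raised when a requested split is infeasible or fails validation."""


@dataclass(frozen=True)
class FoldAssignment:
    """K-fold assignment, stratified by class within ±1 sample."""

    K: int
    fold_of_sample: np.ndarray  # fold index per sample, aligned with the matrix
    seed: int

    def fold_indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_sample == k)

    def holdout_split(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """(train indices, holdout indices) for fold ``k``."""
        return (
            np.flatnonzero(self.fold_of_sample != k),
            np.flatnonzero(self.fold_of_sample == k),
        )

    def write_tsv(self, path, sample_ids) -> None:
        pd.DataFrame({"sample_id": list(sample_ids), "fold": self.fold_of_sample}).to_csv(
            Path(path), sep="\t", index=False
        )


@dataclass(frozen=True)
class ClientPartition:
    """Assignment of training samples to N disjoint client silos."""

    N: int
    strategy: str
    members: tuple[tuple[str, ...], ...]  # per-client sample-id tuples
    seed: int

    @property
    def sizes(self) -> list[int]:
        return [len(m) for m in self.members]

    def write_tsv(self, path) -> None:
        rows = [
            {"sample_id": sid, "client": i}
            for i, silo in enumerate(self.members)
            for sid in silo
        ]
        pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)


def stratified_kfold(matrix: FeatureMatrix, K: int, seed: int) -> FoldAssignment:
    """Class-stratified K folds with balanced totals.

    Each class is shuffled and split into quotas of ``n_c // K`` per fold;
    the per-class remainder goes, one sample each, to the folds with the
    smallest running totals (ties to the lowest fold index).  This keeps the
    per-class fold counts within ±1 *and* the overall fold sizes within ±1.
    """
    if K < 2:
        raise PartitionError("K must be >= 2")
    labels = matrix.labels
    rng = np.random.default_rng(seed)
    fold_of = np.full(matrix.n_samples, -1, dtype=np.int64)
    totals = np.zeros(K, dtype=np.int64)
    for cls in (1, 0):  # cases first: the smaller class anchors balancing
        idx = np.flatnonzero(labels == cls)
        if len(idx) < K:
            raise PartitionError(
                f"class {cls} has {len(idx)} samples, fewer than K={K} folds"
            )
        idx = rng.permutation(idx)
        base, rem = divmod(len(idx), K)
        counts = np.full(K, base, dtype=np.int64)
        # remainder to currently smallest folds, lowest index first on ties
        order = np.lexsort((np.arange(K), totals))
        counts[order[:rem]] += 1
        pos = 0
        for k in range(K):
            fold_of[idx[pos : pos + counts[k]]] = k
            pos += counts[k]
        totals += counts
    return FoldAssignment(K=K, fold_of_sample=fold_of, seed=seed)


def stratified_train_val_split(
    matrix: FeatureMatrix, ratio: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class split into train/validation at ``ratio`` train fraction.

    Validation receives ``floor(n_c * (1 - ratio))`` samples per class, the
    remainder trains.  Returns (train ids, validation ids).
    """
    if not (0.0 < ratio < 1.0):
        raise PartitionError("ratio must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    val_idx: list[np.ndarray] = []
    for cls in (1, 0):
        idx = rng.permutation(np.flatnonzero(matrix.labels == cls))
        n_val = int(np.floor(len(idx) * (1.0 - ratio) + 1e-9))
        if n_val == 0 or n_val == len(idx):
            raise PartitionError(
                f"class {cls} would be empty on one side of the {ratio:.0%} split"
            )
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    train = np.sort(np.concatenate(train_idx))
    val = np.sort(np.concatenate(val_idx))
    return matrix.sample_ids[train], matrix.sample_ids[val]


def _chunk(ids: np.ndarray, sizes: list[int]) -> list[np.ndarray]:
    out, pos = [], 0
    for s in sizes:
        out.append(ids[pos : pos + s])
        pos += s
    return out


def split_clients(
    matrix: FeatureMatrix,
    N: int,
    strategy: str,
    seed: int,
    surplus: str = "last",
) -> ClientPartition:
    """Assign the training samples to ``N`` disjoint client silos.

    ``surplus`` controls where leftover samples land: ``"last"`` (default,
    deterministic) or ``"random"`` (a seeded uniformly chosen client).
    The produced partition is validated; a violation raises
    :class:`PartitionError` with the full report.
    """
    if strategy not in STRATEGIES:
        raise PartitionError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    if N < 1:
        raise PartitionError("N must be >= 1")
    if surplus not in ("last", "random"):
        raise PartitionError("surplus must be 'last' or 'random'")
    rng = np.random.default_rng(seed)
    C = matrix.n_samples
    surplus_client = N - 1 if surplus == "last" else int(rng.integers(N))

    silos: list[list[str]] = [[] for _ in range(N)]
    if strategy == "uniform_stratified":
        for cls in (1, 0):
            ids = rng.permutation(matrix.sample_ids[matrix.labels == cls])
            base = len(ids) // N
            sizes = [base] * N
            sizes[surplus_client] += len(ids) - base * N
            for silo, chunk in zip(silos, _chunk(ids, sizes)):
                silo.extend(chunk)
    elif strategy == "uniform_random":
        ids = rng.permutation(matrix.sample_ids)
        base = C // N
        sizes = [base] * N
        sizes[surplus_client] += C - base * N
        for silo, chunk in zip(silos, _chunk(ids, sizes)):
            silo.extend(chunk)
    else:  # linear_random
        divisor = N * (N + 1) // 2
        c = C // divisor
        if c == 0:
            raise PartitionError(
                f"linear_random infeasible: C={C} < N(N+1)/2={divisor} "
                "(base silo size would be zero)"
            )
        sizes = [(i + 1) * c for i in range(N)]
        sizes[surplus_client] += C - sum(sizes)
        ids = rng.permutation(matrix.sample_ids)
        for silo, chunk in zip(silos, _chunk(ids, sizes)):
            silo.extend(chunk)

    part = ClientPartition(
        N=N,
        strategy=strategy,
        members=tuple(tuple(s) for s in silos),
        seed=seed,
    )
    report = validate_partition(part, matrix)
    if report:
        raise PartitionError(
            "generated partition failed validation: " + "; ".join(report)
        )
    return part


def validate_partition(partition: ClientPartition, matrix: FeatureMatrix) -> list[str]:
    """Check disjointness, exact coverage, and per-client class presence.

    Returns a list of human-readable violation strings — empty when the
    partition is valid.  Never raises, so sweep drivers can log and skip
    infeasible configurations.
    """
    report: list[str] = []
    label_of = dict(zip(matrix.sample_ids, matrix.labels))
    seen: dict[str, int] = {}
    for i, silo in enumerate(partition.members):
        cases = controls = 0
        for sid in silo:
            if sid in seen:
                report.append(
                    f"sample {sid!r} assigned to both client {seen[sid]} and client {i}"
                )
            seen[sid] = i
            if sid not in label_of:
                report.append(f"client {i} references unknown sample {sid!r}")
                continue
            if label_of[sid] == 1:
                cases += 1
            else:
                controls += 1
        if cases == 0:
            report.append(f"client {i} has no case samples")
        if controls == 0:
            report.append(f"client {i} has no control samples")
    missing = set(matrix.sample_ids) - set(seen)
    if missing:
        report.append(
            f"{len(missing)} samples unassigned (e.g. {sorted(missing)[:3]})"
        )
    return report
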