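"""Experiment drivers: cross-validated central-vs-federated comparison,
client-count (sample dispersion) sweeps, split-strategy (heterogeneity)
sweeps, and a light single-split trial used for seed-replicated findings.

All drivers share one result container, :class:`ExperimentResult`, which
keeps fold-level metric records so that every summary cell (mean ± sd over
the K folds, population sd) is recomputable from raw records.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortSpec, FeatureMatrix, generate_cohort
from .federation import FederationConfig, run_federation
from .learners import LearnerConfig, init_weights, local_fit, predict_scores
from .metrics import compute_report
from .partition import (
    PartitionError,
    split_clients,
    stratified_kfold,
    stratified_train_val_split,
)
from .preprocess import Preprocessor

__all__ = [
    "ExperimentResult",
    "run_cv_experiment",
    "run_dispersion_sweep",
    "run_heterogeneity_sweep",
    "measure_runtime",
    "fl_vs_central_trial",
]

METRIC_COLUMNS = [
    "roc_auc",
    "auc_pr",
    "balanced_accuracy",
    "precision",
    "recall",
    "f_half",
    "f_one",
    "f_two",
    "log_loss",
    "mcc",
]

_CONFIG_COLUMNS = [
    "algorithm",
    "mode",
    "n_clients",
    "split_strategy",
    "mu",
    "test_set",
]


@dataclass
class ExperimentResult:
    """Fold-level metric records plus skipped-configuration log."""

    records: pd.DataFrame
    skipped: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Mean ± population sd of every metric per configuration cell."""
        grouped = self.records.groupby(_CONFIG_COLUMNS, dropna=False)
        mean = grouped[METRIC_COLUMNS].mean()
        sd = grouped[METRIC_COLUMNS].std(ddof=0)
        out = mean.join(sd, lsuffix="_mean", rsuffix="_sd").reset_index()
        return out

    def cell(self, metric: str = "auc_pr", **filters) -> tuple[float, float]:
        """(mean, population sd) of one metric in one configuration cell."""
        df = self.records
        for key, value in filters.items():
            df = df[df[key] == value]
        if df.empty:
            raise KeyError(f"no records match {filters}")
        vals = df[metric].to_numpy()
        return float(vals.mean()), float(vals.std())

    def write_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False, float_format="%.6g")


def measure_runtime(task, *args, **kwargs):
    """Run ``task`` and return ``(result, wall-clock seconds)``."""
    t0 = time.perf_counter()
    result = task(*args, **kwargs)
    return result, time.perf_counter() - t0


def _fit_central(config: LearnerConfig, train: FeatureMatrix, seed: int):
    start = init_weights(config, train.n_features, seed)
    return local_fit(config, train, start, mu=0.0, seed=seed)


def _evaluate(weights, test_sets: dict[str, FeatureMatrix], threshold: float = 0.5):
    out = {}
    for name, fm in test_sets.items():
        scores = predict_scores(weights, fm)
        out[name] = compute_report(fm.labels, scores, threshold)
    return out


def run_cv_experiment(
    internal: FeatureMatrix,
    external: FeatureMatrix | None,
    central_learners: dict[str, LearnerConfig],
    federations: dict[str, FederationConfig],
    K: int = 6,
    seed: int = 0,
    split_strategy: str = "uniform_stratified",
    train_ratio: float = 0.8,
    preprocessor_kwargs: dict | None = None,
    repartition_per_fold: bool = True,
) -> ExperimentResult:
    """K-fold cross-validated evaluation of central and federated models.

    Per fold: the held-out fold is the internal test set; the remaining
    folds are preprocessed (fit on them only), split 80:20 into training
    and validation, central learners fit on the training subset, federated
    learners fit on a client partition of the same subset with round
    selection on the validation subset; all selected models are scored on
    the internal holdout and on the entire external cohort.
    """
    folds = stratified_kfold(internal, K, seed)
    rows: list[dict] = []
    skipped: list[str] = []
    for k in range(K):
        train_idx, hold_idx = folds.holdout_split(k)
        train_fm = internal.subset_samples(train_idx)
        hold_fm = internal.subset_samples(hold_idx)
        pre = Preprocessor(**(preprocessor_kwargs or {})).fit(train_fm)
        train_t = pre.transform(train_fm)
        test_sets = {"internal": pre.transform(hold_fm)}
        if external is not None:
            test_sets["external"] = pre.transform(external)

        fold_seed = seed * 1000 + k
        train_ids, val_ids = stratified_train_val_split(
            train_t, train_ratio, fold_seed
        )
        fit_fm = train_t.subset_by_ids(train_ids)
        val_fm = train_t.subset_by_ids(val_ids)

        for name, cfg in central_learners.items():
            weights, secs = measure_runtime(_fit_central, cfg, fit_fm, fold_seed)
            for test_set, report in _evaluate(weights, test_sets).items():
                rows.append(
                    {
                        "algorithm": name,
                        "mode": "central",
                        "n_clients": 0,
                        "split_strategy": "none",
                        "mu": 0.0,
                        "test_set": test_set,
                        "fold": k,
                        "seed": fold_seed,
                        "runtime_seconds": secs,
                        **report.as_dict(),
                    }
                )

        for name, fed in federations.items():
            part_seed = fold_seed if repartition_per_fold else seed
            try:
                partition = split_clients(
                    fit_fm, fed.n_clients, split_strategy, part_seed
                )
            except PartitionError as exc:
                skipped.append(f"fold {k}, {name}: {exc}")
                continue
            (result, secs) = measure_runtime(
                run_federation, fit_fm, partition, val_fm, fed
            )
            for test_set, report in _evaluate(result.best_weights, test_sets).items():
                rows.append(
                    {
                        "algorithm": name,
                        "mode": "federated",
                        "n_clients": fed.n_clients,
                        "split_strategy": split_strategy,
                        "mu": fed.mu,
                        "test_set": test_set,
                        "fold": k,
                        "seed": part_seed,
                        "runtime_seconds": secs,
                        **report.as_dict(),
                    }
                )
    return ExperimentResult(pd.DataFrame(rows), skipped)


def run_dispersion_sweep(
    internal: FeatureMatrix,
    external: FeatureMatrix | None,
    federations: dict[str, FederationConfig],
    n_grid=(2, 4, 6, 8, 10, 12, 14, 16, 18),
    K: int = 6,
    seed: int = 0,
) -> ExperimentResult:
    """Sweep the client count at constant total training data
    (uniform stratified splits)."""
    frames, skipped = [], []
    for n in n_grid:
        feds_n = {
            name: FederationConfig(
                n_clients=n,
                strategy=fed.strategy,
                mu=fed.mu,
                rounds=fed.rounds,
                learner=fed.learner,
                selection_metric=fed.selection_metric,
                seed=fed.seed,
            )
            for name, fed in federations.items()
        }
        res = run_cv_experiment(
            internal,
            external,
            central_learners={},
            federations=feds_n,
            K=K,
            seed=seed,
            split_strategy="uniform_stratified",
        )
        frames.append(res.records)
        skipped.extend(res.skipped)
    return ExperimentResult(pd.concat(frames, ignore_index=True), skipped)


def run_heterogeneity_sweep(
    internal: FeatureMatrix,
    external: FeatureMatrix | None,
    federations: dict[str, FederationConfig],
    strategies=("uniform_stratified", "uniform_random", "linear_random"),
    K: int = 6,
    seed: int = 0,
) -> ExperimentResult:
    """Sweep the client split strategy at fixed client count."""
    frames, skipped = [], []
    for strategy in strategies:
        res = run_cv_experiment(
            internal,
            external,
            central_learners={},
            federations=federations,
            K=K,
            seed=seed,
            split_strategy=strategy,
        )
        frames.append(res.records)
        skipped.extend(res.skipped)
    return ExperimentResult(pd.concat(frames, ignore_index=True), skipped)


# ---------------------------------------------------------------------------
# light single-split trial (seed-replicated findings)
# ---------------------------------------------------------------------------


def fl_vs_central_trial(
    spec: CohortSpec,
    seed: int,
    learner: LearnerConfig | None = None,
    rounds: int = 5,
    variants: list[dict] | None = None,
    test_fraction: float = 0.25,
) -> dict[str, float]:
    """One seed's central-vs-federated comparison on a fresh cohort.

    Generates a cohort with the given seed, holds out ``test_fraction`` of
    it (stratified), z-scores features on the training side, then trains:

    * ``central`` — the learner for ``rounds x local_epochs`` total epochs
      on the training subset, and
    * one federated model per entry of ``variants`` (dicts with keys
      ``name``, ``n_clients``, optional ``split`` and ``mu``),

    all on identical data, returning each model's test AUC-PR.  This is the
    unit trial replicated over seeds to test the qualitative findings
    (federated-tracks-central, dispersion degradation, heterogeneity
    marginality) without the cost of full K-fold pipelines per seed.
    """
    learner = learner or LearnerConfig(
        "logreg", learning_rate=1.0, local_epochs=50, l2_penalty=0.05
    )
    variants = variants if variants is not None else [{"name": "fedavg_n2", "n_clients": 2}]
    fm, _ = generate_cohort(spec.replace(seed=seed))

    train_ids, test_ids = stratified_train_val_split(fm, 1.0 - test_fraction, seed)
    train_fm = fm.subset_by_ids(train_ids)
    test_fm = fm.subset_by_ids(test_ids)
    from .preprocess import z_transform

    train_fm, z_params = z_transform(train_fm)
    test_fm, _ = z_transform(test_fm, z_params)

    fit_ids, val_ids = stratified_train_val_split(train_fm, 0.8, seed + 1)
    fit_fm = train_fm.subset_by_ids(fit_ids)
    val_fm = train_fm.subset_by_ids(val_ids)

    out: dict[str, float] = {}
    # central training consumes the same rounds x local_epochs budget and,
    # symmetrically with the federated round selection, keeps the epoch
    # checkpoint (one per round-equivalent) with the best validation AUC-PR
    weights = init_weights(learner, fit_fm.n_features, seed)
    best_val, best_weights = -np.inf, weights
    for _ in range(rounds):
        weights = local_fit(learner, fit_fm, weights, seed=seed)
        val_auc = compute_report(
            val_fm.labels, predict_scores(weights, val_fm)
        ).auc_pr
        if val_auc > best_val:
            best_val, best_weights = val_auc, weights
    out["central"] = compute_report(
        test_fm.labels, predict_scores(best_weights, test_fm)
    ).auc_pr

    for variant in variants:
        name = variant["name"]
        mu = float(variant.get("mu", 0.0))
        fed = FederationConfig(
            n_clients=int(variant["n_clients"]),
            strategy="fedprox" if mu > 0 else "fedavg",
            mu=mu,
            rounds=rounds,
            learner=learner,
            seed=seed,
        )
        try:
            partition = split_clients(
                fit_fm, fed.n_clients, variant.get("split", "uniform_stratified"), seed
            )
        except PartitionError:
            out[name] = float("nan")
            continue
        result = run_federation(fit_fm, partition, val_fm, fed)
        out[name] = compute_report(
            test_fm.labels, predict_scores(result.best_weights, test_fm)
        ).auc_pr
    return out
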