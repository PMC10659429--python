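"""Aggregation algebra and the federated training loop."""

import numpy as np
import pytest

from fedomics import (
    FederationConfig,
    aggregate_ensembles,
    aggregate_mean,
    run_federation,
    split_clients,
)
from fedomics.cohort import FeatureMatrix
from fedomics.learners import (
    LearnerConfig,
    ModelWeights,
    init_weights,
    local_fit,
    predict_scores,
)
from .conftest import make_matrix


def training_matrix(n_cases=20, n_controls=40, p=8, seed=0):
    labels = np.array([1] * n_cases + [0] * n_controls)
    rng = np.random.default_rng(seed)
    values = rng.normal(size=(len(labels), p))
    values[labels == 1, 0] += 1.0  # learnable signal on F0
    return make_matrix(labels, values, seed=seed)


def constant_tree(value):
    return {
        "feature": np.array([-2]),
        "threshold": np.array([-2.0]),
        "left": np.array([-1]),
        "right": np.array([-1]),
        "value": np.array([float(value)]),
    }


class TestAggregateMean:
    def test_two_point_mean(self):
        base = init_weights(LearnerConfig("logreg"), 1, 0)
        a = base.with_flat(np.array([0.0, 2.0]))
        b = base.with_flat(np.array([2.0, 0.0]))
        assert np.array_equal(aggregate_mean([a, b]).flat, [1.0, 1.0])

    def test_fixed_point_and_permutation(self):
        rng = np.random.default_rng(0)
        base = init_weights(LearnerConfig("logreg"), 4, 0)
        ws = [base.with_flat(rng.normal(size=5)) for _ in range(5)]
        mean = aggregate_mean(ws)
        assert np.abs(
            aggregate_mean(list(reversed(ws))).flat - mean.flat
        ).max() < 1e-12
        same = base.with_flat(rng.normal(size=5))
        assert np.allclose(aggregate_mean([same] * 7).flat, same.flat, atol=1e-15)

    def test_errors(self):
        base = init_weights(LearnerConfig("logreg"), 3, 0)
        other = init_weights(LearnerConfig("logreg"), 4, 0)
        with pytest.raises(ValueError, match="empty"):
            aggregate_mean([])
        with pytest.raises(ValueError, match="layout"):
            aggregate_mean([base, other])
        tree = ModelWeights("tree_ensemble", 3, trees=(constant_tree(0.5),))
        with pytest.raises(ValueError, match="gradient learners"):
            aggregate_mean([tree])


class TestAggregateEnsembles:
    def test_mean_of_constant_leaves(self):
        a = ModelWeights("tree_ensemble", 2, trees=(constant_tree(0.2),))
        b = ModelWeights("tree_ensemble", 2, trees=(constant_tree(0.8),))
        pooled = aggregate_ensembles([a, b])
        data = make_matrix(np.array([0, 1]), np.zeros((2, 2)))
        assert np.allclose(predict_scores(pooled, data), 0.5)

    def test_single_client_identity_and_mean_invariance(self):
        data = training_matrix(seed=3)
        cfg = LearnerConfig("tree_ensemble", n_trees=5, seed=1)
        w = local_fit(cfg, data, init_weights(cfg, data.n_features, 0))
        assert aggregate_ensembles([w]).trees == w.trees
        pooled = aggregate_ensembles([w, w, w])
        assert np.allclose(
            predict_scores(pooled, data), predict_scores(w, data)
        )

    def test_mixed_kinds_fail(self):
        tree = ModelWeights("tree_ensemble", 3, trees=(constant_tree(0.5),))
        lin = init_weights(LearnerConfig("logreg"), 3, 0)
        with pytest.raises(ValueError, match="tree ensembles"):
            aggregate_ensembles([tree, lin])


class TestRunFederation:
    def test_single_client_reduction(self):
        train = training_matrix(seed=4)
        learner = LearnerConfig("logreg", local_epochs=4)
        part = split_clients(train, 1, "uniform_stratified", 0)
        fed = FederationConfig(n_clients=1, rounds=3, learner=learner, seed=9)
        res = run_federation(train, part, train, fed)
        central = init_weights(learner, train.n_features, 9)
        for _ in range(3):
            central = local_fit(learner, train, central)
        assert np.abs(res.final_weights.flat - central.flat).max() < 1e-10

    def test_fedprox_mu_zero_equals_fedavg(self):
        train = training_matrix(seed=5)
        part = split_clients(train, 2, "uniform_stratified", 1)
        learner = LearnerConfig("logreg", local_epochs=3)
        a = run_federation(
            train, part, train,
            FederationConfig(2, "fedavg", 0.0, 3, learner, seed=2),
        )
        b = run_federation(
            train, part, train,
            FederationConfig(2, "fedprox", 0.0, 3, learner, seed=2),
        )
        for la, lb in zip(a.rounds, b.rounds):
            assert np.array_equal(la.global_weights.flat, lb.global_weights.flat)

    def test_identical_clients_match_single_client_trajectory(self):
        """Two clients holding copies of the same samples produce identical
        locals, so the global trajectory equals the one-client trajectory."""
        base = training_matrix(n_cases=10, n_controls=20, seed=6)
        doubled = FeatureMatrix(
            sample_ids=np.array(
                [f"A{i}" for i in range(30)] + [f"B{i}" for i in range(30)],
                dtype=object,
            ),
            labels=np.concatenate([base.labels, base.labels]),
            values=np.vstack([base.values, base.values]),
            feature_names=base.feature_names,
            feature_groups=base.feature_groups,
        )
        part = split_clients(doubled, 1, "uniform_stratified", 0)
        from fedomics.partition import ClientPartition

        two = ClientPartition(
            N=2,
            strategy="uniform_stratified",
            members=(
                tuple(doubled.sample_ids[:30]),
                tuple(doubled.sample_ids[30:]),
            ),
            seed=0,
        )
        learner = LearnerConfig("logreg", local_epochs=3)
        fed1 = FederationConfig(1, rounds=3, learner=learner, seed=4)
        fed2 = FederationConfig(2, rounds=3, learner=learner, seed=4)
        ra = run_federation(base, split_clients(base, 1, "uniform_stratified", 0),
                            base, fed1)
        rb = run_federation(doubled, two, base, fed2)
        assert np.abs(ra.final_weights.flat - rb.final_weights.flat).max() < 1e-10

    def test_client_permutation_invariance(self):
        train = training_matrix(seed=7)
        part = split_clients(train, 3, "uniform_stratified", 2)
        from fedomics.partition import ClientPartition

        permuted = ClientPartition(
            N=3,
            strategy=part.strategy,
            members=(part.members[2], part.members[0], part.members[1]),
            seed=part.seed,
        )
        learner = LearnerConfig("logreg", local_epochs=2)
        fed = FederationConfig(3, rounds=2, learner=learner, seed=1)
        a = run_federation(train, part, train, fed)
        b = run_federation(train, permuted, train, fed)
        assert np.abs(a.final_weights.flat - b.final_weights.flat).max() < 1e-9

    def test_selection_picks_round_max(self):
        train = training_matrix(seed=8)
        part = split_clients(train, 2, "uniform_stratified", 3)
        fed = FederationConfig(
            2, rounds=4, learner=LearnerConfig("logreg", local_epochs=2), seed=5
        )
        res = run_federation(train, part, train, fed)
        vals = [log.validation.auc_pr for log in res.rounds]
        assert res.best_round == int(np.argmax(vals)) + 1
        assert res.rounds[res.best_round - 1].validation.auc_pr == max(vals)

    def test_round_log_completeness(self):
        train = training_matrix(seed=9)
        part = split_clients(train, 2, "uniform_stratified", 4)
        fed = FederationConfig(
            2, rounds=5, learner=LearnerConfig("logreg", local_epochs=1), seed=0
        )
        res = run_federation(train, part, train, fed)
        assert len(res.rounds) == 5
        for i, log in enumerate(res.rounds, start=1):
            assert log.round_index == i
            assert len(log.client_losses) == 2
            assert log.fit_seconds > 0 and np.isfinite(log.fit_seconds)

    def test_invalid_partition_rejected_before_training(self):
        train = training_matrix(seed=10)
        from fedomics.partition import ClientPartition

        bad = ClientPartition(
            N=1, strategy="uniform_random",
            members=(tuple(train.sample_ids[:5]),), seed=0,
        )
        fed = FederationConfig(1, rounds=1, learner=LearnerConfig("logreg"))
        with pytest.raises(ValueError, match="invalid client partition"):
            run_federation(train, bad, train, fed)

    def test_config_invariants(self):
        with pytest.raises(ValueError, match="mu = 0"):
            FederationConfig(2, "fedavg", mu=0.5)
        with pytest.raises(ValueError, match="gradient learners"):
            FederationConfig(2, "fedprox", mu=1.0, learner=LearnerConfig("tree_ensemble"))
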