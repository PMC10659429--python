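"""Learner contract: initialization, gradients, proximal term, trees, IO."""

import numpy as np
import pytest

from fedomics.learners import (
    LearnerConfig,
    ModelWeights,
    gradient,
    init_weights,
    local_fit,
    predict_scores,
    read_weights,
    training_loss,
    write_weights,
)
from .conftest import make_matrix


def small_data(n=16, p=6, seed=0):
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, n)
    labels[:2] = [0, 1]
    return make_matrix(labels, rng.normal(size=(n, p)), seed=seed)


class TestInitWeights:
    def test_logreg_zero_init(self):
        w = init_weights(LearnerConfig("logreg"), 5, seed=0)
        assert w.flat.shape == (6,)
        assert not w.flat.any()
        assert dict(w.layout) == {"coef": (5,), "intercept": (1,)}

    def test_mlp_layout_sizes(self):
        cfg = LearnerConfig("mlp", hidden_units=32)
        w = init_weights(cfg, 673, seed=0)
        assert len(w.flat) == 673 * 32 + 32 + 32 + 1
        blocks = w.blocks()
        assert blocks["w1"].shape == (673, 32)
        assert not blocks["b1"].any() and not blocks["b2"].any()

    def test_mlp_seed_determinism(self):
        cfg = LearnerConfig("mlp", hidden_units=8)
        a = init_weights(cfg, 20, seed=5)
        b = init_weights(cfg, 20, seed=5)
        c = init_weights(cfg, 20, seed=6)
        assert np.array_equal(a.flat, b.flat)
        assert not np.array_equal(a.flat, c.flat)

    def test_flat_layout_mismatch_rejected(self):
        with pytest.raises(ValueError, match="layout"):
            ModelWeights("logreg", 5, np.zeros(4), (("coef", (5,)), ("intercept", (1,))))


class TestGradients:
    @pytest.mark.parametrize("kind", ["logreg", "mlp"])
    @pytest.mark.parametrize("mu", [0.0, 0.7])
    def test_matches_central_finite_differences(self, kind, mu):
        cfg = LearnerConfig(kind, hidden_units=4, l2_penalty=0.01)
        data = small_data(n=12, p=5, seed=3)
        rng = np.random.default_rng(8)
        w0 = init_weights(cfg, 5, seed=1)
        w = w0.with_flat(rng.normal(scale=0.3, size=len(w0.flat)))
        anchor = w0.with_flat(rng.normal(scale=0.3, size=len(w0.flat)))
        X, y = data.values, data.labels.astype(float)
        g = gradient(cfg, w, X, y, mu, anchor)
        eps = 1e-6
        for idx in rng.choice(len(w.flat), size=min(12, len(w.flat)), replace=False):
            up, dn = w.get_flat(), w.get_flat()
            up[idx] += eps
            dn[idx] -= eps
            num = (
                training_loss(cfg, w.with_flat(up), X, y, mu, anchor)
                - training_loss(cfg, w.with_flat(dn), X, y, mu, anchor)
            ) / (2 * eps)
            assert abs(g[idx] - num) < 1e-5

    def test_loss_nonincreasing_default_config(self):
        data = small_data(n=40, p=8, seed=4)
        cfg = LearnerConfig("logreg", learning_rate=0.1, local_epochs=1, l2_penalty=0.01)
        w = init_weights(cfg, 8, seed=0)
        X, y = data.values, data.labels.astype(float)
        losses = [training_loss(cfg, w, X, y)]
        for _ in range(30):
            w = local_fit(cfg, data, w)
            losses.append(training_loss(cfg, w, X, y))
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))


class TestLocalFit:
    def test_mu_zero_equals_plain_fit(self):
        data = small_data(seed=5)
        cfg = LearnerConfig("sgd_linear", local_epochs=3, seed=11)
        start = init_weights(cfg, data.n_features, 0)
        rng = np.random.default_rng(1)
        anchor = start.with_flat(rng.normal(size=len(start.flat)))
        a = local_fit(cfg, data, start, mu=0.0, anchor=anchor, seed=11)
        b = local_fit(cfg, data, start, seed=11)
        assert np.array_equal(a.flat, b.flat)

    def test_proximal_pull_is_monotone_in_mu(self):
        """Growing mu pulls the local fit monotonically toward the anchor."""
        data = small_data(n=30, p=6, seed=6)
        cfg = LearnerConfig("logreg", learning_rate=0.3, local_epochs=50)
        start = init_weights(cfg, 6, 0)
        anchor = start.with_flat(np.full(7, 0.5))
        dists = []
        for mu in [0.0, 0.5, 2.0, 1e3, 1e6]:
            w = local_fit(cfg, data, start, mu=mu, anchor=anchor)
            dists.append(np.linalg.norm(w.flat - anchor.flat))
        assert all(b < a for a, b in zip(dists, dists[1:]))
        assert dists[-1] < 1e-3

    def test_fullbatch_determinism(self):
        data = small_data(seed=7)
        cfg = LearnerConfig("mlp", hidden_units=4, local_epochs=5)
        start = init_weights(cfg, data.n_features, 2)
        a = local_fit(cfg, data, start)
        b = local_fit(cfg, data, start)
        assert np.array_equal(a.flat, b.flat)

    def test_sgd_shuffle_is_seeded(self):
        data = small_data(seed=8)
        cfg = LearnerConfig("sgd_linear", local_epochs=2)
        start = init_weights(cfg, data.n_features, 0)
        a = local_fit(cfg, data, start, seed=3)
        b = local_fit(cfg, data, start, seed=3)
        c = local_fit(cfg, data, start, seed=4)
        assert np.array_equal(a.flat, b.flat)
        assert not np.array_equal(a.flat, c.flat)

    def test_single_class_data_rejected(self):
        data = make_matrix(np.ones(10, dtype=int))
        cfg = LearnerConfig("logreg")
        with pytest.raises(ValueError, match="at least one case and one control"):
            local_fit(cfg, data, init_weights(cfg, data.n_features, 0))

    def test_trees_reject_proximal_term(self):
        data = small_data(seed=9)
        cfg = LearnerConfig("tree_ensemble", n_trees=4)
        start = init_weights(cfg, data.n_features, 0)
        with pytest.raises(ValueError, match="undefined for tree ensembles"):
            local_fit(cfg, data, start, mu=0.5, anchor=start)


class TestPredictScores:
    def test_zero_weights_give_half(self):
        data = small_data(seed=10)
        for kind in ("logreg", "sgd_linear"):
            w = init_weights(LearnerConfig(kind), data.n_features, 0)
            assert np.allclose(predict_scores(w, data), 0.5)

    def test_logistic_at_zero(self):
        w = init_weights(LearnerConfig("logreg"), 2, 0)
        flat = w.get_flat()
        flat[0] = 1.0  # coefficient on F0, x0 = 0 -> logit 0
        w = w.with_flat(flat)
        data = make_matrix(np.array([0, 1]), np.array([[0.0, 3.0], [0.0, -2.0]]))
        assert np.allclose(predict_scores(w, data), 0.5)

    def test_hand_built_tree_routing(self):
        # single stump: x0 <= 0 -> leaf 0.2 else leaf 0.8
        tree = {
            "feature": np.array([0, -2, -2]),
            "threshold": np.array([0.0, -2.0, -2.0]),
            "left": np.array([1, -1, -1]),
            "right": np.array([2, -1, -1]),
            "value": np.array([0.5, 0.2, 0.8]),
        }
        w = ModelWeights("tree_ensemble", 1, trees=(tree,))
        data = make_matrix(
            np.array([0, 1, 0, 1]), np.array([[-1.0], [0.0], [0.5], [3.0]])
        )
        assert np.allclose(predict_scores(w, data), [0.2, 0.2, 0.8, 0.8])

    def test_feature_mismatch_fails(self):
        w = init_weights(LearnerConfig("logreg"), 4, 0)
        with pytest.raises(ValueError, match="mismatch"):
            predict_scores(w, small_data(p=6))

    def test_tree_scores_bounded(self):
        data = small_data(n=60, p=5, seed=12)
        cfg = LearnerConfig("tree_ensemble", n_trees=8, seed=1)
        w = local_fit(cfg, data, init_weights(cfg, 5, 0))
        s = predict_scores(w, data)
        assert (s >= 0).all() and (s <= 1).all()


class TestWeightsIO:
    def test_gradient_round_trip(self, tmp_path):
        cfg = LearnerConfig("mlp", hidden_units=3)
        w = init_weights(cfg, 7, seed=4)
        path = tmp_path / "weights.tsv"
        write_weights(w, path)
        back = read_weights(path)
        assert np.array_equal(back.flat, w.flat)
        assert back.layout == w.layout

    def test_tree_round_trip(self, tmp_path):
        data = small_data(n=40, p=4, seed=13)
        cfg = LearnerConfig("tree_ensemble", n_trees=3, seed=2)
        w = local_fit(cfg, data, init_weights(cfg, 4, 0))
        path = tmp_path / "trees.tsv"
        write_weights(w, path)
        back = read_weights(path)
        assert np.allclose(predict_scores(back, data), predict_scores(w, data))
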