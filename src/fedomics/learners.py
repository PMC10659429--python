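"""Local learners with a uniform weights contract for federated training.

Four learner kinds are available, mirroring the four federated-paired
algorithms of the evaluation:

``logreg``
    L2-regularized logistic regression trained by deterministic full-batch
    gradient descent.
``sgd_linear``
    The same linear model trained by seeded single-sample stochastic
    gradient descent with per-epoch shuffling.
``mlp``
    A one-hidden-layer ReLU network with a logistic output unit, trained by
    full-batch gradient descent.
``tree_ensemble``
    A random-forest-style ensemble of bootstrap CART trees (individual
    trees are fit with scikit-learn and extracted into a plain array
    representation; prediction and aggregation are implemented here).

Gradient learners share a flat-vector weights contract so that federated
averaging and the FedProx proximal objective

    minimize  F_k(w) + (mu / 2) * ||w - w_t||^2

(local regularized log-loss ``F_k`` anchored to the current global model
``w_t``) are uniform across kinds.  Gradient descent is written explicitly
— rather than delegating fits to a library solver — precisely so the
warm-start and proximal-gradient semantics are exact and identical for
every gradient learner.  The proximal term covers the intercept as well;
the L2 penalty does not.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.tree import DecisionTreeClassifier

from .cohort import FeatureMatrix

__all__ = [
    "ModelWeights",
    "LearnerConfig",
    "GRADIENT_KINDS",
    "LEARNER_KINDS",
    "init_weights",
    "local_fit",
    "predict_scores",
    "training_loss",
    "gradient",
]

GRADIENT_KINDS = ("logreg", "sgd_linear", "mlp")
LEARNER_KINDS = GRADIENT_KINDS + ("tree_ensemble",)

_DEFAULT_LR = {"logreg": 0.3, "sgd_linear": 0.05, "mlp": 0.05}


@dataclass(frozen=True)
class ModelWeights:
    """Serializable parameters of one learner.

    Gradient learners carry a flat vector plus a layout (ordered
    ``(block name, shape)`` pairs covering the vector exactly); tree
    ensembles carry a tuple of node-array tables.
    """

    learner_kind: str
    n_features: int
    flat: np.ndarray | None = None
    layout: tuple[tuple[str, tuple[int, ...]], ...] | None = None
    trees: tuple[dict, ...] | None = None

    def __post_init__(self) -> None:
        if self.learner_kind not in LEARNER_KINDS:
            raise ValueError(f"unknown learner kind {self.learner_kind!r}")
        if self.learner_kind in GRADIENT_KINDS:
            if self.flat is None or self.layout is None:
                raise ValueError("gradient learners need flat vector + layout")
            object.__setattr__(
                self, "flat", np.asarray(self.flat, dtype=np.float64)
            )
            total = sum(int(np.prod(shape)) for _, shape in self.layout)
            if self.flat.shape != (total,):
                raise ValueError(
                    f"flat vector length {self.flat.shape} does not match "
                    f"layout total {total}"
                )
        else:
            if self.trees is None:
                raise ValueError("tree_ensemble weights need a tree list")
            for t in self.trees:
                if not np.isfinite(t["value"]).all():
                    raise ValueError("tree leaf values must be finite")

    def get_flat(self) -> np.ndarray:
        return self.flat.copy()

    def with_flat(self, flat: np.ndarray) -> "ModelWeights":
        return dataclasses.replace(self, flat=np.asarray(flat, dtype=np.float64))

    def blocks(self) -> dict[str, np.ndarray]:
        """Unpack the flat vector into named blocks (views reshaped)."""
        out, pos = {}, 0
        for name, shape in self.layout:
            size = int(np.prod(shape))
            out[name] = self.flat[pos : pos + size].reshape(shape)
            pos += size
        return out

    def same_layout(self, other: "ModelWeights") -> bool:
        return (
            self.learner_kind == other.learner_kind
            and self.n_features == other.n_features
            and self.layout == other.layout
        )


@dataclass(frozen=True)
class LearnerConfig:
    """Hyperparameters of a local learner.

    ``learning_rate=None`` resolves to the per-kind default
    (logreg 0.3, sgd_linear 0.05, mlp 0.05).
    """

    kind: str
    learning_rate: float | None = None
    local_epochs: int = 20
    l2_penalty: float = 1e-3
    hidden_units: int = 32
    n_trees: int = 64
    max_depth: int = 4
    subsample: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in LEARNER_KINDS:
            raise ValueError(f"unknown learner kind {self.kind!r}")
        if self.learning_rate is not None and self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.local_epochs < 1:
            raise ValueError("local_epochs must be >= 1")
        if self.kind == "mlp" and self.hidden_units < 1:
            raise ValueError("mlp needs hidden_units >= 1")
        if not (0.0 < self.subsample <= 1.0):
            raise ValueError("subsample must lie in (0, 1]")

    @property
    def lr(self) -> float:
        return (
            self.learning_rate
            if self.learning_rate is not None
            else _DEFAULT_LR.get(self.kind, 0.1)
        )

    def replace(self, **kwargs) -> "LearnerConfig":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def init_weights(config: LearnerConfig, n_features: int, seed: int) -> ModelWeights:
    """Initial weights: zeros for linear models, seeded symmetric-uniform
    (Glorot-style) for the MLP, an empty ensemble for trees."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    kind = config.kind
    if kind in ("logreg", "sgd_linear"):
        layout = (("coef", (n_features,)), ("intercept", (1,)))
        return ModelWeights(kind, n_features, np.zeros(n_features + 1), layout)
    if kind == "mlp":
        h = config.hidden_units
        rng = np.random.default_rng(seed)
        lim1 = np.sqrt(6.0 / (n_features + h))
        lim2 = np.sqrt(6.0 / (h + 1))
        w1 = rng.uniform(-lim1, lim1, size=(n_features, h))
        w2 = rng.uniform(-lim2, lim2, size=(h,))
        flat = np.concatenate([w1.ravel(), np.zeros(h), w2, np.zeros(1)])
        layout = (
            ("w1", (n_features, h)),
            ("b1", (h,)),
            ("w2", (h,)),
            ("b2", (1,)),
        )
        return ModelWeights(kind, n_features, flat, layout)
    # tree_ensemble: empty until the first local fit
    return ModelWeights(kind, n_features, trees=())


# ---------------------------------------------------------------------------
# loss / gradient for the gradient learners
# ---------------------------------------------------------------------------


def _forward_linear(blocks: dict, X: np.ndarray) -> np.ndarray:
    return expit(X @ blocks["coef"] + blocks["intercept"][0])


def _forward_mlp(blocks: dict, X: np.ndarray):
    pre = X @ blocks["w1"] + blocks["b1"]
    act = np.maximum(pre, 0.0)
    z = act @ blocks["w2"] + blocks["b2"][0]
    return expit(z), act, pre


def _mean_log_loss(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-15
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def training_loss(
    config: LearnerConfig,
    weights: ModelWeights,
    X: np.ndarray,
    y: np.ndarray,
    mu: float = 0.0,
    anchor: ModelWeights | None = None,
) -> float:
    """Local objective value: mean log-loss + (l2/2)||coef||^2
    + (mu/2)||w - anchor||^2 (the proximal norm spans the whole flat
    vector, intercepts included)."""
    blocks = weights.blocks()
    if config.kind in ("logreg", "sgd_linear"):
        p = _forward_linear(blocks, X)
        penalty = 0.5 * config.l2_penalty * float(blocks["coef"] @ blocks["coef"])
    elif config.kind == "mlp":
        p, _, _ = _forward_mlp(blocks, X)
        penalty = 0.5 * config.l2_penalty * (
            float(np.sum(blocks["w1"] ** 2)) + float(blocks["w2"] @ blocks["w2"])
        )
    else:
        raise ValueError("training_loss is defined for gradient learners only")
    loss = _mean_log_loss(y, p) + penalty
    if mu > 0.0:
        d = weights.flat - anchor.flat
        loss += 0.5 * mu * float(d @ d)
    return loss


def gradient(
    config: LearnerConfig,
    weights: ModelWeights,
    X: np.ndarray,
    y: np.ndarray,
    mu: float = 0.0,
    anchor: ModelWeights | None = None,
) -> np.ndarray:
    """Flat gradient of :func:`training_loss` (full batch)."""
    blocks = weights.blocks()
    n = len(y)
    if config.kind in ("logreg", "sgd_linear"):
        p = _forward_linear(blocks, X)
        err = (p - y) / n
        g_coef = X.T @ err + config.l2_penalty * blocks["coef"]
        g_int = np.array([err.sum()])
        flat_grad = np.concatenate([g_coef, g_int])
    elif config.kind == "mlp":
        p, act, pre = _forward_mlp(blocks, X)
        err = (p - y) / n  # d loss / d z_out
        g_w2 = act.T @ err + config.l2_penalty * blocks["w2"]
        g_b2 = np.array([err.sum()])
        d_act = np.outer(err, blocks["w2"])
        d_pre = d_act * (pre > 0.0)
        g_w1 = X.T @ d_pre + config.l2_penalty * blocks["w1"]
        g_b1 = d_pre.sum(axis=0)
        flat_grad = np.concatenate([g_w1.ravel(), g_b1, g_w2, g_b2])
    else:
        raise ValueError("gradient is defined for gradient learners only")
    if mu > 0.0:
        flat_grad = flat_grad + mu * (weights.flat - anchor.flat)
    return flat_grad


# ---------------------------------------------------------------------------
# local fitting
# ---------------------------------------------------------------------------


def _check_local_data(data: FeatureMatrix) -> None:
    if data.n_cases == 0 or data.n_controls == 0:
        raise ValueError(
            "local fit requires at least one case and one control "
            f"(got {data.n_cases} cases / {data.n_controls} controls)"
        )


def _fit_gradient_fullbatch(
    config: LearnerConfig,
    X: np.ndarray,
    y: np.ndarray,
    start: ModelWeights,
    mu: float,
    anchor: ModelWeights,
) -> ModelWeights:
    # proximal term handled implicitly (backward Euler): unconditionally
    # stable for any mu, and identical to plain gradient descent at mu=0
    w = start
    lr = config.lr
    for _ in range(config.local_epochs):
        g = gradient(config, w, X, y)
        flat = w.flat - lr * g
        if mu > 0.0:
            flat = (flat + lr * mu * anchor.flat) / (1.0 + lr * mu)
        w = w.with_flat(flat)
    loss = training_loss(config, w, X, y, mu, anchor)
    if not np.isfinite(loss):
        raise FloatingPointError(
            f"non-finite training loss after {config.local_epochs} epochs "
            f"(lr={config.lr}, l2={config.l2_penalty}, mu={mu}); "
            "reduce the learning rate"
        )
    return w


def _fit_sgd(
    config: LearnerConfig,
    X: np.ndarray,
    y: np.ndarray,
    start: ModelWeights,
    mu: float,
    anchor: ModelWeights,
    seed: int,
) -> ModelWeights:
    rng = np.random.default_rng(seed)
    flat = start.get_flat()
    p_dim = start.n_features
    anchor_flat = anchor.flat
    lr, l2 = config.lr, config.l2_penalty
    for _ in range(config.local_epochs):
        for i in rng.permutation(len(y)):
            xi = X[i]
            z = xi @ flat[:p_dim] + flat[p_dim]
            err = expit(z) - y[i]
            g = np.empty_like(flat)
            g[:p_dim] = err * xi + l2 * flat[:p_dim]
            g[p_dim] = err
            flat -= lr * g
            if mu > 0.0:  # implicit proximal step, stable for any mu
                flat = (flat + lr * mu * anchor_flat) / (1.0 + lr * mu)
    if not np.isfinite(flat).all():
        raise FloatingPointError("sgd_linear weights diverged to non-finite values")
    return start.with_flat(flat)


def _extract_tree(tree: DecisionTreeClassifier) -> dict:
    t = tree.tree_
    counts = t.value[:, 0, :]  # (n_nodes, n_classes) class weights per node
    if tree.n_classes_ == 2:
        case_col = int(np.flatnonzero(tree.classes_ == 1)[0])
        prob = counts[:, case_col] / counts.sum(axis=1)
    else:  # bootstrap sample was single-class
        prob = np.full(t.node_count, float(tree.classes_[0]))
    return {
        "feature": t.feature.copy(),
        "threshold": t.threshold.copy(),
        "left": t.children_left.copy(),
        "right": t.children_right.copy(),
        "value": prob,
    }


def _fit_tree_ensemble(
    config: LearnerConfig, X: np.ndarray, y: np.ndarray, seed: int
) -> tuple[dict, ...]:
    rng = np.random.default_rng(seed)
    n = len(y)
    m = max(1, int(round(config.subsample * n)))
    trees = []
    for k in range(config.n_trees):
        idx = rng.integers(0, n, size=m)
        clf = DecisionTreeClassifier(
            max_depth=config.max_depth,
            max_features="sqrt",
            random_state=int(rng.integers(2**31 - 1)),
        )
        clf.fit(X[idx], y[idx])
        trees.append(_extract_tree(clf))
    return tuple(trees)


def local_fit(
    config: LearnerConfig,
    data: FeatureMatrix,
    start: ModelWeights,
    mu: float = 0.0,
    anchor: ModelWeights | None = None,
    seed: int | None = None,
) -> ModelWeights:
    """One client's local training pass.

    Gradient learners run ``local_epochs`` of (full-batch or single-sample)
    gradient descent on the proximal objective starting from ``start``;
    the proximal term is applied as an implicit (backward-Euler) step so
    the update stays stable for arbitrarily large ``mu``.  ``anchor``
    defaults to ``start`` (the freshly received global model).
    Tree ensembles refit ``n_trees`` bootstrap trees on the local data
    (``mu`` does not apply and must be 0).
    """
    _check_local_data(data)
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if anchor is None:
        anchor = start
    if mu > 0 and not start.same_layout(anchor):
        raise ValueError("anchor layout must match start layout")
    if seed is None:
        seed = config.seed
    X, y = data.values, data.labels.astype(np.float64)
    kind = config.kind
    if kind in ("logreg", "mlp"):
        return _fit_gradient_fullbatch(config, X, y, start, mu, anchor)
    if kind == "sgd_linear":
        return _fit_sgd(config, X, y, start, mu, anchor, seed)
    if mu > 0:
        raise ValueError("the proximal objective is undefined for tree ensembles")
    trees = _fit_tree_ensemble(config, X, data.labels, seed)
    return ModelWeights("tree_ensemble", data.n_features, trees=trees)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def _route_tree(tree: dict, X: np.ndarray) -> np.ndarray:
    node = np.zeros(len(X), dtype=np.int64)
    active = tree["feature"][node] >= 0
    while active.any():
        idx = np.flatnonzero(active)
        nd = node[idx]
        go_left = X[idx, tree["feature"][nd]] <= tree["threshold"][nd]
        node[idx] = np.where(go_left, tree["left"][nd], tree["right"][nd])
        active = tree["feature"][node] >= 0
    return tree["value"][node]


def predict_scores(weights: ModelWeights, matrix: FeatureMatrix) -> np.ndarray:
    """Per-sample case probability in [0, 1]."""
    if matrix.n_features != weights.n_features:
        raise ValueError(
            f"feature count mismatch: model expects {weights.n_features}, "
            f"matrix has {matrix.n_features}"
        )
    X = matrix.values
    if weights.learner_kind in ("logreg", "sgd_linear"):
        return _forward_linear(weights.blocks(), X)
    if weights.learner_kind == "mlp":
        return _forward_mlp(weights.blocks(), X)[0]
    if not weights.trees:
        return np.full(len(X), 0.5)
    return np.mean([_route_tree(t, X) for t in weights.trees], axis=0)


# ---------------------------------------------------------------------------
# serialization: a JSON manifest plus plain numeric tables (layout v1)
# ---------------------------------------------------------------------------


def write_weights(weights: ModelWeights, path) -> None:
    """Serialize to ``<path>`` (TSV table) + ``<path>.manifest.json``."""
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    manifest = {
        "format_version": 1,
        "learner_kind": weights.learner_kind,
        "n_features": weights.n_features,
    }
    if weights.learner_kind in GRADIENT_KINDS:
        manifest["layout"] = [[n, list(s)] for n, s in weights.layout]
        pd.DataFrame({"value": weights.flat}).to_csv(
            path, sep="\t", index=False, float_format="%.17g"
        )
    else:
        manifest["n_trees"] = len(weights.trees)
        rows = []
        for ti, t in enumerate(weights.trees):
            for ni in range(len(t["feature"])):
                rows.append(
                    {
                        "tree": ti,
                        "node": ni,
                        "feature": t["feature"][ni],
                        "threshold": t["threshold"][ni],
                        "left": t["left"][ni],
                        "right": t["right"][ni],
                        "value": t["value"][ni],
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")
    path.with_suffix(path.suffix + ".manifest.json").write_text(
        json.dumps(manifest, indent=2)
    )


def read_weights(path) -> ModelWeights:
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    manifest = json.loads(
        path.with_suffix(path.suffix + ".manifest.json").read_text()
    )
    kind = manifest["learner_kind"]
    if kind in GRADIENT_KINDS:
        flat = pd.read_csv(path, sep="\t", float_precision="round_trip")[
            "value"
        ].to_numpy(dtype=np.float64)
        layout = tuple((n, tuple(s)) for n, s in manifest["layout"])
        return ModelWeights(kind, manifest["n_features"], flat, layout)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    trees = []
    for ti, grp in df.groupby("tree", sort=True):
        grp = grp.sort_values("node")
        trees.append(
            {
                "feature": grp["feature"].to_numpy(dtype=np.int64),
                "threshold": grp["threshold"].to_numpy(dtype=np.float64),
                "left": grp["left"].to_numpy(dtype=np.int64),
                "right": grp["right"].to_numpy(dtype=np.int64),
                "value": grp["value"].to_numpy(dtype=np.float64),
            }
        )
    return ModelWeights(kind, manifest["n_features"], trees=tuple(trees))
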