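"""Leakage-safe feature-adjustment chain for multi-omics matrices.

The chain mirrors the standard multi-omics hygiene steps for case/control
modelling:

1. **Per-block principal components** — top-k principal axes of the
   centered genetic (SNP dosage) block and of the transcriptomic block,
   computed separately (k = 10 each by default).  These summarize latent
   population substructure / experimental covariates.
2. **Residualization** — every feature in a block is replaced by its
   least-squares residual on (intercept + that block's PC scores),
   removing quantifiable substructure before modelling.
3. **Z-transform** — continuous features standardized to mean 0, sd 1
   (population sd, i.e. divide by n).  Binary indicators pass through
   unchanged; zero-variance features are flagged and left untouched.
4. **Optional feature selection** — extremely-randomized-trees impurity
   importance ranking followed by greedy correlation pruning (drop any
   feature whose squared correlation with an already-kept, higher-ranked
   feature exceeds ``corr_threshold``, default r^2 = 0.36).

Everything is fit on training data only; ``transform`` applies the stored
training-fit parameters to held-out data without refitting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier

from .cohort import (
    GROUP_GENETIC,
    GROUP_TRANSCRIPTOMIC,
    FeatureMatrix,
)

__all__ = [
    "BlockPCA",
    "ZParams",
    "Preprocessor",
    "compute_block_pcs",
    "residualize",
    "z_transform",
    "select_features",
]


# ---------------------------------------------------------------------------
# principal components
# ---------------------------------------------------------------------------


@dataclass
class BlockPCA:
    """Top-k principal axes of one feature block (training fit)."""

    feature_names: np.ndarray
    center: np.ndarray  # per-feature training means
    loadings: np.ndarray  # (p_block, k), orthonormal columns
    explained_variance: np.ndarray  # (k,), non-increasing

    def scores(self, matrix: FeatureMatrix) -> np.ndarray:
        sub = matrix.subset_features(self.feature_names)
        return (sub.values - self.center) @ self.loadings


def compute_block_pcs(matrix: FeatureMatrix, block: str, k: int) -> tuple[np.ndarray, BlockPCA]:
    """PC scores + loadings for the top-k principal axes of ``block``.

    Raises when ``k`` exceeds the centered block's numerical rank.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    cols = matrix.group_columns(block)
    if len(cols) < k:
        raise ValueError(
            f"block {block!r} has {len(cols)} features, fewer than k={k}"
        )
    X = matrix.values[:, cols]
    center = X.mean(axis=0)
    Xc = X - center
    # SVD of the centered block: principal axes = right singular vectors
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size and s[0] > 0 else 0
    if k > rank:
        raise ValueError(
            f"k={k} exceeds the numerical rank {rank} of block {block!r}"
        )
    loadings = Vt[:k].T
    explained = (s[:k] ** 2) / max(matrix.n_samples - 1, 1)
    model = BlockPCA(
        feature_names=matrix.feature_names[cols].copy(),
        center=center,
        loadings=loadings,
        explained_variance=explained,
    )
    return Xc @ loadings, model


# ---------------------------------------------------------------------------
# residualization
# ---------------------------------------------------------------------------


def residualize(
    matrix: FeatureMatrix,
    covariates: np.ndarray,
    coefficients: np.ndarray | None = None,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Replace every feature by its least-squares residual on
    (intercept + covariates).

    With ``coefficients=None`` the regression is fit (training call) and the
    fitted ``(1 + n_cov, p)`` coefficient matrix is returned for reuse; a
    held-out call passes the stored coefficients and no refit happens.
    Rank-deficient covariate sets have their dependent columns zeroed with
    a warning (fit call only).
    """
    covariates = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
    if covariates.shape[0] != matrix.n_samples:
        raise ValueError("covariate rows must align with matrix rows")
    design = np.column_stack([np.ones(matrix.n_samples), covariates])
    if coefficients is None:
        # detect dependent covariate columns via rank-revealing QR
        r = np.linalg.qr(design, mode="r")
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(design.shape) * np.finfo(float).eps
        dependent = np.flatnonzero(diag < tol)
        if dependent.size:
            warnings.warn(
                f"dropping {dependent.size} linearly dependent covariate "
                "column(s) from the residualization design",
                stacklevel=2,
            )
            design = design.copy()
            design[:, dependent] = 0.0
        coefficients, *_ = np.linalg.lstsq(design, matrix.values, rcond=None)
    elif coefficients.shape != (design.shape[1], matrix.n_features):
        raise ValueError("stored coefficient shape does not match design")
    residuals = matrix.values - design @ coefficients
    out = matrix.copy()
    out.values = residuals
    return out, coefficients


# ---------------------------------------------------------------------------
# z-transform
# ---------------------------------------------------------------------------


@dataclass
class ZParams:
    """Per-feature (mean, sd) from training data, population-sd convention.

    ``passthrough`` lists binary features left untouched; ``zero_variance``
    lists constant training features flagged and excluded from the
    transform.
    """

    mean: dict[str, float]
    sd: dict[str, float]
    passthrough: tuple[str, ...]
    zero_variance: tuple[str, ...]


def _is_binary(col: np.ndarray) -> bool:
    return np.isin(col, (0.0, 1.0)).all()


def z_transform(
    matrix: FeatureMatrix, params: ZParams | None = None
) -> tuple[FeatureMatrix, ZParams]:
    """Standardize continuous features to mean 0 / sd 1.

    Training call (``params=None``) fits per-column (mean, sd) with the
    population-sd convention (divide by n); binary 0/1 columns pass
    through unchanged, constant columns are flagged and skipped.  A
    held-out call applies the stored parameters.
    """
    out = matrix.copy()
    if params is None:
        mean: dict[str, float] = {}
        sd: dict[str, float] = {}
        passthrough: list[str] = []
        zero_var: list[str] = []
        for j, name in enumerate(matrix.feature_names):
            col = matrix.values[:, j]
            if _is_binary(col):
                passthrough.append(name)
                continue
            s = float(col.std())  # ddof=0
            if s < 1e-12:
                zero_var.append(name)
                continue
            mean[name] = float(col.mean())
            sd[name] = s
        params = ZParams(mean, sd, tuple(passthrough), tuple(zero_var))
        if zero_var:
            warnings.warn(
                f"{len(zero_var)} zero-variance feature(s) excluded from the "
                f"Z-transform (e.g. {zero_var[:3]})",
                stacklevel=2,
            )
    name_to_col = {n: j for j, n in enumerate(matrix.feature_names)}
    for name, m in params.mean.items():
        if name in name_to_col:
            j = name_to_col[name]
            out.values[:, j] = (out.values[:, j] - m) / params.sd[name]
    return out, params


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------


def select_features(
    train: FeatureMatrix,
    n_trees: int = 512,
    corr_threshold: float = 0.36,
    keep: int | float | None = None,
    seed: int = 0,
) -> list[str]:
    """Importance-ranked feature list after correlation pruning.

    Features are ranked by mean Gini impurity importance over an
    extremely-randomized-trees ensemble (``n_trees`` trees, sqrt(p) random
    candidate features with one uniform-random threshold each — the
    canonical construction, via scikit-learn).  Walking the ranking, any
    feature whose squared Pearson correlation with an already-kept feature
    exceeds ``corr_threshold`` is pruned.  Returns the top ``keep``
    survivors in rank order (``keep`` may be an int, a fraction of the
    feature count, or None for all survivors).
    """
    if train.n_cases == 0 or train.n_controls == 0:
        raise ValueError("feature selection needs both classes in the training data")
    forest = ExtraTreesClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features="sqrt",
        bootstrap=False,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(train.values, train.labels)
    importance = forest.feature_importances_
    order = np.argsort(-importance, kind="stable")

    X = train.values
    sds = X.std(axis=0)
    kept: list[int] = []
    for j in order:
        ok = True
        for k_idx in kept:
            if sds[j] < 1e-12 or sds[k_idx] < 1e-12:
                r2 = 1.0 if sds[j] < 1e-12 and sds[k_idx] < 1e-12 else 0.0
            else:
                r = np.corrcoef(X[:, j], X[:, k_idx])[0, 1]
                r2 = r * r
            if r2 > corr_threshold:
                ok = False
                break
        if ok:
            kept.append(j)

    if keep is None:
        n_keep = len(kept)
    elif isinstance(keep, float) and 0 < keep < 1:
        n_keep = max(1, int(round(keep * train.n_features)))
    else:
        n_keep = int(keep)
    if n_keep > len(kept):
        warnings.warn(
            f"requested keep={n_keep} exceeds the {len(kept)} pruning "
            "survivors; returning all survivors",
            stacklevel=2,
        )
        n_keep = len(kept)
    return [train.feature_names[j] for j in kept[:n_keep]]


# ---------------------------------------------------------------------------
# the fitted chain
# ---------------------------------------------------------------------------


@dataclass
class Preprocessor:
    """The full train-fit/held-out-apply adjustment chain.

    ``fit`` computes per-block PCs, residual regressions, Z-parameters and
    (optionally) the selected feature list from training data only;
    ``transform`` applies all stored parameters to any matrix on the same
    feature space.
    """

    n_pcs: int = 10
    corr_threshold: float = 0.36
    n_trees: int = 512
    keep: int | float | None = None
    select: bool = False
    seed: int = 0

    pca_genetic: BlockPCA | None = None
    pca_transcriptomic: BlockPCA | None = None
    coef_genetic: np.ndarray | None = None
    coef_transcriptomic: np.ndarray | None = None
    z_params: ZParams | None = None
    selected_features: list[str] | None = None

    def fit(self, train: FeatureMatrix) -> "Preprocessor":
        work = train.copy()
        for block, pca_attr, coef_attr in (
            (GROUP_GENETIC, "pca_genetic", "coef_genetic"),
            (GROUP_TRANSCRIPTOMIC, "pca_transcriptomic", "coef_transcriptomic"),
        ):
            scores, pca = compute_block_pcs(work, block, self.n_pcs)
            sub = work.subset_features(pca.feature_names)
            resid, coef = residualize(sub, scores)
            setattr(self, pca_attr, pca)
            setattr(self, coef_attr, coef)
            cols = work.group_columns(block)
            work.values[:, cols] = resid.values
        work, self.z_params = z_transform(work)
        if self.select:
            self.selected_features = select_features(
                work,
                n_trees=self.n_trees,
                corr_threshold=self.corr_threshold,
                keep=self.keep,
                seed=self.seed,
            )
        return self

    def transform(self, matrix: FeatureMatrix) -> FeatureMatrix:
        if self.z_params is None:
            raise RuntimeError("Preprocessor must be fit before transform")
        work = matrix.copy()
        for block, pca, coef in (
            (GROUP_GENETIC, self.pca_genetic, self.coef_genetic),
            (GROUP_TRANSCRIPTOMIC, self.pca_transcriptomic, self.coef_transcriptomic),
        ):
            scores = pca.scores(work)
            sub = work.subset_features(pca.feature_names)
            resid, _ = residualize(sub, scores, coefficients=coef)
            cols = work.group_columns(block)
            work.values[:, cols] = resid.values
        work, _ = z_transform(work, self.z_params)
        if self.selected_features is not None:
            work = work.subset_features(self.selected_features)
        return work

    def fit_transform(self, train: FeatureMatrix) -> FeatureMatrix:
        return self.fit(train).transform(train)

    # -- serialization: directory of TSV tables + a JSON manifest ---------
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": 1,
            "n_pcs": self.n_pcs,
            "corr_threshold": self.corr_threshold,
            "n_trees": self.n_trees,
            "select": self.select,
            "seed": self.seed,
            "selected_features": self.selected_features,
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for tag, pca, coef in (
            ("genetic", self.pca_genetic, self.coef_genetic),
            ("transcriptomic", self.pca_transcriptomic, self.coef_transcriptomic),
        ):
            pd.DataFrame(
                pca.loadings,
                index=list(pca.feature_names),
                columns=[f"PC{i + 1}" for i in range(pca.loadings.shape[1])],
            ).assign(center=pca.center).to_csv(d / f"pca_{tag}.tsv", sep="\t")
            pd.DataFrame(coef).to_csv(d / f"residual_coef_{tag}.tsv", sep="\t")
        z = self.z_params
        pd.DataFrame(
            {
                "feature": list(z.mean),
                "mean": [z.mean[f] for f in z.mean],
                "sd": [z.sd[f] for f in z.mean],
            }
        ).to_csv(d / "z_params.tsv", sep="\t", index=False)
        pd.DataFrame({"feature": list(z.passthrough)}).to_csv(
            d / "z_passthrough.tsv", sep="\t", index=False
        )
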