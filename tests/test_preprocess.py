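"""Preprocessing chain: PCs, residualization, Z-transform, selection."""

import numpy as np
import pytest

from fedomics import CohortSpec, generate_cohort
from fedomics.preprocess import (
    Preprocessor,
    compute_block_pcs,
    residualize,
    select_features,
    z_transform,
)
from .conftest import make_matrix


class TestBlockPCs:
    def test_rank_one_block_explains_everything(self):
        base = np.arange(1.0, 11.0)
        values = np.column_stack([base, 2 * base, -0.5 * base])
        fm = make_matrix(np.array([0, 1] * 5), values)
        scores, pca = compute_block_pcs(fm, "clinical", 1)
        total = ((values - values.mean(0)) ** 2).sum() / (len(base) - 1)
        assert pca.explained_variance[0] == pytest.approx(total, rel=1e-10)
        with pytest.raises(ValueError, match="rank"):
            compute_block_pcs(fm, "clinical", 2)

    def test_isotropic_block_equal_eigenvalues(self):
        # zero-mean columns with X^T X = 4I: every principal axis carries
        # the same variance, so explained-variance fractions are 1/3 each
        # (closed-form eigendecomposition oracle; any orthonormal basis valid)
        X = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        )
        fm = make_matrix(np.array([0, 1, 1, 0]), X)
        scores, pca = compute_block_pcs(fm, "clinical", 3)
        assert np.allclose(pca.explained_variance, 4 / 3, atol=1e-10)
        fractions = pca.explained_variance / pca.explained_variance.sum()
        assert np.allclose(fractions, 1 / 3, atol=1e-10)

    def test_default_cohort_ten_pcs(self, small_matrix):
        scores, pca = compute_block_pcs(small_matrix, "genetic", 10)
        assert scores.shape == (small_matrix.n_samples, 10)
        assert (np.diff(pca.explained_variance) <= 1e-12).all()
        # orthonormal loadings
        assert np.allclose(pca.loadings.T @ pca.loadings, np.eye(10), atol=1e-8)


class TestResidualize:
    def test_perfect_covariate_zeroes_feature(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        fm = make_matrix(np.array([0, 1] * 10), x[:, None])
        resid, _ = residualize(fm, x[:, None])
        assert np.abs(resid.values).max() < 1e-10

    def test_zero_covariates_mean_center(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(15, 4))
        fm = make_matrix(np.array([0, 1, 1] * 5), values)
        with pytest.warns(UserWarning, match="dependent"):
            resid, _ = residualize(fm, np.zeros((15, 2)))
        assert np.allclose(resid.values, values - values.mean(0), atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(50, 5))
        Z = rng.normal(size=(50, 2))
        fm = make_matrix(rng.integers(0, 2, 50), Y)
        resid, coef = residualize(fm, Z)
        design = np.column_stack([np.ones(50), Z])
        beta = np.linalg.solve(design.T @ design, design.T @ Y)
        assert np.allclose(resid.values, Y - design @ beta, atol=1e-8)
        # residuals orthogonal to every covariate column
        assert np.abs(resid.values.T @ Z).max() < 1e-8

    def test_idempotence(self):
        rng = np.random.default_rng(3)
        fm = make_matrix(rng.integers(0, 2, 30), rng.normal(size=(30, 4)))
        Z = rng.normal(size=(30, 2))
        once, _ = residualize(fm, Z)
        twice, _ = residualize(once, Z)
        assert np.allclose(once.values, twice.values, atol=1e-10)

    def test_heldout_uses_training_coefficients(self):
        rng = np.random.default_rng(4)
        fm = make_matrix(rng.integers(0, 2, 30), rng.normal(size=(30, 3)))
        Z = rng.normal(size=(30, 2))
        _, coef = residualize(fm, Z)
        held = make_matrix(rng.integers(0, 2, 10), rng.normal(size=(10, 3)), seed=9)
        Zh = rng.normal(size=(10, 2))
        resid_h, coef_h = residualize(held, Zh, coefficients=coef)
        assert coef_h is coef  # no refit
        design = np.column_stack([np.ones(10), Zh])
        assert np.allclose(resid_h.values, held.values - design @ coef, atol=1e-10)


class TestZTransform:
    def test_hand_computed_column(self):
        fm = make_matrix(np.array([0, 1, 1]), np.array([[1.0], [2.0], [3.0]]))
        out, params = z_transform(fm)
        # population sd of [1,2,3] is sqrt(2/3)
        assert np.allclose(
            out.values[:, 0], [-1.224744871391589, 0.0, 1.224744871391589]
        )

    def test_train_moments_and_idempotence(self, small_matrix):
        out, params = z_transform(small_matrix)
        cont = [f for f in small_matrix.feature_names if f in params.mean]
        sub = out.subset_features(cont)
        assert np.abs(sub.values.mean(0)).max() < 1e-10
        assert np.abs(sub.values.std(0) - 1).max() < 1e-10
        again, _ = z_transform(out)
        assert np.allclose(again.values, out.values, atol=1e-10)

    def test_binary_passthrough_and_constant_flagging(self):
        values = np.column_stack(
            [np.array([0, 1, 0, 1.0]), np.full(4, 3.0), np.arange(4.0)]
        )
        fm = make_matrix(np.array([0, 1, 0, 1]), values)
        with pytest.warns(UserWarning, match="zero-variance"):
            out, params = z_transform(fm)
        assert "F0" in params.passthrough
        assert "F1" in params.zero_variance
        assert np.array_equal(out.values[:, 0], values[:, 0])
        assert np.array_equal(out.values[:, 1], values[:, 1])

    def test_stored_params_applied_to_heldout(self, small_matrix):
        train = small_matrix.subset_samples(np.arange(0, 100))
        held = small_matrix.subset_samples(np.arange(100, 140))
        _, params = z_transform(train)
        out, _ = z_transform(held, params)
        name = next(iter(params.mean))
        j = list(held.feature_names).index(name)
        expect = (held.values[:, j] - params.mean[name]) / params.sd[name]
        assert np.allclose(out.values[:, j], expect)


class TestSelectFeatures:
    def test_dominant_signal_ranked_first(self):
        rng = np.random.default_rng(0)
        hits = 0
        for seed in range(10):
            y = rng.integers(0, 2, 80)
            y[:2] = [0, 1]
            X = rng.normal(size=(80, 21))
            X[:, 0] = y + 0.01 * rng.normal(size=80)  # perfectly separating
            fm = make_matrix(y, X, seed=seed)
            sel = select_features(fm, n_trees=128, seed=seed)
            hits += sel[0] == "F0"
        assert hits >= 9

    def test_duplicate_columns_pruned_to_one(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        signal = y + 0.1 * rng.normal(size=60)
        X = np.column_stack([signal, signal.copy(), rng.normal(size=(60, 5))])
        fm = make_matrix(y, X)
        sel = select_features(fm, n_trees=64, corr_threshold=0.9, seed=0)
        assert ("F0" in sel) != ("F1" in sel)  # exactly one survives

    def test_causal_feature_retention(self):
        """Genetics-driven cohorts: the detectable causal SNPs survive
        selection (median over 10 seeds, threshold from pre-build
        calibration — a quarter of Gaussian-drawn effects are too small to
        detect at n=600)."""
        retained = []
        for seed in range(10):
            spec = CohortSpec(
                200, 400, beta_scale_genetic=1.2, beta_scale_expr=0.0,
                beta_scale_clin=0.0, expr_disease_loading=0.0,
                noise_sd=0.3, seed=seed,
            )
            fm, gt = generate_cohort(spec)
            fmz, _ = z_transform(fm)
            sel = select_features(fmz, n_trees=256, keep=50, seed=seed)
            gnames = fm.feature_names[fm.group_columns("genetic")]
            causal = set(gnames[gt.causal_snp_index])
            retained.append(len(causal & set(sel)))
        assert np.median(retained) >= 12

    def test_keep_overflow_warns(self, small_matrix):
        with pytest.warns(UserWarning, match="survivors"):
            sel = select_features(
                small_matrix, n_trees=16, corr_threshold=0.01, keep=10_000, seed=0
            )
        assert len(sel) <= small_matrix.n_features


class TestPreprocessorChain:
    def test_fit_transform_consistency(self, small_matrix):
        pre = Preprocessor(n_pcs=3)
        out1 = pre.fit_transform(small_matrix)
        out2 = pre.transform(small_matrix)
        assert np.allclose(out1.values, out2.values)

    def test_no_heldout_leakage(self, small_matrix):
        """Fitted parameters must be a function of training data only."""
        train = small_matrix.subset_samples(np.arange(0, 100))
        pre = Preprocessor(n_pcs=3).fit(train)
        held = small_matrix.subset_samples(np.arange(100, 140))
        mutated = held.copy()
        mutated.values = mutated.values + 100.0
        pre2 = Preprocessor(n_pcs=3).fit(train)  # refit; held-out never seen
        assert np.allclose(pre.pca_genetic.loadings, pre2.pca_genetic.loadings)
        assert pre.z_params.mean == pre2.z_params.mean
        # and transform is linear in the held-out values, using train stats
        a = pre.transform(held)
        b = pre.transform(mutated)
        assert not np.allclose(a.values, b.values)
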