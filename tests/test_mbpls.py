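import numpy as np
import pandas as pd
import pytest

from oralblocks import (
    MBPLSModel,
    MultiblockDataset,
    VariableBlock,
    block_importance,
    explained_inertia,
    fit_mbpls,
    preprocess,
)

from _oracles import nipals_pls2, standardize_block
from conftest import random_multiblock


def make_dataset(X_blocks, Y, names=None):
    n = Y.shape[0]
    idx = pd.Index([f"S{i:02d}" for i in range(n)], name="subject_id")
    y = VariableBlock(
        "Y", "response",
        pd.DataFrame(Y, index=idx, columns=[f"y{j}" for j in range(Y.shape[1])]),
    )
    xs = []
    for i, X in enumerate(X_blocks):
        name = names[i] if names else f"X{i + 1}"
        xs.append(
            VariableBlock(
                name, "predictor",
                pd.DataFrame(X, index=idx, columns=[f"{name}_v{j}" for j in range(X.shape[1])]),
            )
        )
    return MultiblockDataset(y=y, x_blocks=xs)


class TestPreprocess:
    def test_every_block_has_unit_total_ss(self, study_dataset):
        pp = preprocess(study_dataset)
        for name in pp.block_names:
            assert np.sum(pp.arrays[name] ** 2) == pytest.approx(1.0, abs=1e-12)
            np.testing.assert_allclose(pp.arrays[name].mean(axis=0), 0, atol=1e-14)

    def test_single_variable_block(self):
        rng = np.random.default_rng(0)
        ds = make_dataset([rng.standard_normal((10, 1))], rng.standard_normal((10, 2)))
        pp = preprocess(ds)
        assert np.sum(pp.arrays["X1"] ** 2) == pytest.approx(1.0, abs=1e-12)

    def test_unequal_block_sizes_balanced(self):
        rng = np.random.default_rng(1)
        ds = make_dataset(
            [rng.standard_normal((15, 3)), rng.standard_normal((15, 30))],
            rng.standard_normal((15, 2)),
        )
        pp = preprocess(ds)
        assert np.sum(pp.arrays["X1"] ** 2) == pytest.approx(
            np.sum(pp.arrays["X2"] ** 2), abs=1e-12
        )

    def test_zero_variance_variable_named_in_error(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((10, 3))
        X[:, 1] = 5.0
        ds = make_dataset([X], rng.standard_normal((10, 2)))
        with pytest.raises(ValueError, match="X1_v1"):
            preprocess(ds)

    def test_missing_values_rejected(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((10, 3))
        X[0, 0] = np.nan
        ds = make_dataset([X], rng.standard_normal((10, 2)))
        with pytest.raises(ValueError, match="impute"):
            preprocess(ds)


class TestFit:
    def test_single_block_equals_ordinary_pls(self):
        """With one predictor block, MB-PLS degenerates to PLS2."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n, p, q = 18, 6, 3
            ds = make_dataset([rng.standard_normal((n, p))], rng.standard_normal((n, q)))
            model = fit_mbpls(ds, 3)
            Xs = standardize_block(ds.x_blocks[0].values.to_numpy())
            Ys = standardize_block(ds.y.values.to_numpy())
            T, W, _, _ = nipals_pls2(Xs, Ys, 3)
            for h in range(3):
                sign = np.sign(T[:, h] @ model.super_scores[:, h])
                np.testing.assert_allclose(
                    model.super_scores[:, h], sign * T[:, h], atol=1e-8
                )
                np.testing.assert_allclose(
                    model.block_weights["X1"][:, h], sign * W[:, h], atol=1e-8
                )

    def test_concatenation_equivalence(self):
        """Super scores equal PLS2 scores on the concatenated scaled blocks."""
        for seed in range(5):
            ds = random_multiblock(seed, n=25, block_sizes=(4, 6, 3, 5))
            model = fit_mbpls(ds, 3)
            Xc = np.hstack(
                [standardize_block(b.values.to_numpy()) for b in ds.x_blocks]
            )
            Ys = standardize_block(ds.y.values.to_numpy())
            T, W, _, _ = nipals_pls2(Xc, Ys, 3)
            for h in range(3):
                sign = np.sign(T[:, h] @ model.super_scores[:, h])
                np.testing.assert_allclose(
                    model.super_scores[:, h], sign * T[:, h], atol=1e-8
                )

    def test_noise_free_rank1_explains_y(self):
        rng = np.random.default_rng(7)
        n = 30
        z = rng.standard_normal((n, 1))
        X1 = z @ rng.standard_normal((1, 5))
        X1 += 1e-9 * rng.standard_normal(X1.shape)  # avoid exact zero variance noise dims
        Y = z @ rng.standard_normal((1, 4))
        ds = make_dataset([X1], Y)
        model = fit_mbpls(ds, 1)
        assert model.explained_inertia_y[0] >= 99.99

    def test_super_score_orthogonality(self, study_dataset):
        model = fit_mbpls(study_dataset, 4)
        T = model.super_scores
        G = T.T @ T
        norms = np.sqrt(np.diag(G))
        off = G / np.outer(norms, norms) - np.eye(4)
        assert np.max(np.abs(off)) < 1e-10

    def test_deterministic_refit(self, study_dataset):
        m1 = fit_mbpls(study_dataset, 3)
        m2 = fit_mbpls(study_dataset, 3)
        np.testing.assert_array_equal(m1.super_scores, m2.super_scores)
        np.testing.assert_array_equal(m1.y_loadings, m2.y_loadings)

    def test_h_too_large_rejected(self, study_dataset):
        with pytest.raises(ValueError, match="n_components"):
            fit_mbpls(study_dataset, 48)

    def test_sklearn_cross_check(self):
        """Concatenated-matrix scores also agree with scikit-learn's PLS."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        ds = random_multiblock(3, n=22, block_sizes=(4, 5))
        model = fit_mbpls(ds, 2)
        Xc = np.hstack([standardize_block(b.values.to_numpy()) for b in ds.x_blocks])
        Ys = standardize_block(ds.y.values.to_numpy())
        ref = sklearn.PLSRegression(
            n_components=2, scale=False, tol=1e-14, max_iter=50000
        ).fit(Xc, Ys)
        for h in range(2):
            sign = np.sign(ref.x_scores_[:, h] @ model.super_scores[:, h])
            np.testing.assert_allclose(
                model.super_scores[:, h], sign * ref.x_scores_[:, h], atol=1e-7
            )


class TestBlockImportance:
    def test_columns_sum_to_one(self, study_dataset):
        model = fit_mbpls(study_dataset, 3)
        imp = model.block_importance
        np.testing.assert_allclose(imp.sum(axis=0), 1.0, atol=1e-10)
        assert np.all(imp >= 0)

    def test_identical_blocks_share_importance(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((20, 4))
        Y = rng.standard_normal((20, 3))
        ds = make_dataset([X.copy(), X.copy(), X.copy()], Y)
        model = fit_mbpls(ds, 2)
        np.testing.assert_allclose(model.block_importance, 1 / 3, atol=1e-8)

    def test_block_permutation_equivariance(self):
        ds = random_multiblock(13, n=24, block_sizes=(4, 6, 3))
        model = fit_mbpls(ds, 2)
        permuted = MultiblockDataset(
            y=ds.y, x_blocks=[ds.x_blocks[2], ds.x_blocks[0], ds.x_blocks[1]]
        )
        model_p = fit_mbpls(permuted, 2)
        imp = block_importance(model)
        imp_p = block_importance(model_p)
        for name in imp.index:
            np.testing.assert_allclose(imp.loc[name], imp_p.loc[name], atol=1e-10)

    def test_signal_block_dominates(self):
        rng = np.random.default_rng(17)
        n = 200
        z = rng.standard_normal((n, 1))
        signal = z @ rng.standard_normal((1, 5))
        blocks = [signal + 0.1 * rng.standard_normal((n, 5))]
        blocks += [rng.standard_normal((n, 5)) for _ in range(4)]
        Y = z @ rng.standard_normal((1, 3)) + 0.1 * rng.standard_normal((n, 3))
        ds = make_dataset(blocks, Y)
        model = fit_mbpls(ds, 1)
        assert model.block_importance[0, 0] > 0.9


class TestInertia:
    def test_full_rank_noise_free_cumulates_to_100(self):
        rng = np.random.default_rng(19)
        n, p = 20, 4
        X = rng.standard_normal((n, p))
        B = rng.standard_normal((p, 3))
        Y = X @ B  # Y lies exactly in the span of X
        ds = make_dataset([X], Y)
        model = fit_mbpls(ds, p)
        assert model.explained_inertia_y.sum() == pytest.approx(100.0, abs=1e-8)

    def test_nonnegative_and_bounded(self, study_dataset):
        model = fit_mbpls(study_dataset, 4)
        table = explained_inertia(model)
        assert (table.values >= -1e-12).all()
        assert (table.values.sum(axis=1) <= 100 + 1e-8).all()

    def test_y_inertia_matches_projection_oracle(self, study_dataset):
        """Summed per-dimension Y inertia equals the least-squares
        projection of preprocessed Y onto the score space."""
        model = fit_mbpls(study_dataset, 3)
        pp = preprocess(study_dataset)
        Y0 = pp.arrays["Y"]
        T = model.super_scores
        proj = T @ np.linalg.lstsq(T, Y0, rcond=None)[0]
        expected = 100.0 * np.sum(proj**2) / np.sum(Y0**2)
        assert model.explained_inertia_y.sum() == pytest.approx(expected, abs=1e-8)


class TestPredict:
    def test_training_rows_reconstruct(self, study_dataset):
        model = fit_mbpls(study_dataset, 3)
        pred = model.predict(study_dataset)
        pp = model.preprocessing
        recon_pre = np.zeros_like(pp.arrays["Y"])
        for h in range(3):
            recon_pre += np.outer(model.super_scores[:, h], model.y_loadings[:, h])
        recon = pp.inverse_transform_block("Y", recon_pre)
        np.testing.assert_allclose(pred, recon, atol=1e-10)

    def test_centered_input_predicts_y_means(self, study_dataset):
        model = fit_mbpls(study_dataset, 3)
        x_means = {
            b.name: b.values.mean(axis=0).to_numpy()[None, :]
            for b in study_dataset.x_blocks
        }
        pred = model.predict(x_means)
        np.testing.assert_allclose(
            pred[0], study_dataset.y.values.mean(axis=0).to_numpy(), atol=1e-10
        )

    def test_noise_free_heldout_prediction(self):
        rng = np.random.default_rng(23)
        n = 40
        z = rng.standard_normal((n, 1))
        X = z @ rng.standard_normal((1, 6)) + 1e-10 * rng.standard_normal((n, 6))
        Y = z @ rng.standard_normal((1, 3))
        ds = make_dataset([X], Y)
        train = ds.drop_rows([ds.subject_ids[-1]])
        model = fit_mbpls(train, 1)
        held = {b.name: b.values.iloc[[-1]].to_numpy() for b in ds.x_blocks}
        pred = model.predict(held)
        np.testing.assert_allclose(
            pred[0], ds.y.values.iloc[-1].to_numpy(), atol=1e-6
        )

    def test_schema_mismatch_lists_offenders(self, study_dataset):
        model = fit_mbpls(study_dataset, 2)
        bad = {b.name: b.values.to_numpy()[:, :-1] for b in study_dataset.x_blocks}
        with pytest.raises(ValueError, match="X1"):
            model.predict(bad)


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, study_dataset, tmp_path):
        model = fit_mbpls(study_dataset, 3)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = MBPLSModel.load(path)
        np.testing.assert_allclose(
            loaded.predict(study_dataset), model.predict(study_dataset), atol=1e-12
        )
        np.testing.assert_allclose(
            loaded.block_importance, model.block_importance, atol=1e-15
        )
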