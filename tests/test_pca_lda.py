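import numpy as np
import pytest

from specsplit.data import SpectralDataset
from specsplit.pca_lda import (CvCurve, classify, fit_lda, fit_pca,
                               fit_pca_lda, lda_score, predict, project,
                               select_n_pcs, venetian_blinds_cv)
from specsplit.simulate import make_fixture

from conftest import random_dataset


# ---------------------------------------------------------------------------
# independent naive CV oracle (explicit loops, explicit inverse, fresh SVD
# per component count; shares no code with the implementation under test)

def naive_cv_error(X, labels, max_pcs, n_splits=10):
    n = len(X)
    errors = []
    for k in range(1, max_pcs + 1):
        wrong = total = 0
        for f in range(n_splits):
            tr = [i for i in range(n) if i % n_splits != f]
            te = [i for i in range(n) if i % n_splits == f]
            Xtr, ytr = X[tr], labels[tr]
            mean = Xtr.mean(axis=0)
            _, _, vt = np.linalg.svd(Xtr - mean, full_matrices=False)
            V = vt[:k].T
            Str = (Xtr - mean) @ V
            classes = list(dict.fromkeys(ytr))
            mus = {c: Str[ytr == c].mean(axis=0) for c in classes}
            scat = sum((Str[ytr == c] - mus[c]).T @ (Str[ytr == c] - mus[c])
                       for c in classes)
            C = scat / (len(tr) - len(classes))
            Cinv = np.linalg.inv(C)
            for i in te:
                s = (X[i] - mean) @ V
                L = [float((s - mus[c]) @ Cinv @ (s - mus[c])) for c in classes]
                pred = classes[int(np.argmin(L))]
                wrong += int(pred != labels[i])
                total += 1
        errors.append(wrong / total)
    return np.array(errors)


class TestFitPca:
    def test_collinear_data_k1_explains_everything(self):
        t = np.linspace(0, 1, 8)
        X = np.column_stack([t, 2 * t])
        m = fit_pca(X, 1)
        assert np.allclose(m.explained_variance_ratio, [1.0])

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((10, 6))
        m = fit_pca(X, 6)
        scores = project(m, X)
        assert np.allclose(scores @ m.loadings.T + m.mean_spectrum, X, atol=1e-8)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(1)
        m = fit_pca(rng.standard_normal((15, 8)), 5)
        assert np.allclose(m.loadings.T @ m.loadings, np.eye(5), atol=1e-8)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((12, 7))
        scores = project(fit_pca(X, 4), X)
        g = scores.T @ scores
        assert np.allclose(g - np.diag(np.diag(g)), 0, atol=1e-8)

    def test_evr_non_increasing_and_bounded(self):
        rng = np.random.default_rng(3)
        m = fit_pca(rng.standard_normal((20, 10)), 8)
        evr = m.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert np.all((evr >= 0) & (evr <= 1)) and evr.sum() <= 1 + 1e-12

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_independent_svd_route(self, trial):
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(trial)
        X = rng.standard_normal((20, 10))
        k = 4
        ours = fit_pca(X, k)
        ref = sklearn.PCA(n_components=k).fit(X)
        for j in range(k):  # sign conventions may differ per column
            a, b = ours.loadings[:, j], ref.components_[j]
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)
        assert np.allclose(ours.explained_variance_ratio,
                           ref.explained_variance_ratio_, atol=1e-8)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.random.default_rng(0).normal(size=(5, 3)), 5)


class TestProject:
    def test_mean_maps_to_zero(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((9, 5))
        m = fit_pca(X, 3)
        assert np.allclose(project(m, m.mean_spectrum), 0, atol=1e-10)

    def test_mean_plus_loading_gives_unit_vector(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((9, 5))
        m = fit_pca(X, 3)
        s = project(m, m.mean_spectrum + m.loadings[:, 1])
        assert np.allclose(s, [0, 1, 0], atol=1e-10)

    def test_dimension_mismatch(self):
        m = fit_pca(np.random.default_rng(0).normal(size=(6, 4)), 2)
        with pytest.raises(ValueError):
            project(m, np.zeros((3, 5)))


class TestFitLda:
    def test_pooled_variance_hand_case(self):
        # classes {0,0,2,2} and {10,10,12,12}: means 1, 11;
        # scatter = 4 + 4 = 8, N - K = 6 -> pooled = 4/3
        scores = np.array([[0.0], [0.0], [2.0], [2.0],
                           [10.0], [10.0], [12.0], [12.0]])
        labels = np.array(["a"] * 4 + ["b"] * 4, dtype=object)
        m = fit_lda(scores, labels)
        assert np.allclose(m.class_means, [[1.0], [11.0]])
        assert np.allclose(m.pooled_cov, [[8.0 / 6.0]])

    def test_denominator_n_option(self):
        scores = np.array([[0.0], [0.0], [2.0], [2.0],
                           [10.0], [10.0], [12.0], [12.0]])
        labels = np.array(["a"] * 4 + ["b"] * 4, dtype=object)
        m = fit_lda(scores, labels, cov_denominator="n")
        assert np.allclose(m.pooled_cov, [[1.0]])

    def test_identical_class_covariances_pool_to_same(self):
        rng = np.random.default_rng(6)
        base = rng.standard_normal((10, 2))
        base -= base.mean(axis=0)
        scores = np.vstack([base, base + 5.0])
        labels = np.array(["a"] * 10 + ["b"] * 10, dtype=object)
        m = fit_lda(scores, labels)
        cls_cov = base.T @ base / 9  # per-class unbiased covariance
        assert np.allclose(m.pooled_cov, cls_cov, atol=1e-8)

    def test_singleton_class_rejected(self):
        scores = np.arange(5.0)[:, None]
        labels = np.array(["a", "a", "a", "a", "b"], dtype=object)
        with pytest.raises(ValueError, match="'b'"):
            fit_lda(scores, labels)

    def test_singular_covariance_advises_fewer_pcs(self):
        scores = np.zeros((8, 2))
        scores[:, 0] = [0, 0, 1, 1, 5, 5, 6, 6]  # second dim constant
        labels = np.array(["a"] * 4 + ["b"] * 4, dtype=object)
        with pytest.raises(np.linalg.LinAlgError, match="PCs"):
            fit_lda(scores, labels)

    def test_score_dim_too_large_rejected(self):
        rng = np.random.default_rng(7)
        scores = rng.standard_normal((6, 4))
        labels = np.array(["a"] * 3 + ["b"] * 3, dtype=object)
        with pytest.raises(ValueError, match="dimension"):
            fit_lda(scores, labels)


class TestLdaScore:
    @pytest.fixture
    def model(self):
        scores = np.array([[0.0, 0.0], [0.0, 2.0], [2.0, 0.0], [2.0, 2.0],
                           [10.0, 10.0], [10.0, 12.0], [12.0, 10.0], [12.0, 12.0]])
        labels = np.array(["a"] * 4 + ["b"] * 4, dtype=object)
        return fit_lda(scores, labels)

    def test_zero_at_class_mean(self, model):
        for k in range(2):
            L = lda_score(model, model.class_means[k])
            assert L[k] == pytest.approx(0.0, abs=1e-12)

    def test_scores_nonnegative(self, model):
        rng = np.random.default_rng(8)
        L = lda_score(model, rng.standard_normal((20, 2)) * 10)
        assert np.all(L >= 0)

    def test_diag_covariance_hand_case(self):
        from specsplit.pca_lda import LdaModel
        m = LdaModel(class_means=np.array([[0.0, 0.0]]),
                     pooled_cov=np.diag([1.0, 4.0]), class_order=["a"])
        # (2,2) with C = diag(1,4): 4/1 + 4/4 = 5
        assert lda_score(m, np.array([2.0, 2.0]))[0] == pytest.approx(5.0)

    def test_identity_covariance_is_squared_euclidean(self):
        from specsplit.pca_lda import LdaModel
        m = LdaModel(class_means=np.array([[1.0, 1.0], [3.0, 0.0]]),
                     pooled_cov=np.eye(2), class_order=["a", "b"])
        x = np.array([2.0, 2.0])
        L = lda_score(m, x)
        assert L[0] == pytest.approx(2.0)
        assert L[1] == pytest.approx(5.0)

    def test_invariance_under_linear_reparameterization(self, model):
        rng = np.random.default_rng(9)
        A = rng.standard_normal((2, 2)) + 2 * np.eye(2)
        from specsplit.pca_lda import LdaModel
        m2 = LdaModel(class_means=model.class_means @ A.T,
                      pooled_cov=A @ model.pooled_cov @ A.T,
                      class_order=model.class_order)
        X = rng.standard_normal((10, 2))
        assert np.allclose(lda_score(model, X), lda_score(m2, X @ A.T), atol=1e-8)


class TestClassify:
    def test_class_means_classified_as_themselves(self):
        ds = make_fixture(n_per_class=10, n_vars=4, separation=8.0, seed=10)
        m = fit_lda(ds.intensities, ds.labels)
        pred = classify(m, m.class_means)
        assert list(pred) == m.class_order

    def test_midpoint_tie_goes_to_first_class(self):
        from specsplit.pca_lda import LdaModel
        m = LdaModel(class_means=np.array([[0.0], [2.0]]),
                     pooled_cov=np.eye(1), class_order=["a", "b"])
        assert classify(m, np.array([[1.0]]))[0] == "a"

    def test_identity_covariance_equals_nearest_centroid(self):
        from specsplit.pca_lda import LdaModel
        rng = np.random.default_rng(11)
        means = rng.standard_normal((3, 4))
        m = LdaModel(class_means=means, pooled_cov=np.eye(4),
                     class_order=["a", "b", "c"])
        X = rng.standard_normal((50, 4))
        pred = classify(m, X)
        # brute-force nearest-mean oracle
        for x, p in zip(X, pred):
            dists = [np.sum((x - mu) ** 2) for mu in means]
            assert p == ["a", "b", "c"][int(np.argmin(dists))]

    def test_permutation_equivariance(self):
        ds = make_fixture(n_per_class=8, n_vars=3, seed=12)
        m = fit_lda(ds.intensities, ds.labels)
        X = np.random.default_rng(13).standard_normal((10, 3))
        perm = np.random.default_rng(14).permutation(10)
        assert list(classify(m, X)[perm]) == list(classify(m, X[perm]))


class TestVenetianBlinds:
    def test_fold_sizes_and_conservation(self):
        # n=20, 10 splits: fold i holds samples i and i+10
        n = 20
        folds = np.arange(n) % 10
        for f in range(10):
            assert int((folds == f).sum()) == 2

    def test_perfectly_separated_zero_error(self):
        ds = make_fixture(n_per_class=10, n_vars=4, separation=20.0, seed=15)
        curve = venetian_blinds_cv(ds.intensities, ds.labels, max_pcs=1)
        assert curve.cv_error[0] == 0.0

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_naive_reimplementation(self, trial):
        rng = np.random.default_rng(100 + trial)
        ds = random_dataset(rng, n_per_class=(15, 15), n_vars=6)
        # interleave classes so every fold keeps both
        order = np.argsort(np.tile(np.arange(15), 2), kind="stable")
        X, y = ds.intensities[order], ds.labels[order]
        curve = venetian_blinds_cv(X, y, max_pcs=3)
        expected = naive_cv_error(X, y, max_pcs=3)
        assert np.allclose(curve.cv_error, expected, atol=1e-12)

    def test_n_splits_exceeding_n_rejected(self):
        ds = make_fixture(n_per_class=3, n_vars=3, seed=16)
        with pytest.raises(ValueError, match="n_splits"):
            venetian_blinds_cv(ds.intensities, ds.labels, 1, n_splits=10)


class TestSelectNPcs:
    def test_smallest_argmin(self):
        c = CvCurve(np.arange(1, 5), np.array([0.3, 0.1, 0.1, 0.2]))
        assert select_n_pcs(c) == 2

    def test_monotone_decreasing_picks_last(self):
        c = CvCurve(np.arange(1, 5), np.array([0.4, 0.3, 0.2, 0.1]))
        assert select_n_pcs(c) == 4

    def test_constant_curve_picks_first(self):
        c = CvCurve(np.arange(1, 5), np.full(4, 0.25))
        assert select_n_pcs(c) == 1


class TestFitPcaLda:
    def test_separated_blobs_train_accuracy_100(self):
        ds = make_fixture(n_per_class=10, n_vars=5, separation=15.0, seed=17)
        model = fit_pca_lda(ds, max_pcs=3)
        assert model.training_accuracy == 100.0
        assert model.n_pcs <= 3

    def test_cv_accuracy_consistent_with_curve(self):
        ds = make_fixture(n_per_class=12, n_vars=6, separation=4.0, seed=18)
        model = fit_pca_lda(ds, max_pcs=4)
        at_k = model.cv_curve.cv_error[model.cv_curve.n_pcs_grid == model.n_pcs]
        assert model.cv_accuracy == pytest.approx(100 * (1 - float(at_k[0])))

    def test_predict_round_trips_serialization(self, tmp_path):
        from specsplit.pca_lda import PcaLdaModel
        ds = make_fixture(n_per_class=10, n_vars=5, separation=6.0, seed=19)
        model = fit_pca_lda(ds, max_pcs=3)
        p = tmp_path / "model.json"
        model.save(p)
        back = PcaLdaModel.load(p)
        assert list(predict(back, ds)) == list(predict(model, ds))
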