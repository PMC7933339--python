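import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA as SklearnPCA

from mwfp import (
    MWFPError,
    OPLSDA,
    cut_clusters,
    hca,
    misassignment_count,
    oplsda,
    pca,
    vip,
)


def brute_force_average_linkage(X):
    """Independent oracle: recompute mean pairwise squared distances at
    every merge over explicit member lists."""
    X = np.asarray(X, float)
    n = len(X)
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    clusters = {i: [i] for i in range(n)}
    heights = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([sq[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return np.array(heights)


class TestHCA:
    def test_two_points_merge_at_their_squared_distance(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        d = hca(X)
        assert d.merges.shape == (1, 4)
        assert d.heights[0] == pytest.approx(25.0)

    def test_two_separated_pairs_merge_last(self):
        X = np.array([[0.0, 0.0], [0.1, 0.0], [10.0, 0.0], [10.1, 0.0]])
        d = hca(X)
        # final merge joins the two pair-clusters
        assert d.merges[-1, 3] == 4
        labels = cut_clusters(d, 2)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_merge_heights_match_brute_force_oracle(self, n):
        rng = np.random.default_rng(n)
        X = rng.normal(size=(n, 4))
        np.testing.assert_allclose(
            hca(X).heights, brute_force_average_linkage(X), atol=1e-10
        )

    def test_merge_heights_match_scipy_average_linkage(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(12, 5))
        ours = hca(X).heights
        theirs = scipy_linkage(pdist(X) ** 2, method="average")[:, 2]
        np.testing.assert_allclose(ours, theirs, atol=1e-8)

    def test_cut_extremes(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 3))
        d = hca(X)
        assert len(set(cut_clusters(d, 6))) == 6
        assert len(set(cut_clusters(d, 1))) == 1
        with pytest.raises(MWFPError):
            cut_clusters(d, 7)

    def test_non_finite_rows_rejected(self):
        with pytest.raises(MWFPError):
            hca(np.array([[1.0, np.inf], [0.0, 0.0]]))

    def test_misassignment_count_is_swap_invariant(self):
        a = [0, 0, 1, 1, 1]
        assert misassignment_count(a, [1, 1, 0, 0, 0]) == 0
        assert misassignment_count(a, [0, 0, 0, 1, 1]) == 1


class TestPCA:
    def test_collinear_points_have_single_component(self):
        t = np.linspace(0, 1, 10)
        X = np.column_stack([2 * t, -t])
        model = pca(X, n_components=1, scaling="center")
        assert model.explained_variance_ratio_[0] == pytest.approx(1.0, abs=1e-10)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(3)
        model = pca(rng.normal(size=(10, 6)))
        gram = model.loadings_.T @ model.loadings_
        np.testing.assert_allclose(gram, np.eye(model.n_components_), atol=1e-8)

    def test_matches_eigendecomposition_oracle_up_to_sign(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 5))
        model = pca(X, scaling="center")
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / (len(X) - 1))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        k = model.n_components_
        for j in range(k):
            dot = abs(model.loadings_[:, j] @ evecs[:, j])
            assert dot == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(
            model.explained_variance_ratio_, evals[:k] / evals.sum(), atol=1e-10
        )
        np.testing.assert_allclose(
            np.abs(model.scores_), np.abs(Xc @ evecs[:, :k]), atol=1e-8
        )

    def test_matches_sklearn_cross_check(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(9, 4))
        ours = pca(X, n_components=3, scaling="center")
        ref = SklearnPCA(n_components=3).fit(X)
        np.testing.assert_allclose(
            ours.explained_variance_ratio_, ref.explained_variance_ratio_, atol=1e-10
        )
        np.testing.assert_allclose(
            np.abs(ours.loadings_), np.abs(ref.components_.T), atol=1e-8
        )

    def test_total_variance_accounted_under_centring(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(7, 4))
        model = pca(X, n_components=4, scaling="center")
        assert model.explained_variance_ratio_.sum() == pytest.approx(1.0, abs=1e-10)

    def test_zero_variance_column_names_offender(self):
        X = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(MWFPError, match="1"):
            pca(X, scaling="uv")

    def test_sklearn_params_protocol(self):
        model = OPLSDA(n_orthogonal=2)
        assert model.get_params()["n_orthogonal"] == 2
        model.set_params(n_orthogonal=0)
        assert model.n_orthogonal == 0


def _two_group_data(seed=0, n=(8, 9), p=12, effect_cols=(0, 3, 5), effect=2.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(sum(n), p))
    y = np.array(["a"] * n[0] + ["b"] * n[1])
    X[y == "b"][:, effect_cols]  # no-op guard for readability
    X[n[0]:, list(effect_cols)] += effect
    return X, y


class TestOPLSDA:
    def test_single_informative_variable_dominates_weights(self):
        rng = np.random.default_rng(7)
        n = 10
        X = np.zeros((2 * n, 4))
        X[:, 0] = np.r_[np.zeros(n), np.ones(n)] + rng.normal(0, 0.01, 2 * n)
        X[:, 1:] = rng.normal(0, 0.01, (2 * n, 3))
        y = ["a"] * n + ["b"] * n
        model = oplsda(X, y, n_orthogonal=0, scaling="center")
        w = np.abs(model.weights_)
        assert w[0] > 0.99

    def test_predictive_scores_orthogonal_to_orthogonal_scores(self):
        X, y = _two_group_data(seed=8)
        model = oplsda(X, y, n_orthogonal=2)
        t = model.scores_
        for j in range(model.ortho_scores_.shape[1]):
            t_o = model.ortho_scores_[:, j]
            cos = abs(t @ t_o) / (np.linalg.norm(t) * np.linalg.norm(t_o))
            assert cos < 1e-8

    def test_zero_orthogonal_components_equal_one_step_pls_oracle(self):
        X, y = _two_group_data(seed=9)
        model = oplsda(X, y, n_orthogonal=0, scaling="center")
        # independent one-step PLS (NIPALS first component by hand)
        Xc = X - X.mean(axis=0)
        yv = np.where(np.asarray(y) == "b", 1.0, -1.0)
        yc = yv - yv.mean()
        w = Xc.T @ yc
        w /= np.linalg.norm(w)
        np.testing.assert_allclose(model.weights_, w, atol=1e-10)
        np.testing.assert_allclose(model.scores_, Xc @ w, atol=1e-10)

    def test_scores_invariant_to_sample_permutation(self):
        X, y = _two_group_data(seed=10)
        rng = np.random.default_rng(11)
        perm = rng.permutation(len(y))
        m1 = oplsda(X, y)
        m2 = oplsda(X[perm], np.asarray(y)[perm])
        s1, s2 = m1.scores_[perm], m2.scores_
        sign = np.sign(s1 @ s2)
        np.testing.assert_allclose(s1, sign * s2, atol=1e-8)

    def test_r2y_high_for_separable_groups(self):
        X, y = _two_group_data(seed=12, effect=4.0)
        model = oplsda(X, y)
        assert 0.8 < model.r2y_ <= 1.0
        assert (model.predict(X) == np.asarray(y)).mean() == 1.0

    def test_design_errors(self):
        with pytest.raises(MWFPError):
            oplsda(np.ones((4, 3)), ["a", "a", "a", "b"])
        with pytest.raises(MWFPError):
            oplsda(np.ones((4, 3)), ["a", "b", "c", "a"])


class TestVIP:
    def test_equal_weights_give_unit_vip(self):
        rng = np.random.default_rng(13)
        n, p = 20, 6
        signal = np.r_[-np.ones(10), np.ones(10)]
        X = np.outer(signal, np.ones(p)) + rng.normal(0, 0.05, (n, p))
        model = oplsda(X, ["a"] * 10 + ["b"] * 10, n_orthogonal=0)
        np.testing.assert_allclose(vip(model), 1.0, atol=0.05)

    def test_mean_squared_vip_is_one(self):
        X, y = _two_group_data(seed=14)
        model = oplsda(X, y)
        assert np.mean(vip(model) ** 2) == pytest.approx(1.0, abs=1e-8)

    def test_unfitted_model_rejected(self):
        with pytest.raises(MWFPError):
            vip(OPLSDA())
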