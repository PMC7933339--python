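"""Multivariate analysis of fingerprint matrices.

Implements the three workhorse chemometric methods applied to the
samples x peaks area matrix:

* agglomerative hierarchical clustering with between-groups (average)
  linkage on squared Euclidean distances,
* principal component analysis on centred or autoscaled data,
* two-class OPLS-DA (orthogonal projections to latent structures
  discriminant analysis) with VIP (variable influence on projection)
  scores.

PCA and OPLS-DA follow the scikit-learn estimator protocol (``fit`` /
``transform`` / ``get_params``) so they compose with sklearn pipelines;
``pca``/``oplsda`` module functions are thin wrappers.  All three
methods are authored here (the clustering/decomposition routines of
scipy and scikit-learn serve only as independent cross-checks in the
test suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import MWFPError
from .peaks import FingerprintMatrix


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, FingerprintMatrix):
        X = X.areas
    elif isinstance(X, pd.DataFrame):
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise MWFPError(f"expected a 2-D matrix, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise MWFPError("matrix contains non-finite values")
    return X


def _scale(X: np.ndarray, scaling: str):
    """Centre (and for 'uv' autoscale) columns; returns (Xs, mean, scale)."""
    if scaling not in ("center", "uv"):
        raise MWFPError(f"scaling must be 'center' or 'uv', got {scaling!r}")
    mean = X.mean(axis=0)
    if scaling == "uv":
        sd = X.std(axis=0, ddof=1)
        zero = np.nonzero(sd <= 0)[0]
        if zero.size:
            raise MWFPError(
                f"cannot autoscale zero-variance column(s) {zero.tolist()}"
            )
    else:
        sd = np.ones(X.shape[1])
    return (X - mean) / sd, mean, sd


# --------------------------------------------------------------------------
# Hierarchical clustering
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Dendrogram:
    """Merge history of an agglomerative clustering.

    ``merges`` has one row per merge: (node_a, node_b, height, size),
    with original observations numbered 0..n-1 and the cluster created
    by merge ``i`` numbered ``n + i`` (the scipy linkage convention).
    """

    merges: np.ndarray
    n_leaves: int

    def __post_init__(self) -> None:
        merges = np.asarray(self.merges, dtype=float)
        if merges.shape != (self.n_leaves - 1, 4):
            raise MWFPError(
                f"expected {self.n_leaves - 1} merges x 4 columns, "
                f"got {merges.shape}"
            )
        object.__setattr__(self, "merges", merges)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def leaf_order(self) -> list:
        """Left-to-right leaf order of the tree (recursive expansion)."""
        n = self.n_leaves

        def expand(node: int) -> list:
            if node < n:
                return [node]
            a, b = int(self.merges[node - n, 0]), int(self.merges[node - n, 1])
            return expand(a) + expand(b)

        return expand(2 * n - 2) if n > 1 else [0]


def hca(
    X,
    metric: str = "squared_euclidean",
    linkage: str = "between_groups_average",
) -> Dendrogram:
    """Agglomerative clustering with average linkage on squared distances.

    The distance between two clusters is the mean of all pairwise
    squared Euclidean distances between their members ("between-groups
    linkage").  The implementation keeps the full average-distance
    matrix and updates it exactly after each merge (Lance-Williams);
    ties break on the smallest pair of node indices, so the result is
    deterministic.
    """
    if metric != "squared_euclidean":
        raise MWFPError(f"unsupported metric {metric!r}")
    if linkage != "between_groups_average":
        raise MWFPError(f"unsupported linkage {linkage!r}")
    X = _as_matrix(X)
    n = X.shape[0]
    if n < 2:
        raise MWFPError("clustering needs at least 2 rows")
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    # active clusters: node id -> (size, row index into the distance table)
    dist = {}
    nodes = list(range(n))
    sizes = {i: 1 for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = sq[i, j]
    merges = np.zeros((n - 1, 4))
    for step in range(n - 1):
        (a, b), height = min(
            dist.items(), key=lambda kv: (kv[1], kv[0][0], kv[0][1])
        )
        new = n + step
        merges[step] = (a, b, height, sizes[a] + sizes[b])
        nodes.remove(a)
        nodes.remove(b)
        for k in nodes:
            da = dist.pop((min(a, k), max(a, k)))
            db = dist.pop((min(b, k), max(b, k)))
            dist[(k, new)] = (sizes[a] * da + sizes[b] * db) / (
                sizes[a] + sizes[b]
            )
        del dist[(a, b)]
        sizes[new] = sizes.pop(a) + sizes.pop(b)
        nodes.append(new)
    return Dendrogram(merges, n)


def cut_clusters(dendro: Dendrogram, k: int) -> np.ndarray:
    """Labels of the k-cluster cut (undoing the last k-1 merges).

    Labels are integers 0..k-1 in order of first appearance.
    """
    n = dendro.n_leaves
    if not 1 <= k <= n:
        raise MWFPError(f"k must lie in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for step in range(n - k):
        a, b = int(dendro.merges[step, 0]), int(dendro.merges[step, 1])
        root = n + step
        parent[find(a)] = root
        parent[find(b)] = root
    raw = [find(i) for i in range(n)]
    relabel: dict = {}
    return np.array([relabel.setdefault(r, len(relabel)) for r in raw])


def misassignment_count(labels_a, labels_b) -> int:
    """Disagreement of two 2-class labelings, minimised over label swap."""
    a = np.asarray(pd.factorize(np.asarray(labels_a))[0])
    b = np.asarray(pd.factorize(np.asarray(labels_b))[0])
    direct = int((a != b).sum())
    return min(direct, a.size - direct)


def heatmap_matrix(matrix: FingerprintMatrix) -> pd.DataFrame:
    """Autoscaled area matrix reordered by row and column dendrograms.

    Rendering is left to the caller; this returns the data a heat map
    would display.
    """
    Z, _, _ = _scale(_as_matrix(matrix), "uv")
    row_order = hca(Z).leaf_order()
    col_order = hca(Z.T).leaf_order() if Z.shape[1] > 1 else [0]
    frame = pd.DataFrame(
        Z,
        index=list(matrix.sample_ids),
        columns=[f"{rt:.3f}" for rt in matrix.peak_rts],
    )
    return frame.iloc[row_order, col_order]


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

class PCA(BaseEstimator):
    """Principal component analysis on centred or autoscaled data.

    Parameters
    ----------
    n_components : int or None
        Number of components to keep; None keeps min(n_samples - 1,
        n_features).
    scaling : {"uv", "center"}
        "uv" autoscales columns to unit variance (the chemometrics
        default); "center" only centres.

    Attributes (after fit)
    ----------------------
    loadings_ : ndarray (n_features, n_components), orthonormal columns
    scores_ : ndarray (n_samples, n_components) of the training data
    explained_variance_ratio_ : fractions of total variance, non-increasing
    mean_, scale_ : the column statistics applied before decomposition
    """

    def __init__(self, n_components: int | None = None, scaling: str = "uv"):
        self.n_components = n_components
        self.scaling = scaling

    def fit(self, X, y=None) -> "PCA":
        X = _as_matrix(X)
        n, p = X.shape
        k_max = min(n - 1, p)
        k = k_max if self.n_components is None else int(self.n_components)
        if not 1 <= k <= k_max:
            raise MWFPError(
                f"n_components must lie in [1, {k_max}] for a {n}x{p} matrix"
            )
        Z, self.mean_, self.scale_ = _scale(X, self.scaling)
        u, s, vt = np.linalg.svd(Z, full_matrices=False)
        var = s**2 / (n - 1)
        total = Z.var(axis=0, ddof=1).sum()
        loadings = vt[:k_max].T
        # deterministic sign: largest-magnitude loading element positive
        for j in range(loadings.shape[1]):
            i = int(np.argmax(np.abs(loadings[:, j])))
            if loadings[i, j] < 0:
                loadings[:, j] = -loadings[:, j]
        self.loadings_ = loadings[:, :k]
        self.explained_variance_ = var[:k]
        self.explained_variance_ratio_ = var[:k] / total
        self.scores_ = Z @ self.loadings_
        self.n_components_ = k
        return self

    def transform(self, X) -> np.ndarray:
        X = _as_matrix(X)
        return (X - self.mean_) / self.scale_ @ self.loadings_

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).scores_


def pca(X, n_components: int | None = None, scaling: str = "uv") -> PCA:
    """Fit a :class:`PCA` model (convenience wrapper)."""
    return PCA(n_components=n_components, scaling=scaling).fit(X)


# --------------------------------------------------------------------------
# OPLS-DA
# --------------------------------------------------------------------------

class OPLSDA(BaseEstimator):
    """Two-class OPLS-DA with one predictive component.

    The class response is encoded +-1 and centred.  For each of
    ``n_orthogonal`` rounds the PLS weight ``w ∝ X'y`` is computed, the
    loading of its score is split into the part orthogonal to ``w``
    (``w_orth ∝ p - (w'p) w``), and X is deflated by the resulting
    orthogonal component.  The final predictive component comes from the
    deflated X; R2Y is the variance of y explained by regressing y on
    the predictive score.

    VIP scores are computed from the predictive component only (the
    usual OPLS-DA reporting convention): with one predictive component
    ``VIP_j = sqrt(p_vars) * |w_j|`` for unit-norm ``w``, so the mean
    squared VIP is exactly 1.

    Attributes (after fit): ``weights_`` (unit-norm predictive weights),
    ``scores_``, ``loadings_``, ``ortho_weights_/scores_/loadings_``,
    ``r2y_``, ``vip_``, ``classes_``.
    """

    def __init__(self, n_orthogonal: int = 1, scaling: str = "uv"):
        self.n_orthogonal = n_orthogonal
        self.scaling = scaling

    def fit(self, X, y) -> "OPLSDA":
        X = _as_matrix(X)
        labels = np.asarray(y)
        classes = np.unique(labels)
        if classes.size != 2:
            raise MWFPError(f"OPLS-DA needs exactly two classes, got {classes}")
        counts = [(labels == c).sum() for c in classes]
        if min(counts) < 2:
            raise MWFPError("each class needs at least 2 samples")
        if self.n_orthogonal < 0:
            raise MWFPError("n_orthogonal must be >= 0")
        yv = np.where(labels == classes[1], 1.0, -1.0)
        self._y_mean = yv.mean()
        yc = yv - self._y_mean
        Z, self.mean_, self.scale_ = _scale(X, self.scaling)
        n, p = Z.shape
        w_o_list, t_o_list, p_o_list = [], [], []
        Xd = Z.copy()
        for _ in range(int(self.n_orthogonal)):
            w = Xd.T @ yc
            w = w / np.linalg.norm(w)
            t = Xd @ w
            p_load = Xd.T @ t / (t @ t)
            w_o = p_load - (w @ p_load) * w
            norm = np.linalg.norm(w_o)
            if norm < 1e-12:
                break  # no orthogonal variation left
            w_o = w_o / norm
            t_o = Xd @ w_o
            p_o = Xd.T @ t_o / (t_o @ t_o)
            Xd = Xd - np.outer(t_o, p_o)
            w_o_list.append(w_o)
            t_o_list.append(t_o)
            p_o_list.append(p_o)
        w = Xd.T @ yc
        w = w / np.linalg.norm(w)
        t = Xd @ w
        p_load = Xd.T @ t / (t @ t)
        b = (t @ yc) / (t @ t)
        resid = yc - b * t
        self.weights_ = w
        self.scores_ = t
        self.loadings_ = p_load
        self.coef_ = b
        self.ortho_weights_ = (
            np.column_stack(w_o_list) if w_o_list else np.empty((p, 0))
        )
        self.ortho_scores_ = (
            np.column_stack(t_o_list) if t_o_list else np.empty((n, 0))
        )
        self.ortho_loadings_ = (
            np.column_stack(p_o_list) if p_o_list else np.empty((p, 0))
        )
        self.r2y_ = 1.0 - (resid @ resid) / (yc @ yc)
        self.vip_ = np.sqrt(p) * np.abs(w)
        self.classes_ = classes
        return self

    def _predictive_scores(self, X) -> np.ndarray:
        X = _as_matrix(X)
        Z = (X - self.mean_) / self.scale_
        for j in range(self.ortho_weights_.shape[1]):
            t_o = Z @ self.ortho_weights_[:, j]
            Z = Z - np.outer(t_o, self.ortho_loadings_[:, j])
        return Z @ self.weights_

    def transform(self, X) -> np.ndarray:
        """Predictive score of new samples (orthogonal variation removed)."""
        return self._predictive_scores(X)

    def decision_function(self, X) -> np.ndarray:
        return self.coef_ * self._predictive_scores(X) + self._y_mean

    def predict(self, X) -> np.ndarray:
        return np.where(
            self.decision_function(X) >= 0, self.classes_[1], self.classes_[0]
        )


def oplsda(X, labels, n_orthogonal: int = 1, scaling: str = "uv") -> OPLSDA:
    """Fit an :class:`OPLSDA` model (convenience wrapper)."""
    return OPLSDA(n_orthogonal=n_orthogonal, scaling=scaling).fit(X, labels)


def vip(model: OPLSDA) -> np.ndarray:
    """VIP vector of a fitted OPLS-DA model (mean squared VIP = 1)."""
    if not hasattr(model, "vip_"):
        raise MWFPError("model is not fitted")
    return model.vip_
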