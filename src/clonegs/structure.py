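"""Discriminant analysis of principal components (DAPC).

The procedure: (1) PCA of the centered dosage matrix (or the
eigen-coordinates of a supplied relationship matrix), retaining the
leading axes whose cumulative variance share reaches a threshold
(default 85%); (2) k-means on the retained scores, with k either fixed or
chosen by minimum BIC over a grid; (3) linear discriminant analysis of the
k-means labels on the retained scores; (4) final labels by
nearest-centroid assignment in discriminant space, keeping the leading
discriminant functions that reach a variance-share threshold (default
94%).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .containers import GenotypeMatrix, KinshipMatrix

__all__ = ["DAPC", "dapc_fit", "cluster_sizes"]


class DAPC(ClusterMixin, BaseEstimator):
    """DAPC clustering estimator.

    Parameters
    ----------
    n_clusters : int or "auto"
        Number of clusters; "auto" picks the minimum-BIC k over
        ``k_grid``.
    pc_variance : float, default 0.85
        Cumulative variance share of retained principal components.
    df_variance : float, default 0.94
        Cumulative variance share of retained discriminant functions.
    k_grid : iterable of int
        Candidate k values for automatic selection (default 2..10).
    n_init : int, default 25
        k-means++ restarts.
    random_state : int or None
        Seed; fixing it fixes labels bit-exactly.

    Attributes
    ----------
    labels_ : ndarray of int
        Final cluster labels (0-based).
    n_clusters_ : int
        Chosen k.
    pc_scores_, pc_variance_ratio_ : retained PCA scores and shares.
    bic_table_ : DataFrame (k, bic) when k was selected automatically.
    df_coefficients_, df_variance_ratio_ : retained discriminant-function
        loadings (on PC scores) and their variance shares.
    cluster_sizes_ : ndarray, label histogram.
    """

    def __init__(
        self,
        n_clusters="auto",
        pc_variance=0.85,
        df_variance=0.94,
        k_grid=tuple(range(2, 11)),
        n_init=25,
        random_state=None,
    ):
        self.n_clusters = n_clusters
        self.pc_variance = pc_variance
        self.df_variance = df_variance
        self.k_grid = k_grid
        self.n_init = n_init
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------
    @staticmethod
    def _coordinates(X):
        """PCA scores + variance shares from dosages or a kinship matrix."""
        if isinstance(X, GenotypeMatrix):
            M = X.dosages
            if np.isnan(M).any():
                M = np.where(np.isnan(M), np.nanmean(M, axis=0), M)
            M = M - M.mean(axis=0)
            pca = PCA()
            scores = pca.fit_transform(M)
            return scores, pca.explained_variance_ratio_
        if isinstance(X, KinshipMatrix):
            X = X.values
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[0] == X.shape[1] and np.allclose(
            X, X.T, atol=1e-8
        ):
            vals, vecs = np.linalg.eigh(X)
            order = np.argsort(vals)[::-1]
            vals, vecs = np.maximum(vals[order], 0.0), vecs[:, order]
            scores = vecs * np.sqrt(vals)
            shares = vals / vals.sum() if vals.sum() > 0 else vals
            return scores, shares
        M = X - X.mean(axis=0)
        pca = PCA()
        return pca.fit_transform(M), pca.explained_variance_ratio_

    @staticmethod
    def _retain(shares, threshold):
        cum = np.cumsum(shares)
        return int(np.searchsorted(cum, threshold - 1e-12) + 1)

    @staticmethod
    def _bic(scores, labels, k):
        # conventional DAPC criterion: n*log(WSS/n) + k*log(n)
        n = len(labels)
        wss = 0.0
        for c in range(k):
            pts = scores[labels == c]
            if len(pts):
                wss += ((pts - pts.mean(axis=0)) ** 2).sum()
        return n * np.log(max(wss, 1e-300) / n) + k * np.log(n)

    def _kmeans(self, scores, k, seed):
        for attempt in range(10):
            km = KMeans(
                n_clusters=k,
                init="k-means++",
                n_init=self.n_init,
                random_state=(seed or 0) + attempt,
            ).fit(scores)
            if len(np.unique(km.labels_)) == k:
                return km.labels_
        raise RuntimeError(f"k-means produced an empty cluster for k={k}")

    # -- API --------------------------------------------------------------
    def fit(self, X, y=None):
        scores, shares = self._coordinates(X)
        n = scores.shape[0]
        npc = min(self._retain(shares, self.pc_variance), scores.shape[1], n - 1)
        pcs = scores[:, :npc]
        self.pc_scores_ = pcs
        self.pc_variance_ratio_ = shares[:npc]

        seed = self.random_state
        if self.n_clusters == "auto":
            rows = []
            for k in self.k_grid:
                if k > n - 1:
                    continue
                labels_k = self._kmeans(pcs, k, seed)
                rows.append({"k": k, "bic": self._bic(pcs, labels_k, k)})
            self.bic_table_ = pd.DataFrame(rows)
            k = int(self.bic_table_.loc[self.bic_table_["bic"].idxmin(), "k"])
        else:
            k = int(self.n_clusters)
            if k > n - 1:
                raise ValueError(f"k={k} exceeds n-1={n - 1}")
            self.bic_table_ = None

        if k == 1:
            self.n_clusters_ = 1
            self.labels_ = np.zeros(n, dtype=int)
            self.df_coefficients_ = np.empty((npc, 0))
            self.df_variance_ratio_ = np.array([])
            self.cluster_sizes_ = np.array([n])
            return self

        km_labels = self._kmeans(pcs, k, seed)
        lda = LinearDiscriminantAnalysis(n_components=min(k - 1, npc))
        df_scores = lda.fit_transform(pcs, km_labels)
        evr = lda.explained_variance_ratio_
        ndf = min(self._retain(evr, self.df_variance), df_scores.shape[1])
        df_scores = df_scores[:, :ndf]

        centroids = np.vstack(
            [df_scores[km_labels == c].mean(axis=0) for c in range(k)]
        )
        dist = ((df_scores[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        # nearest-centroid reassignment; ties resolved to the lowest index
        self.labels_ = np.argmin(dist, axis=1)
        self.n_clusters_ = k
        self.df_coefficients_ = lda.scalings_[:, :ndf]
        self.df_variance_ratio_ = evr[:ndf]
        self.cluster_sizes_ = np.bincount(self.labels_, minlength=k)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def dapc_fit(
    geno_or_kinship,
    k="auto",
    pc_variance_threshold=0.85,
    df_variance_threshold=0.94,
    seed=None,
) -> DAPC:
    """Functional wrapper over :class:`DAPC`."""
    return DAPC(
        n_clusters=k,
        pc_variance=pc_variance_threshold,
        df_variance=df_variance_threshold,
        random_state=seed,
    ).fit(geno_or_kinship)


def cluster_sizes(model: DAPC) -> np.ndarray:
    """Label histogram of a fitted DAPC model (sums to n)."""
    if not hasattr(model, "labels_"):
        raise ValueError("model is not fitted")
    return np.bincount(model.labels_, minlength=model.n_clusters_)
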