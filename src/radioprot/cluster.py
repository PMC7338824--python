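"""Kernel K-means for texture sub-region discovery.

Voxels are clustered on their (standardized) Haralick feature vectors in an
implicit kernel feature space.  Point-to-centroid squared distances are
computed purely from the Gram matrix:

    d^2(x, C) = K(x,x) - 2/|C| sum_{j in C} K(x,j) + 1/|C|^2 sum_{j,l in C} K(j,l)

With the linear kernel this reduces exactly to Lloyd's K-means objective,
which the tests use as an oracle.  Initialization is kernel-space
K-means++-style seeding; the best of ``n_init`` restarts by objective wins,
and the whole procedure is deterministic given ``random_state``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .errors import ParameterError
from .texture import TextureMap, standardize_features

logger = logging.getLogger("radioprot")


def median_bandwidth(X: np.ndarray, subsample: int = 1000, seed: int = 0) -> float:
    """Median pairwise Euclidean distance on a seeded subsample (RBF scale)."""
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    if n > subsample:
        idx = rng.choice(n, size=subsample, replace=False)
        X = X[idx]
    d = pdist(X)
    med = float(np.median(d)) if d.size else 0.0
    return med if med > 0 else 1.0


class KernelKMeans(BaseEstimator, ClusterMixin):
    """Kernel K-means clustering (rbf or linear kernel).

    Parameters
    ----------
    n_clusters : int
        Number of clusters K (>= 2; K = n points is allowed and yields
        objective 0 on distinct points).
    kernel : {'rbf', 'linear'}
    gamma : float or None
        RBF coefficient exp(-gamma ||x-y||^2); None selects
        1 / (2 * median_bandwidth^2) on a seeded <=1000-point subsample.
    n_init : int
        Restarts; the run with the lowest objective is kept.
    max_iter : int
    random_state : int

    Attributes
    ----------
    labels_ : (n,) cluster labels in 0..K-1, every cluster non-empty
    inertia_ : float, sum of squared kernel-space distances to centroids
    n_iter_ : iterations of the winning restart
    gamma_ : the rbf gamma actually used
    """

    def __init__(self, n_clusters: int = 4, kernel: str = "rbf", gamma: float | None = None,
                 n_init: int = 5, max_iter: int = 100, random_state: int = 0,
                 bandwidth_subsample: int = 1000):
        self.n_clusters = n_clusters
        self.kernel = kernel
        self.gamma = gamma
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state
        self.bandwidth_subsample = bandwidth_subsample

    # -- kernel ------------------------------------------------------------
    def _gram(self, X: np.ndarray) -> np.ndarray:
        if self.kernel == "linear":
            self.gamma_ = None
            return X @ X.T
        if self.kernel == "rbf":
            if self.gamma is None:
                sigma = median_bandwidth(X, self.bandwidth_subsample, seed=self.random_state)
                self.gamma_ = 1.0 / (2.0 * sigma * sigma)
            else:
                self.gamma_ = float(self.gamma)
            sq = squareform(pdist(X, "sqeuclidean"))
            return np.exp(-self.gamma_ * sq)
        raise ParameterError(f"unknown kernel {self.kernel!r}")

    # -- seeding -----------------------------------------------------------
    @staticmethod
    def _plusplus_init(K_mat: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
        n = K_mat.shape[0]
        diag = np.diag(K_mat)
        centers = [int(rng.integers(n))]
        # d2 to the nearest chosen center, as single-point clusters
        d2 = diag - 2 * K_mat[:, centers[0]] + diag[centers[0]]
        d2 = np.maximum(d2, 0)
        for _ in range(1, k):
            total = d2.sum()
            if total <= 0:
                unchosen = np.setdiff1d(np.arange(n), centers)
                c = int(rng.choice(unchosen))
            else:
                c = int(rng.choice(n, p=d2 / total))
                if c in centers:  # duplicate point; fall back to any unchosen
                    unchosen = np.setdiff1d(np.arange(n), centers)
                    c = int(rng.choice(unchosen))
            centers.append(c)
            d2 = np.minimum(d2, np.maximum(diag - 2 * K_mat[:, c] + diag[c], 0))
        return np.asarray(centers)

    @staticmethod
    def _dist2(K_mat: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
        """(n, k) squared kernel distances to each cluster mean."""
        n = K_mat.shape[0]
        Z = np.zeros((n, k))
        Z[np.arange(n), labels] = 1.0
        m = Z.sum(axis=0)
        m_safe = np.where(m > 0, m, 1.0)
        KZ = K_mat @ Z
        f = KZ / m_safe
        g = np.einsum("nk,nk->k", Z, KZ) / (m_safe * m_safe)
        d2 = np.diag(K_mat)[:, None] - 2 * f + g[None, :]
        d2[:, m == 0] = np.inf
        return np.maximum(d2, 0)

    def _single_run(self, K_mat: np.ndarray, rng: np.random.Generator):
        n = K_mat.shape[0]
        k = self.n_clusters
        centers = self._plusplus_init(K_mat, k, rng)
        diag = np.diag(K_mat)
        d2c = diag[:, None] - 2 * K_mat[:, centers] + diag[centers][None, :]
        labels = np.argmin(d2c, axis=1)
        labels[centers] = np.arange(k)  # chosen seeds anchor their clusters
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            d2 = self._dist2(K_mat, labels, k)
            new = np.argmin(d2, axis=1)
            # repair empty clusters with the worst-fitting point
            for kk in np.flatnonzero(np.bincount(new, minlength=k) == 0):
                worst = int(np.argmax(d2[np.arange(n), new]))
                new[worst] = kk
                d2[worst, :] = 0  # cannot be stolen again this sweep
            if np.array_equal(new, labels):
                break
            labels = new
        d2 = self._dist2(K_mat, labels, k)
        objective = float(d2[np.arange(n), labels].sum())
        return labels, objective, n_iter

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ParameterError("X must be 2D (n_samples, n_features)")
        if not np.isfinite(X).all():
            raise ParameterError("non-finite values in clustering input")
        n = X.shape[0]
        if self.n_clusters < 2:
            raise ParameterError(f"n_clusters must be >= 2, got {self.n_clusters}")
        if n < self.n_clusters:
            raise ParameterError(f"{n} points < K={self.n_clusters}")
        K_mat = self._gram(X)
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(max(1, self.n_init)):
            labels, obj, n_iter = self._single_run(K_mat, rng)
            if best is None or obj < best[1]:
                best = (labels, obj, n_iter)
        self.labels_, self.inertia_, self.n_iter_ = best
        return self


@dataclass
class ClusterAssignment:
    """Cluster labels over one patient's masked voxels.

    labels are 1..K (every cluster non-empty); ``sites`` carries each voxel's
    site label so heterogeneity summaries can cross-tabulate site x cluster.
    """

    labels: np.ndarray
    sites: np.ndarray
    K: int
    kernel: str
    kernel_params: dict
    seed: int
    objective: float

    def site_cluster_table(self, n_sites: int | None = None) -> np.ndarray:
        """(S, K) counts of voxels per site and cluster."""
        S = int(n_sites or self.sites.max())
        out = np.zeros((S, self.K), dtype=np.int64)
        np.add.at(out, (self.sites - 1, self.labels - 1), 1)
        return out


def kernel_kmeans(features: TextureMap | np.ndarray, K: int, kernel: str = "rbf",
                  seed: int = 0, restarts: int = 5, sites: np.ndarray | None = None,
                  standardize: bool = True) -> ClusterAssignment:
    """Cluster texture features into K sub-regions (best of ``restarts`` runs).

    Accepts a TextureMap (its site labels are carried through) or a plain
    (n, 4) array with explicit ``sites``.  Features are z-scored per feature
    before kernel evaluation unless ``standardize=False``.
    """
    if isinstance(features, TextureMap):
        X = features.features
        sites = features.sites
    else:
        X = np.asarray(features, dtype=float)
        if sites is None:
            sites = np.ones(X.shape[0], dtype=np.int32)
    if standardize:
        X = standardize_features(X)
    est = KernelKMeans(n_clusters=K, kernel=kernel, n_init=restarts, random_state=seed)
    est.fit(X)
    return ClusterAssignment(
        labels=est.labels_ + 1,
        sites=np.asarray(sites),
        K=K,
        kernel=kernel,
        kernel_params={"gamma": est.gamma_},
        seed=seed,
        objective=est.inertia_,
    )
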