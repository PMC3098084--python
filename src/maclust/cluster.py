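"""The eleven sample-clustering methods.

Six hierarchical variants (Euclidean/Manhattan/correlation distance crossed
with Ward and average linkage), k-means with 100 random starts, PAM on
Euclidean or correlation distance, a one-dimensional self-organizing map, and
Gaussian-mixture clustering (EM initialized from a hierarchical partition,
restricted to <= 500 features).  Every method partitions the samples into at
most ``n_clusters`` (default 10) non-empty clusters labelled 1..c by first
appearance; all stochastic methods are reproducible from a seed.

Ward linkage is applied to whatever dissimilarity is supplied (the pragmatic
convention that makes Ward meaningful with Manhattan and correlation
distances); with Euclidean input this is the classical Ward criterion on the
observations.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .structures import FeatureMatrix

__all__ = [
    "CLUSTERING_METHODS",
    "MCLUST_MAX_FEATURES",
    "InvalidMethodError",
    "distance_matrix",
    "cluster",
]

CLUSTERING_METHODS = (
    "hclust.eucl.ward", "hclust.eucl.ave",
    "hclust.manh.ward", "hclust.manh.ave",
    "hclust.corr.ward", "hclust.corr.ave",
    "kmeans", "pam.eucl", "pam.corr", "som", "mclust",
)

#: Gaussian-mixture clustering is only valid after selection to <= 500 features
MCLUST_MAX_FEATURES = 500

_METRICS = {"eucl": "euclidean", "manh": "cityblock", "corr": "correlation"}


class InvalidMethodError(ValueError):
    """A method/feature-count combination outside the method's validity.

    Consumed structurally by grid enumeration; carries ``reason``.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def distance_matrix(f: FeatureMatrix, metric: str) -> np.ndarray:
    """Square symmetric sample–sample distance matrix.

    ``corr`` is 1 − Pearson correlation between sample profiles; constant
    sample rows make the correlation undefined and raise an error naming the
    sample.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {list(_METRICS)}")
    X = f.values
    if X.shape[0] < 2:
        raise ValueError("distance_matrix: need >= 2 samples")
    if metric == "corr":
        if X.shape[1] < 2:
            raise ValueError("correlation distance needs >= 2 features")
        const = X.std(axis=1) == 0
        if const.any():
            bad = f.sample_ids[const][:5]
            raise ValueError(
                f"correlation distance undefined for constant sample(s) {list(bad)}")
    d = squareform(pdist(X, metric=_METRICS[metric]))
    np.fill_diagonal(d, 0.0)
    return d


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Map arbitrary labels to 1..c by order of first appearance."""
    out = np.empty(len(labels), dtype=int)
    seen: dict = {}
    for i, lab in enumerate(labels):
        out[i] = seen.setdefault(lab, len(seen) + 1)
    return out


def _hclust(d: np.ndarray, linkage_method: str, n_clusters: int) -> np.ndarray:
    z = linkage(squareform(d, checks=False),
                method={"ward": "ward", "ave": "average"}[linkage_method])
    return fcluster(z, t=n_clusters, criterion="maxclust")


def _pam(d: np.ndarray, k: int) -> np.ndarray:
    """Partitioning around medoids: greedy BUILD then best-improvement SWAP."""
    n = d.shape[0]
    medoids: list[int] = [int(d.sum(axis=1).argmin())]
    while len(medoids) < k:
        cur = d[:, medoids].min(axis=1)
        gains = np.maximum(cur[None, :] - d, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(gains.argmax()))
    medoids_arr = np.array(sorted(medoids))
    cost = d[:, medoids_arr].min(axis=1).sum()
    improved = True
    while improved:
        improved = False
        best = (0.0, None)
        non_medoids = np.setdiff1d(np.arange(n), medoids_arr)
        for mi, m_ in enumerate(medoids_arr):
            trial = medoids_arr.copy()
            for h in non_medoids:
                trial[mi] = h
                new_cost = d[:, trial].min(axis=1).sum()
                if cost - new_cost > best[0] + 1e-12:
                    best = (cost - new_cost, (mi, h))
        if best[1] is not None:
            mi, h = best[1]
            medoids_arr[mi] = h
            medoids_arr = np.sort(medoids_arr)
            cost = d[:, medoids_arr].min(axis=1).sum()
            improved = True
    return medoids_arr[d[:, medoids_arr].argmin(axis=1)] + 1


def _som_1d(X: np.ndarray, k: int, seed: int, *, epochs: int = 100,
            lr_start: float = 0.05, lr_end: float = 0.01) -> np.ndarray:
    """One-dimensional self-organizing map with k grid units.

    Learning rate decays linearly lr_start → lr_end and the Gaussian
    neighborhood radius shrinks linearly from k/2 to 1 over the epochs.
    """
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    proto = X[rng.choice(n, size=k, replace=n < k)].astype(float)
    proto += rng.normal(0, 1e-6, proto.shape)
    grid = np.arange(k, dtype=float)
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        lr = lr_start + (lr_end - lr_start) * frac
        radius = max(k / 2.0 + (1.0 - k / 2.0) * frac, 1.0)
        for i in rng.permutation(n):
            x = X[i]
            bmu = int(((proto - x) ** 2).sum(axis=1).argmin())
            h = np.exp(-((grid - bmu) ** 2) / (2 * radius ** 2))
            proto += lr * h[:, None] * (x - proto)
    d2 = ((X[:, None, :] - proto[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1) + 1


def _mclust(X: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Gaussian-mixture clustering, EM initialized from Ward/Euclidean
    hierarchical clustering; covariance family in {spherical, diag} by BIC."""
    init = _hclust(squareform(pdist(X)), "ward", k)
    k_eff = len(np.unique(init))
    means = np.vstack([X[init == c].mean(axis=0) for c in np.unique(init)])
    weights = np.array([(init == c).mean() for c in np.unique(init)])
    best = None
    for cov in ("spherical", "diag"):
        gm = GaussianMixture(n_components=k_eff, covariance_type=cov,
                             means_init=means, weights_init=weights,
                             reg_covar=1e-4, max_iter=200,
                             random_state=seed)
        gm.fit(X)
        bic = gm.bic(X)
        if best is None or bic < best[0]:
            best = (bic, gm)
    return best[1].predict(X) + 1


def cluster(
    f: FeatureMatrix,
    method: str,
    *,
    n_clusters: int = 10,
    kmeans_starts: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Partition the samples with one of the eleven methods.

    Returns integer labels 1..c (c <= ``n_clusters``, relabelled by first
    appearance).  Raises :class:`InvalidMethodError` for method/feature-count
    combinations outside a method's validity (the mclust restriction), which
    grid enumeration treats as a structured skip rather than a crash.
    """
    if method not in CLUSTERING_METHODS:
        raise ValueError(f"unknown clustering method {method!r}")
    if f.n_samples < n_clusters:
        raise ValueError(
            f"cluster: {f.n_samples} samples < n_clusters={n_clusters}")
    if method == "mclust" and f.n_features > MCLUST_MAX_FEATURES:
        raise InvalidMethodError(
            f"mclust restricted to <= {MCLUST_MAX_FEATURES} features "
            f"(got {f.n_features})")

    if method.startswith("hclust."):
        _, metric, link = method.split(".")
        labels = _hclust(distance_matrix(f, metric), link, n_clusters)
    elif method == "kmeans":
        km = KMeans(n_clusters=n_clusters, n_init=kmeans_starts,
                    random_state=seed)
        labels = km.fit_predict(f.values) + 1
    elif method.startswith("pam."):
        labels = _pam(distance_matrix(f, method.split(".")[1]), n_clusters)
    elif method == "som":
        labels = _som_1d(f.values, n_clusters, seed)
    elif method == "mclust":
        labels = _mclust(f.values, n_clusters, seed)
    else:  # pragma: no cover
        raise ValueError(method)
    return _relabel(labels)
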