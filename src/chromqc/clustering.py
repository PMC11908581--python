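"""PCA reduction and quality-sensitive k-means clustering.

The preprocessed feature matrix is projected onto its leading principal
components (chosen either as a fixed count or as the smallest count whose
cumulative variance ratio reaches a threshold), k is pre-identified with the
elbow method on the within-cluster-sum-of-squares (WCSS) curve, validated by
the mean silhouette score, and the partition is produced by restarted
k-means in the reduced space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

from .errors import NoElbowError, ParameterError, RankError


@dataclass
class ReducedMatrix:
    """PCA scores plus the full variance-ratio spectrum and loadings."""

    scores: np.ndarray  # n x m component scores
    variance_ratios: np.ndarray  # all available components, non-increasing
    loadings: np.ndarray  # feature x component weights (m columns)
    n_components: int


@dataclass
class ClusterResult:
    """A k-means partition with its selection evidence."""

    k: int
    labels: np.ndarray
    centroids: np.ndarray
    wcss: float
    seed: int
    wcss_curve: dict = field(default_factory=dict)  # k -> WCSS
    mean_silhouette: float = float("nan")


def pca_reduce(matrix, n_components=None, variance_threshold=None) -> ReducedMatrix:
    """Project the centered matrix onto its top principal axes.

    Exactly one of ``n_components`` (fixed m) or ``variance_threshold``
    (smallest m whose cumulative variance ratio reaches the threshold) must
    be given.  The variance ratio of a component is its eigenvalue divided
    by the sum of all eigenvalues.
    """
    X = np.asarray(matrix, float)
    if not np.isfinite(X).all():
        raise ParameterError("matrix contains non-finite values")
    n, p = X.shape
    if (n_components is None) == (variance_threshold is None):
        raise ParameterError("give exactly one of n_components or variance_threshold")
    max_rank = min(n, p)
    full = PCA(n_components=None, svd_solver="full").fit(X)
    ratios = full.explained_variance_ratio_
    if n_components is not None:
        m = int(n_components)
        if not (1 <= m <= max_rank) or m > len(ratios):
            raise RankError(f"cannot extract {m} components from a {n}x{p} matrix")
    else:
        cum = np.cumsum(ratios)
        m = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
        m = min(m, len(ratios))
    if n <= m:
        raise RankError(f"need more rows ({n}) than components ({m})")
    scores = full.transform(X)[:, :m]
    return ReducedMatrix(
        scores=scores,
        variance_ratios=ratios,
        loadings=full.components_[:m].T,
        n_components=m,
    )


def _kmeans(scores, k, seed, n_init=10, max_iter=300, tol=1e-4) -> KMeans:
    return KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    ).fit(scores)


def wcss_curve(scores, k_range, seed, n_init=10) -> dict:
    """Minimised within-cluster sum of squares for each k in ``k_range``
    (best of ``n_init`` restarts)."""
    scores = np.asarray(scores, float)
    n = len(scores)
    curve = {}
    for k in k_range:
        if not (1 <= k <= n):
            raise ParameterError(f"k={k} outside [1, n={n}]")
        curve[int(k)] = float(_kmeans(scores, int(k), seed, n_init=n_init).inertia_)
    return curve


def select_k_elbow(curve: dict) -> int:
    """Elbow selection: the k maximising the second forward difference
    (discrete curvature) of the WCSS curve; ties break to the smaller k.

    Raises :class:`NoElbowError` when no interior point has positive
    curvature (a linear or degenerate curve carries no elbow signal).
    """
    ks = sorted(curve)
    if len(ks) < 4:
        raise ParameterError("elbow selection needs at least 4 curve points")
    if any(ks[i + 1] - ks[i] != ks[1] - ks[0] for i in range(len(ks) - 1)):
        raise ParameterError("k grid must be evenly spaced")
    best_k, best_curv = None, 0.0
    for i in range(1, len(ks) - 1):
        curv = curve[ks[i - 1]] - 2.0 * curve[ks[i]] + curve[ks[i + 1]]
        if curv > best_curv:
            best_k, best_curv = ks[i], curv
    if best_k is None:
        raise NoElbowError(
            "WCSS curve has no positive curvature; no elbow is identifiable "
            f"(curve: {curve})"
        )
    return int(best_k)


def silhouette_validate(scores, labels) -> float:
    """Mean silhouette score of the partition in the clustering space.

    Per point: (b − a) / max(a, b) with a the mean intra-cluster distance
    and b the smallest mean distance to another cluster; points in singleton
    clusters score 0.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ParameterError("silhouette requires at least 2 clusters")
    return float(np.mean(silhouette_samples(np.asarray(scores, float), labels)))


def kmeans_fit(scores, k, seed, n_init=10, max_iter=300, tol=1e-4) -> ClusterResult:
    """Restarted Lloyd k-means with k-means++ seeding; deterministic for a
    fixed seed.  Mean silhouette is attached for k >= 2."""
    if k <= 0:
        raise ParameterError("k must be >= 1")
    scores = np.asarray(scores, float)
    if k > len(scores):
        raise ParameterError(f"k={k} exceeds n={len(scores)}")
    km = _kmeans(scores, int(k), seed, n_init=n_init, max_iter=max_iter, tol=tol)
    sil = silhouette_validate(scores, km.labels_) if k >= 2 else float("nan")
    return ClusterResult(
        k=int(k),
        labels=km.labels_.copy(),
        centroids=km.cluster_centers_.copy(),
        wcss=float(km.inertia_),
        seed=int(seed),
        mean_silhouette=sil,
    )


def relabel_by_feature(labels, values, descending=True):
    """Re-index cluster labels by the cluster mean of ``values`` (default:
    descending, so cluster 0 has the highest mean — used with SNR to make
    reports stable across seeds).  Returns (new_labels, old->new map)."""
    labels = np.asarray(labels)
    values = np.asarray(values, float)
    uniq = np.unique(labels)
    means = {int(c): float(np.nanmean(values[labels == c])) for c in uniq}
    order = sorted(uniq, key=lambda c: means[int(c)], reverse=descending)
    mapping = {int(old): new for new, old in enumerate(order)}
    return np.array([mapping[int(c)] for c in labels]), mapping
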