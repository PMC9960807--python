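"""k-means conformational clustering with sieving and validity indices.

Frames are clustered in the flattened Cα coordinate space after
superposition onto the trajectory-average structure, so Euclidean distance
between feature vectors approximates the pairwise Cα RMSD metric (the
convention used by the CPPTRAJ cluster command) while keeping centroids
well defined.

Sieving: k-means runs on every ``sieve``-th frame from a seeded random
initialization, then the remaining frames are assigned to the nearest
centroid.  The number of clusters is chosen by scanning k over a range and
minimizing the Davies-Bouldin index, with the pseudo-F statistic
(Calinski-Harabasz) as tie-breaker among near-optimal k; the full per-k
index table is always returned so any other rule can be applied.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .geometry import average_structure
from .trajio import Selection, Trajectory

__all__ = [
    "ClusterModel",
    "trajectory_features",
    "kmeans_cluster",
    "davies_bouldin",
    "pseudo_f",
    "ssr_sst",
    "sums_of_squares",
    "select_k",
    "representative_frame",
]

#: Relative DBI band within which k values are considered tied.
_DBI_TIE_REL = 0.05
#: A DBI minimum above this fraction of the scan's median DBI is a shallow
#: valley: no clearly optimal k (featureless data drifts gently with k).
_DBI_VALLEY_FRACTION = 0.7


@dataclasses.dataclass
class ClusterModel:
    """Result of one clustering run plus its validity indices."""

    k: int
    labels: np.ndarray
    centroids: np.ndarray
    representative_frames: np.ndarray
    dbi: float
    psf: float
    ssr_sst: float

    def __post_init__(self) -> None:
        if self.labels.min() < 0 or self.labels.max() >= self.k:
            raise ValueError("labels out of range [0, k)")
        if len(np.unique(self.labels)) != self.k:
            raise ValueError("every cluster must be non-empty")

    @property
    def populations(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


def trajectory_features(traj: Trajectory, selection: Selection | None = None) -> np.ndarray:
    """Flattened fitted Cα coordinates, shape (F, 3*N_sel).

    Frames are superposed onto the iterated trajectory-average structure
    first, so rigid-body motion does not masquerade as a conformational
    change.
    """
    _, fitted = average_structure(traj, selection)
    return fitted.reshape(fitted.shape[0], -1)


def sums_of_squares(features: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """(SSR, SSE, SST): between-cluster, within-cluster and total sums of
    squares about the grand mean.  SSR + SSE = SST by construction."""
    features = np.asarray(features, float)
    labels = np.asarray(labels)
    grand = features.mean(axis=0)
    sst = float(np.sum((features - grand) ** 2))
    sse = 0.0
    ssr = 0.0
    for lab in np.unique(labels):
        members = features[labels == lab]
        centroid = members.mean(axis=0)
        sse += float(np.sum((members - centroid) ** 2))
        ssr += members.shape[0] * float(np.sum((centroid - grand) ** 2))
    return ssr, sse, sst


def davies_bouldin(features: np.ndarray, labels: np.ndarray,
                   centroids: np.ndarray | None = None) -> float:
    """Davies-Bouldin index: mean over clusters of the worst-case
    (s_i + s_j) / d_ij similarity ratio; lower is better.

    s_i is the mean Euclidean distance of members to their centroid and
    d_ij the centroid separation.  Coincident centroids yield +inf.
    """
    features = np.asarray(features, float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2:
        raise ValueError("Davies-Bouldin index requires k >= 2")
    if centroids is None:
        centroids = np.stack([features[labels == lab].mean(axis=0) for lab in uniq])
    scatter = np.array([
        float(np.mean(np.linalg.norm(features[labels == lab] - centroids[i], axis=1)))
        for i, lab in enumerate(uniq)
    ])
    sep = cdist(centroids, centroids)
    total = 0.0
    for i in range(k):
        worst = -np.inf
        for j in range(k):
            if i == j:
                continue
            if sep[i, j] == 0:
                return float("inf")
            worst = max(worst, (scatter[i] + scatter[j]) / sep[i, j])
        total += worst
    return total / k


def pseudo_f(features: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F statistic (SSR/(k-1)) / (SSE/(n-k)); +inf when SSE = 0."""
    labels = np.asarray(labels)
    n = len(labels)
    k = len(np.unique(labels))
    if k < 2:
        raise ValueError("pseudo-F requires k >= 2")
    if n <= k:
        raise ValueError("pseudo-F requires n > k")
    ssr, sse, _ = sums_of_squares(features, labels)
    if sse == 0:
        return float("inf")
    return (ssr / (k - 1)) / (sse / (n - k))


def ssr_sst(features: np.ndarray, labels: np.ndarray) -> float:
    """Explained-variance ratio SSR/SST, in [0, 1]."""
    if np.asarray(features).shape[0] < 2:
        raise ValueError("SSR/SST requires n >= 2")
    ssr, _, sst = sums_of_squares(features, labels)
    if sst == 0:
        raise ValueError("zero total variance: SSR/SST undefined")
    return min(1.0, max(0.0, ssr / sst))


def representative_frame(features: np.ndarray, labels: np.ndarray,
                         centroids: np.ndarray) -> np.ndarray:
    """Per-cluster index of the member frame closest to the centroid.

    Ties are broken toward the lowest frame index (np.argmin convention on
    the member distance vector).
    """
    features = np.asarray(features, float)
    labels = np.asarray(labels)
    out = np.empty(centroids.shape[0], dtype=int)
    for lab in range(centroids.shape[0]):
        members = np.flatnonzero(labels == lab)
        if members.size == 0:
            raise ValueError(f"cluster {lab} is empty")
        dists = np.linalg.norm(features[members] - centroids[lab], axis=1)
        out[lab] = members[int(np.argmin(dists))]
    return out


def kmeans_cluster(features: np.ndarray, k: int, max_iter: int = 1000,
                   sieve: int = 10, seed: int = 2023) -> ClusterModel:
    """Sieved k-means on frame feature vectors.

    k-means (random initial points, seeded) runs on every ``sieve``-th
    frame; all frames are then assigned to the nearest centroid.  Validity
    indices are computed on the full assignment.
    """
    features = np.asarray(features, float)
    n = features.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    sieved = features[::sieve]
    if len(np.unique(sieved, axis=0)) < k:
        raise ValueError(f"k={k} exceeds the number of distinct sieved frames")
    # k-means++ point seeding with many restarts: a short-dwell state may
    # contribute only a couple of sieved frames, and uniform-random point
    # initialization almost never seeds it
    km = KMeans(n_clusters=k, init="k-means++", n_init=50, max_iter=max_iter,
                random_state=seed % (2 ** 31))
    km.fit(sieved)
    centroids = km.cluster_centers_
    labels = np.argmin(cdist(features, centroids), axis=1)
    # renumber clusters by first appearance so labels are deterministic
    order = {old: new for new, old in enumerate(pd.unique(labels))}
    labels = np.array([order[l] for l in labels])
    centroids = centroids[sorted(order, key=order.get)]
    reps = representative_frame(features, labels, centroids)
    dbi = davies_bouldin(features, labels, centroids) if k >= 2 else float("nan")
    psf = pseudo_f(features, labels) if 2 <= k < n else float("nan")
    ratio = ssr_sst(features, labels) if n >= 2 else float("nan")
    return ClusterModel(k=k, labels=labels, centroids=centroids,
                        representative_frames=reps, dbi=dbi, psf=psf,
                        ssr_sst=ratio)


def select_k(features: np.ndarray, k_range: range | list[int] = range(2, 11),
             seed: int = 2023, sieve: int = 10, max_iter: int = 1000,
             ) -> tuple[int, pd.DataFrame, dict[int, ClusterModel]]:
    """Scan k, compute the three validity indices, and choose k_best.

    Rule: k_best minimizes the Davies-Bouldin index; among k whose DBI is
    within 5% (relative) of the minimum, the one with the highest pseudo-F
    wins.  The returned table carries DBI, pSF and SSR/SST for every k plus
    an ``ambiguous`` flag, set when there is no clear optimum: several k tie
    under the DBI rule, or the DBI minimum is a shallow valley (above 70% of
    the scan's median DBI, the signature of a single featureless basin).
    """
    ks = list(k_range)
    models: dict[int, ClusterModel] = {}
    rows = []
    for k in ks:
        m = kmeans_cluster(features, k, max_iter=max_iter, sieve=sieve, seed=seed)
        models[k] = m
        rows.append({"k": k, "dbi": m.dbi, "psf": m.psf, "ssr_sst": m.ssr_sst})
    table = pd.DataFrame(rows)
    finite = table[np.isfinite(table["dbi"])]
    if finite.empty:
        raise ValueError("no k produced a finite Davies-Bouldin index")
    dbi_min = float(finite["dbi"].min())
    tied = finite[finite["dbi"] <= dbi_min * (1.0 + _DBI_TIE_REL)]
    k_best = int(tied.loc[tied["psf"].idxmax(), "k"])
    shallow = dbi_min > _DBI_VALLEY_FRACTION * float(finite["dbi"].median())
    table["ambiguous"] = (len(tied) > 1) or shallow
    table["selected"] = table["k"] == k_best
    return k_best, table, models
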