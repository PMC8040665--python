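"""Hierarchical clustering, gap-statistic model selection, enrichment.

Subjects (or signaling parameters) are clustered agglomeratively; the
number of clusters is chosen by the gap statistic of Tibshirani, Walther
and Hastie — compare log of the pooled within-cluster dispersion

    W_k = sum_r D_r / (2 n_r),   D_r = sum of pairwise squared distances,

against its expectation under B reference datasets drawn uniformly over
each feature's observed range, and pick the smallest k with
Gap(k) >= Gap(k+1) - s_{k+1}.  Cluster composition is scored by the exact
upper-tail hypergeometric test.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom

from ._rng import derive_rng

__all__ = [
    "ClusterTree",
    "hierarchical_cluster",
    "GapCurve",
    "gap_statistic",
    "hypergeom_pvalue",
    "hypergeom_enrichment",
]


@dataclasses.dataclass
class ClusterTree:
    """Agglomerative merge tree with a cut-at-k accessor."""

    Z: np.ndarray  # scipy linkage matrix
    method: str
    metric: str
    n: int

    def labels_at_k(self, k: int) -> np.ndarray:
        if not 1 <= k <= self.n:
            raise ValueError(f"k must be in [1, {self.n}]")
        return fcluster(self.Z, t=k, criterion="maxclust")

    @property
    def heights(self) -> np.ndarray:
        return self.Z[:, 2]


def hierarchical_cluster(
    matrix, metric: str = "euclidean", method: str = "average"
) -> ClusterTree:
    """Agglomerative clustering of the rows of ``matrix``.

    Ties in merge distance are broken deterministically by the underlying
    nearest-neighbor chain (lowest-index pair first), so results are
    reproducible for a fixed row order.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    bad = np.flatnonzero(~np.isfinite(X).all(axis=1))
    if bad.size:
        raise ValueError(f"non-finite values in rows {bad.tolist()}")
    Z = linkage(X, method=method, metric=metric)
    return ClusterTree(Z, method, metric, X.shape[0])


def _log_wk(X: np.ndarray, labels: np.ndarray) -> float:
    """log of the pooled within-cluster dispersion (squared Euclidean)."""
    w = 0.0
    for lab in np.unique(labels):
        block = X[labels == lab]
        if len(block) > 1:
            # sum of pairwise squared distances / (2 n_r) == within-cluster SS
            w += float(((block - block.mean(axis=0)) ** 2).sum())
    return float(np.log(max(w, np.finfo(float).tiny)))


@dataclasses.dataclass
class GapCurve:
    """Gap-statistic curve and the selected number of clusters."""

    k: np.ndarray
    log_wk: np.ndarray
    e_log_wk: np.ndarray
    s_k: np.ndarray
    chosen_k: int

    @property
    def gap(self) -> np.ndarray:
        return self.e_log_wk - self.log_wk

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k,
                "logW": self.log_wk,
                "ElogW": self.e_log_wk,
                "gap": self.gap,
                "s": self.s_k,
                "chosen": self.k == self.chosen_k,
            }
        )

    def plot(self, ax=None):
        """Gap(k) with one-standard-error bars; the chosen k is marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(self.k, self.gap, yerr=self.s_k, marker="o", capsize=3)
        ax.axvline(self.chosen_k, linestyle="--", color="grey")
        ax.set_xlabel("number of clusters k")
        ax.set_ylabel("Gap(k)")
        return ax


def gap_statistic(
    matrix,
    kmax: int,
    B: int = 100,
    seed: int = 0,
    metric: str = "euclidean",
    method: str = "average",
    reference: str = "uniform",
) -> GapCurve:
    """Gap-statistic selection of the cluster count for row clustering.

    ``reference="uniform"`` draws each reference feature uniformly over its
    observed range; ``"pca"`` draws uniformly in the principal-component
    frame and rotates back.
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if not 1 <= kmax < n:
        raise ValueError(f"kmax must be in [1, {n - 1}]")
    if B < 10:
        raise ValueError("B must be >= 10")
    ks = np.arange(1, kmax + 1)

    def logw_curve(M):
        tree = hierarchical_cluster(M, metric=metric, method=method)
        return np.array([_log_wk(M, tree.labels_at_k(k)) for k in ks])

    obs = logw_curve(X)
    rng = derive_rng(seed, "gap-reference")
    if reference == "pca":
        center = X.mean(axis=0)
        _, _, Vt = np.linalg.svd(X - center, full_matrices=False)
        Xp = (X - center) @ Vt.T
        lo, hi = Xp.min(axis=0), Xp.max(axis=0)
    else:
        lo, hi = X.min(axis=0), X.max(axis=0)
    ref = np.empty((B, len(ks)))
    for b in range(B):
        R = rng.uniform(lo, hi, size=X.shape)
        if reference == "pca":
            R = R @ Vt + center
        ref[b] = logw_curve(R)
    e_log = ref.mean(axis=0)
    s_k = ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    gap = e_log - obs
    chosen = int(ks[-1])
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - s_k[i + 1]:
            chosen = int(ks[i])
            break
    return GapCurve(ks, obs, e_log, s_k, chosen)


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k).

    ``N`` universe size, ``K`` category size, ``n`` draw (cluster) size,
    ``k`` observed overlap.
    """
    if K > N or n > N:
        raise ValueError("category or draw larger than universe")
    if k > min(K, n) or k < 0:
        raise ValueError(f"impossible overlap k={k} for K={K}, n={n}")
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrichment(labels, clusters) -> pd.DataFrame:
    """Upper-tail enrichment of every label category in every cluster.

    ``labels`` and ``clusters`` are equal-length sequences over the same
    universe of items.
    """
    labels = np.asarray(labels)
    clusters = np.asarray(clusters)
    if labels.shape != clusters.shape:
        raise ValueError("labels and clusters must have equal length")
    N = labels.size
    rows = []
    for cl in np.unique(clusters):
        in_cluster = clusters == cl
        n = int(in_cluster.sum())
        for cat in np.unique(labels):
            in_cat = labels == cat
            K = int(in_cat.sum())
            k = int((in_cluster & in_cat).sum())
            rows.append(
                {
                    "cluster": cl,
                    "category": cat,
                    "N": N,
                    "K": K,
                    "n": n,
                    "k": k,
                    "p": hypergeom_pvalue(N, K, n, k),
                }
            )
    return pd.DataFrame(rows)
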