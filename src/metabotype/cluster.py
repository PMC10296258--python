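"""Patient subtype discovery by agglomerative clustering.

The primary method is hierarchical clustering with Euclidean distance and
"Ward.D" linkage — the Lance-Williams recurrence with Ward coefficients

    d(i+j, k) = a_i d(i,k) + a_j d(j,k) + b d(i,j),
    a_i = (n_i + n_k) / (n_i + n_j + n_k),
    b   = -n_k / (n_i + n_j + n_k),

applied to the *unsquared* input dissimilarities (the classic hclust
``ward.D`` dialect; ``ward.D2`` — the recurrence on squared distances with
square-rooted heights — is available as an option). Candidate models over a
range of cluster counts are scored with six validity metrics (BIC, AIC,
silhouette, Dunn, Calinski-Harabasz, allocation entropy) and the cluster
count is chosen by metric majority vote. K-means and unsupervised
random-forest-proximity clusterings are provided as sensitivity methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import calinski_harabasz_score, silhouette_samples

K_RANGE = (2, 6)
LOWER_IS_BETTER = ("bic", "aic", "entropy")
HIGHER_IS_BETTER = ("silhouette", "dunn", "calinski_harabasz")
METRICS = LOWER_IS_BETTER + HIGHER_IS_BETTER


@dataclass
class ClusterModel:
    k: int
    labels: np.ndarray
    metrics: dict
    method: str = "hierarchical"
    extras: dict = field(default_factory=dict)


# ------------------------------------------------------------- distances

def pairwise_euclidean(X) -> np.ndarray:
    """Symmetric Euclidean distance matrix over the rows of ``X``."""
    X = np.asarray(X, float)
    if np.isnan(X).any():
        raise ValueError("distance computation requires a complete matrix")
    return squareform(pdist(X, metric="euclidean"))


# ---------------------------------------------------------------- linkage

def ward_linkage(D: np.ndarray, dialect: str = "ward.D") -> np.ndarray:
    """Agglomerate a dissimilarity matrix with Ward linkage.

    Returns a linkage matrix in the usual (n-1, 4) layout: left node, right
    node, merge height, new cluster size; original observations are nodes
    0..n-1 and the cluster formed at step t is node n+t. Ties in the
    minimum merge dissimilarity are broken toward the smallest (left,
    right) node-id pair.
    """
    D = np.asarray(D, float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    if dialect == "ward.D2":
        Z = _scipy_linkage(squareform(D, checks=False), method="ward")
        return Z
    if dialect != "ward.D":
        raise ValueError(f"unknown Ward dialect: {dialect!r}")

    work = D.astype(float).copy()
    np.fill_diagonal(work, np.inf)
    sizes = np.ones(n)
    node_id = np.arange(n)
    active = np.ones(n, dtype=bool)
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        sub = np.where(active[:, None] & active[None, :], work, np.inf)
        mn = np.min(sub)
        rows, cols = np.where(np.triu(sub == mn, 1))
        ids_lo = np.minimum(node_id[rows], node_id[cols])
        ids_hi = np.maximum(node_id[rows], node_id[cols])
        sel = np.lexsort((ids_hi, ids_lo))[0]
        bi, bj = int(rows[sel]), int(cols[sel])
        h = work[bi, bj]
        ni, nj = sizes[bi], sizes[bj]
        left, right = sorted((node_id[bi], node_id[bj]))
        Z[step] = (left, right, h, ni + nj)

        # Lance-Williams update into slot bi
        others = active.copy()
        others[[bi, bj]] = False
        idx = np.flatnonzero(others)
        nk = sizes[idx]
        denom = ni + nj + nk
        new_d = ((ni + nk) / denom * work[bi, idx]
                 + (nj + nk) / denom * work[bj, idx]
                 - nk / denom * h)
        work[bi, idx] = new_d
        work[idx, bi] = new_d
        sizes[bi] = ni + nj
        node_id[bi] = n + step
        active[bj] = False
        work[bj, :] = np.inf
        work[:, bj] = np.inf
    return Z


def cut_tree(Z: np.ndarray, k: int) -> np.ndarray:
    """Labels for ``k`` clusters obtained by undoing the last k-1 merges.

    Label ids are assigned by order of first appearance across samples.
    """
    n = Z.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in 1..{n}, got {k}")
    parent = list(range(2 * n - 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n - k):
        left, right = int(Z[t, 0]), int(Z[t, 1])
        parent[find(left)] = n + t
        parent[find(right)] = n + t
    roots = [find(i) for i in range(n)]
    remap: dict = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        labels[i] = remap.setdefault(r, len(remap))
    return labels


# ---------------------------------------------------------------- metrics

def cluster_metrics(X, labels, D: np.ndarray | None = None) -> dict:
    """The six validity metrics for one candidate partition.

    BIC and AIC are the sum-of-squares information criteria W + ln(n)*k*p
    and W + 2*k*p, where W is the total within-cluster sum of squares and p
    the number of metabolites. Silhouette terms of singleton clusters are
    0; a Dunn denominator of 0 yields +inf (flagged upstream).
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    n, p = X.shape
    ks = np.unique(labels)
    k = len(ks)
    if not 2 <= k <= n - 1:
        raise ValueError("metrics require 2 <= k <= n-1 clusters")
    if D is None:
        D = pairwise_euclidean(X)

    sil = float(np.mean(silhouette_samples(D, labels, metric="precomputed")))

    intra_max = 0.0
    inter_min = np.inf
    for a in ks:
        ia = labels == a
        if ia.sum() > 1:
            intra_max = max(intra_max, float(D[np.ix_(ia, ia)].max()))
        for b in ks:
            if b <= a:
                continue
            ib = labels == b
            inter_min = min(inter_min, float(D[np.ix_(ia, ib)].min()))
    dunn = inter_min / intra_max if intra_max > 0 else np.inf

    W = 0.0
    for a in ks:
        block = X[labels == a]
        W += float(((block - block.mean(axis=0)) ** 2).sum())
    ch = float(calinski_harabasz_score(X, labels))

    counts = np.array([(labels == a).sum() for a in ks], float) / n
    entropy = float(-(counts * np.log(counts)).sum())

    return {
        "bic": W + np.log(n) * k * p,
        "aic": W + 2.0 * k * p,
        "silhouette": sil,
        "dunn": dunn,
        "calinski_harabasz": ch,
        "entropy": entropy,
    }


# ------------------------------------------------------- model selection

def hierarchical_models(X, kmin: int = K_RANGE[0], kmax: int = K_RANGE[1],
                        dialect: str = "ward.D") -> list[ClusterModel]:
    """Fit the Ward tree once and score every k in [kmin, kmax]."""
    X = np.asarray(X, float)
    D = pairwise_euclidean(X)
    Z = ward_linkage(D, dialect=dialect)
    models = []
    for k in range(kmin, kmax + 1):
        labels = cut_tree(Z, k)
        models.append(ClusterModel(
            k=k, labels=labels, metrics=cluster_metrics(X, labels, D),
            method="hierarchical", extras={"linkage": Z}))
    return models


def select_k(models: list[ClusterModel]) -> tuple[int, dict]:
    """Majority vote over the six metrics; ties break toward smaller k.

    Returns the chosen k and the vote table {metric: voted k}.
    """
    if len(models) < 2:
        raise ValueError("need at least two candidate models")
    ks = [m.k for m in models]
    votes: dict = {}
    for metric in METRICS:
        vals = np.array([m.metrics[metric] for m in models], float)
        direction = 1.0 if metric in LOWER_IS_BETTER else -1.0
        order = np.lexsort((ks, direction * vals))
        votes[metric] = ks[order[0]]
    counts = pd.Series(list(votes.values())).value_counts()
    top = counts[counts == counts.max()].index.min()
    return int(top), votes


# --------------------------------------------------- sensitivity methods

def kmeans_cluster(X, k: int, n_restarts: int = 10, seed: int = 0
                   ) -> ClusterModel:
    """Best-of-``n_restarts`` Lloyd k-means from k-means++ starts."""
    if k < 2:
        raise ValueError("k must be >= 2")
    X = np.asarray(X, float)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed,
                algorithm="lloyd").fit(X)
    labels = _first_appearance_relabel(km.labels_)
    metrics = cluster_metrics(X, labels) if k <= X.shape[0] - 1 else {}
    return ClusterModel(k=k, labels=labels, metrics=metrics, method="kmeans",
                        extras={"inertia": float(km.inertia_)})


def rf_proximity_cluster(X, k: int, n_trees: int = 500, seed: int = 0
                         ) -> ClusterModel:
    """Unsupervised random-forest clustering.

    A synthetic contrast set is drawn by independently permuting each
    metabolite's values; a forest classifies real vs synthetic; the
    proximity of two real samples is the fraction of trees placing them in
    the same terminal node; Ward clustering of sqrt(1 - proximity) is cut
    at ``k``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_trees < 50:
        warnings.warn("fewer than 50 trees gives unstable proximities")
    X = np.asarray(X, float)
    rng = np.random.default_rng(seed)
    contrast = np.column_stack([rng.permutation(col) for col in X.T])
    data = np.vstack([X, contrast])
    y = np.r_[np.zeros(len(X)), np.ones(len(contrast))]
    rf = RandomForestClassifier(n_estimators=n_trees,
                                random_state=int(rng.integers(2 ** 31)))
    rf.fit(data, y)
    leaves = rf.apply(X)  # (n, trees)
    n = len(X)
    prox = np.zeros((n, n))
    for t in range(leaves.shape[1]):
        col = leaves[:, t]
        prox += (col[:, None] == col[None, :])
    prox /= leaves.shape[1]
    dissim = np.sqrt(np.clip(1.0 - prox, 0.0, None))
    np.fill_diagonal(dissim, 0.0)
    Z = ward_linkage(dissim)
    labels = cut_tree(Z, k)
    metrics = cluster_metrics(X, labels) if k <= n - 1 else {}
    return ClusterModel(k=k, labels=labels, metrics=metrics, method="rf",
                        extras={"proximity": prox})


def _first_appearance_relabel(labels: np.ndarray) -> np.ndarray:
    remap: dict = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        out[i] = remap.setdefault(lab, len(remap))
    return out
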