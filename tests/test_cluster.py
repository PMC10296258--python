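"""Hierarchical / k-means / random-forest clustering and model selection."""

import itertools
import shutil
import subprocess

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from metabotype.cluster import (
    ClusterModel, cluster_metrics, cut_tree, hierarchical_models,
    kmeans_cluster, pairwise_euclidean, rf_proximity_cluster, select_k,
    ward_linkage,
)


def blobs(seed=0, n=30, sep=8.0, p=2):
    rng = np.random.default_rng(seed)
    half = n // 2
    X = rng.standard_normal((n, p))
    X[half:] += sep
    labels = np.r_[np.zeros(half, int), np.ones(n - half, int)]
    return X, labels


class TestPairwiseEuclidean:
    def test_three_four_five(self):
        D = pairwise_euclidean([[0.0, 0.0], [3.0, 4.0]])
        assert D[0, 1] == pytest.approx(5.0)

    def test_identical_rows_zero(self):
        D = pairwise_euclidean([[1.0, 2.0], [1.0, 2.0]])
        assert D[0, 1] == 0.0

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((4, 5))
        D = pairwise_euclidean(X)
        for i in range(4):
            for j in range(4):
                ref = np.sqrt(((X[i] - X[j]) ** 2).sum())
                assert abs(D[i, j] - ref) < 1e-12


def naive_ward_d(D):
    """Independent recompute-all agglomeration of the unsquared-distance
    Ward recurrence (dictionary-based, O(n^3))."""
    D = np.asarray(D, float)
    n = D.shape[0]
    dist = {(i, j): D[i, j] for i in range(n) for j in range(n) if i < j}
    size = {i: 1 for i in range(n)}
    merges = []
    next_id = n
    while len(size) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        ni, nj = size[i], size[j]
        new = {}
        for k in size:
            if k in (i, j):
                continue
            nk = size[k]
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            denom = ni + nj + nk
            new[k] = ((ni + nk) / denom * dik + (nj + nk) / denom * djk
                      - nk / denom * h)
        merges.append((i, j, h, ni + nj))
        del size[i], size[j]
        dist = {kv: v for kv, v in dist.items()
                if i not in kv and j not in kv}
        for k, v in new.items():
            dist[tuple(sorted((next_id, k)))] = v
        size[next_id] = ni + nj
        next_id += 1
    return merges


class TestWardLinkage:
    def test_coincident_points_merge_at_zero(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        Z = ward_linkage(pairwise_euclidean(X))
        assert Z[0, 2] == pytest.approx(0.0)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_one_dimensional_merge_order(self):
        X = np.array([[0.0], [1.0], [10.0]])
        Z = ward_linkage(pairwise_euclidean(X))
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert {int(Z[1, 0]), int(Z[1, 1])} == {2, 3}

    @pytest.mark.parametrize("seed", range(5))
    def test_against_recompute_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((8, 3))
        D = pairwise_euclidean(X)
        Z = ward_linkage(D)
        ref = naive_ward_d(D)
        for step, (_, _, h, sz) in enumerate(ref):
            assert abs(Z[step, 2] - h) < 1e-10
            assert Z[step, 3] == sz

    def test_heights_monotone(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((15, 4))
            Z = ward_linkage(pairwise_euclidean(X))
            assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_ward_d2_matches_scipy(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import pdist

        rng = np.random.default_rng(2)
        X = rng.standard_normal((12, 3))
        Z = ward_linkage(pairwise_euclidean(X), dialect="ward.D2")
        ref = linkage(pdist(X), method="ward")
        assert np.allclose(Z[:, 2], ref[:, 2])

    def test_asymmetric_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            ward_linkage(D)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript unavailable")
    def test_against_r_hclust(self, tmp_path):
        """Independent oracle: R's hclust(method='ward.D') heights."""
        rng = np.random.default_rng(7)
        X = rng.standard_normal((10, 4))
        D = pairwise_euclidean(X)
        np.savetxt(tmp_path / "X.csv", X, delimiter=",")
        script = tmp_path / "ward.R"
        script.write_text(f"""
X <- as.matrix(read.csv("{tmp_path}/X.csv", header=FALSE))
h <- hclust(dist(X), method="ward.D")
write(h$height, "{tmp_path}/heights.txt", ncolumns=1)
""")
        proc = subprocess.run(["Rscript", str(script)], capture_output=True)
        if proc.returncode != 0:
            pytest.skip("Rscript failed")
        heights = np.loadtxt(tmp_path / "heights.txt")
        Z = ward_linkage(D)
        assert np.allclose(np.sort(Z[:, 2]), np.sort(heights), atol=1e-8)


class TestCutTree:
    def test_extremes(self):
        X, _ = blobs(n=10)
        Z = ward_linkage(pairwise_euclidean(X))
        assert len(np.unique(cut_tree(Z, 1))) == 1
        assert len(np.unique(cut_tree(Z, 10))) == 10
        with pytest.raises(ValueError):
            cut_tree(Z, 11)

    def test_planted_partition_recovered(self):
        X, truth = blobs(seed=3)
        Z = ward_linkage(pairwise_euclidean(X))
        labels = cut_tree(Z, 2)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_partitions_nested_across_k(self):
        X, _ = blobs(seed=4, n=20)
        Z = ward_linkage(pairwise_euclidean(X))
        prev = cut_tree(Z, 2)
        for k in range(3, 8):
            nxt = cut_tree(Z, k)
            # every new cluster must sit inside exactly one previous cluster
            for lab in np.unique(nxt):
                parents = np.unique(prev[nxt == lab])
                assert len(parents) == 1
            prev = nxt


def oracle_metrics(X, labels):
    """From-definition validity metrics for the hand instance."""
    X = np.asarray(X, float)
    n, p = X.shape
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    ks = np.unique(labels)
    sil_terms = []
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            sil_terms.append(0.0)
            continue
        a = D[i, own & (np.arange(n) != i)].mean()
        b = min(D[i, labels == c].mean() for c in ks if c != labels[i])
        sil_terms.append((b - a) / max(a, b))
    inter = min(D[np.ix_(labels == a, labels == b)].min()
                for a in ks for b in ks if a < b)
    intra = max(D[np.ix_(labels == c, labels == c)].max() for c in ks)
    W = sum(((X[labels == c] - X[labels == c].mean(0)) ** 2).sum()
            for c in ks)
    grand = X.mean(0)
    B = sum((labels == c).sum() * ((X[labels == c].mean(0) - grand) ** 2).sum()
            for c in ks)
    k = len(ks)
    props = np.array([(labels == c).mean() for c in ks])
    return {
        "silhouette": float(np.mean(sil_terms)),
        "dunn": inter / intra,
        "calinski_harabasz": (B / (k - 1)) / (W / (n - k)),
        "entropy": float(-(props * np.log(props)).sum()),
        "bic": W + np.log(n) * k * p,
        "aic": W + 2 * k * p,
    }


class TestClusterMetrics:
    def test_separated_blobs_silhouette(self):
        X, truth = blobs(sep=12.0)
        m = cluster_metrics(X, truth)
        assert m["silhouette"] > 0.9

    def test_equal_halves_entropy(self):
        X, truth = blobs()
        m = cluster_metrics(X, truth)
        assert m["entropy"] == pytest.approx(np.log(2), abs=1e-12)

    def test_hand_instance_matches_definition_oracle(self):
        X = np.array([[0.0, 0.0], [0.5, 0.2], [0.1, 0.9],
                      [5.0, 5.0], [5.5, 4.6], [9.0, 1.0]])
        labels = np.array([0, 0, 0, 1, 1, 2])
        got = cluster_metrics(X, labels)
        ref = oracle_metrics(X, labels)
        for key, val in ref.items():
            assert got[key] == pytest.approx(val, abs=1e-9), key


def model(k, **metrics):
    return ClusterModel(k=k, labels=np.zeros(1), metrics=metrics)


def metrics_for(k, best_for):
    """Metric dict making ``k`` win exactly the metrics in best_for."""
    vals = {}
    for m in ("bic", "aic", "entropy"):
        vals[m] = 0.0 if m in best_for else 1.0
    for m in ("silhouette", "dunn", "calinski_harabasz"):
        vals[m] = 1.0 if m in best_for else 0.0
    return vals


class TestSelectK:
    def test_unanimity(self):
        models = [model(2, **metrics_for(2, set("abcdef"))),
                  model(3, **metrics_for(3, set()))]
        # k=2 best on all six metrics
        models[0].metrics = metrics_for(2, {"bic", "aic", "entropy",
                                            "silhouette", "dunn",
                                            "calinski_harabasz"})
        k, votes = select_k(models)
        assert k == 2 and set(votes.values()) == {2}

    def test_five_of_six_majority(self):
        five = {"bic", "entropy", "silhouette", "dunn", "calinski_harabasz"}
        models = [model(2, **metrics_for(2, five)),
                  model(3, **metrics_for(3, {"aic"}))]
        k, votes = select_k(models)
        assert k == 2
        assert sorted(votes.values()).count(2) == 5

    def test_tie_breaks_to_smaller_k(self):
        three = {"bic", "aic", "entropy"}
        other = {"silhouette", "dunn", "calinski_harabasz"}
        models = [model(2, **metrics_for(2, three)),
                  model(3, **metrics_for(3, other))]
        k, votes = select_k(models)
        assert k == 2


class TestKMeans:
    def test_planted_blobs(self):
        X, truth = blobs(seed=5)
        res = kmeans_cluster(X, 2, seed=0)
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_k_equals_n_gives_zero_wss(self):
        X, _ = blobs(n=8)
        res = kmeans_cluster(X, 8, seed=0)
        assert res.extras["inertia"] == pytest.approx(0.0, abs=1e-12)

    def test_exhaustive_two_partition_optimum(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((8, 2))
        res = kmeans_cluster(X, 2, n_restarts=50, seed=0)

        def wss(mask):
            parts = [X[mask], X[~mask]]
            return sum(((p - p.mean(0)) ** 2).sum() for p in parts)

        best = min(
            wss(np.array(bits, bool))
            for bits in itertools.product([0, 1], repeat=8)
            if 0 < sum(bits) < 8
        )
        assert res.extras["inertia"] == pytest.approx(best, rel=1e-9)


class TestRFProximity:
    def test_planted_recovery_across_seeds(self):
        hits = 0
        for seed in range(10):
            X, truth = blobs(seed=seed, n=40, sep=4.0, p=8)
            res = rf_proximity_cluster(X, 2, n_trees=150, seed=seed)
            hits += adjusted_rand_score(truth, res.labels) >= 0.8
        assert hits >= 9

    def test_proximity_symmetric_unit_diagonal(self):
        X, _ = blobs(seed=1, n=20)
        res = rf_proximity_cluster(X, 2, n_trees=60, seed=0)
        P = res.extras["proximity"]
        assert np.allclose(P, P.T)
        assert np.allclose(np.diag(P), 1.0)

    def test_deterministic_given_seed(self):
        X, _ = blobs(seed=2, n=24, p=4)
        a = rf_proximity_cluster(X, 2, n_trees=80, seed=3)
        b = rf_proximity_cluster(X, 2, n_trees=80, seed=3)
        assert np.array_equal(a.labels, b.labels)

    def test_few_trees_warns(self):
        X, _ = blobs(seed=2, n=16)
        with pytest.warns(UserWarning, match="unstable"):
            rf_proximity_cluster(X, 2, n_trees=20, seed=0)


def test_hierarchical_models_deterministic():
    X, _ = blobs(seed=6, n=25, sep=3.0, p=5)
    a = hierarchical_models(X)
    b = hierarchical_models(X)
    for ma, mb in zip(a, b):
        assert np.array_equal(ma.labels, mb.labels)
        assert ma.metrics == mb.metrics
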