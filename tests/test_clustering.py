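import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from phenoclust.clustering import (
    ALGORITHMS,
    Partition,
    align_for_display,
    cluster,
    concordance,
    silhouette_individuals,
    silhouette_profile,
)


def two_blobs(n=100, sep=10.0, sd=0.1, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    X = np.vstack([rng.normal(0, sd, size=(half, 2)),
                   rng.normal(sep, sd, size=(n - half, 2))])
    truth = np.array([0] * half + [1] * (n - half))
    return X, truth


def brute_force_silhouette(X, labels):
    """Textbook per-sample silhouette, straight loops."""
    n = len(labels)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    out = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            out[i] = 0.0
            continue
        a = D[i, own & (np.arange(n) != i)].mean()
        b = min(
            D[i, labels == c].mean()
            for c in set(labels.tolist()) if c != labels[i]
        )
        out[i] = (b - a) / max(a, b)
    return out


class TestCluster:
    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_recovers_planted_blobs(self, algorithm):
        X, truth = two_blobs()
        part = cluster(X, algorithm, 2, seed=0)
        assert adjusted_rand_score(truth, part.labels) == 1.0

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_seed_determinism(self, algorithm):
        X, _ = two_blobs(n=60, sep=3.0, sd=0.8, seed=3)
        a = cluster(X, algorithm, 3, seed=11)
        b = cluster(X, algorithm, 3, seed=11)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_k_one_all_zero(self):
        X, _ = two_blobs(n=20)
        for algorithm in ALGORITHMS:
            part = cluster(X, algorithm, 1, seed=0)
            assert (part.labels == 0).all()

    def test_k_equals_n_singletons(self):
        X = np.arange(6, dtype=float).reshape(-1, 1) * 10
        part = cluster(X, "kmeans", 6, seed=0)
        assert len(set(part.labels.tolist())) == 6

    def test_errors(self):
        X, _ = two_blobs(n=10)
        with pytest.raises(ValueError, match="unknown algorithm"):
            cluster(X, "dbscan", 2)
        with pytest.raises(ValueError, match="exceeds"):
            cluster(X, "kmeans", 11)

    def test_labels_contiguous_from_zero(self):
        X, _ = two_blobs(n=40, sep=4, sd=0.5, seed=5)
        part = cluster(X, "ward", 4, seed=0)
        assert set(part.labels.tolist()) == {0, 1, 2, 3}
        assert part.labels[0] == 0  # first-appearance relabelling


class TestSilhouette:
    def test_profile_prefers_planted_k(self):
        X, _ = two_blobs()
        prof = silhouette_profile(X, "kmeans", range(2, 7), seed=0)
        assert max(prof, key=prof.get) == 2
        assert all(-1 <= v <= 1 for v in prof.values())

    def test_degenerate_coordinates_error(self):
        X = np.zeros((10, 2))
        X[0] = [1.0, 1.0]  # all points identical except one
        with pytest.raises(ValueError):
            silhouette_profile(X, "kmeans", [2, 3], seed=0)

    def test_out_of_range_k(self):
        X, _ = two_blobs(n=10)
        with pytest.raises(ValueError, match="range"):
            silhouette_profile(X, "kmeans", [1], seed=0)

    def test_individuals_match_brute_force(self):
        rng = np.random.default_rng(21)
        for n in (6, 9, 12):
            X = rng.normal(size=(n, 3))
            part = cluster(X, "kmeans", 3, seed=0)
            df = silhouette_individuals(X, part)
            ref = brute_force_silhouette(X, part.labels)
            by_id = dict(zip(df["id"], df["silhouette"]))
            for i, expected in zip(part.ids, ref):
                assert by_id[i] == pytest.approx(expected, abs=1e-9)

    def test_two_blobs_all_strong(self):
        X, _ = two_blobs()
        part = cluster(X, "kmeans", 2, seed=0)
        df = silhouette_individuals(X, part)
        assert (df["silhouette"] > 0.8).all()

    def test_output_grouped_by_cluster(self):
        X, _ = two_blobs(n=30, sep=4, sd=0.5)
        part = cluster(X, "kmeans", 3, seed=0)
        df = silhouette_individuals(X, part)
        assert (df["cluster"].diff().fillna(0) >= 0).all()


class TestConcordance:
    def test_self_concordance_is_diagonal(self):
        part = Partition(ids=list("abcdef"), labels=[0, 0, 1, 1, 2, 2],
                         algorithm="kmeans", k=3)
        table = concordance(part, part)
        np.testing.assert_array_equal(table.counts.values, np.diag([2, 2, 2]))

    def test_hand_enumerated_case(self):
        ref = Partition(ids=list("abcd"), labels=[0, 0, 1, 1],
                        algorithm="kmeans", k=2)
        other = Partition(ids=list("abcd"), labels=[0, 1, 1, 1],
                          algorithm="ward", k=2)
        table = concordance(ref, other)
        np.testing.assert_array_equal(table.counts.values, [[1, 1], [0, 2]])

    def test_marginals_conserved_on_random_partitions(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            n = int(rng.integers(10, 40))
            ids = [f"i{j}" for j in range(n)]
            la = rng.integers(0, 3, n)
            lb = rng.integers(0, 4, n)
            la[:3] = [0, 1, 2]
            lb[:4] = [0, 1, 2, 3]
            pa = Partition(ids=ids, labels=la, algorithm="kmeans", k=3)
            pb = Partition(ids=ids, labels=lb, algorithm="gmm", k=4)
            t = concordance(pa, pb)
            assert t.n == n
            np.testing.assert_array_equal(t.counts.sum(axis=1).values,
                                          pa.sizes())
            np.testing.assert_array_equal(t.counts.sum(axis=0).values,
                                          pb.sizes())

    def test_id_mismatch_error(self):
        pa = Partition(ids=["a", "b"], labels=[0, 1], algorithm="kmeans", k=2)
        pb = Partition(ids=["b", "a"], labels=[0, 1], algorithm="ward", k=2)
        with pytest.raises(ValueError, match="different individuals"):
            concordance(pa, pb)

    def test_align_for_display_permutes_columns_only(self):
        ref = Partition(ids=list("abcdef"), labels=[0, 0, 0, 1, 1, 1],
                        algorithm="kmeans", k=2)
        other = Partition(ids=list("abcdef"), labels=[1, 1, 0, 0, 0, 0],
                          algorithm="ward", k=2)
        t = concordance(ref, other)
        aligned = align_for_display(t)
        assert np.trace(aligned.counts.values) >= np.trace(t.counts.values)
        assert sorted(map(tuple, aligned.counts.T.values.tolist())) == sorted(
            map(tuple, t.counts.T.values.tolist())
        )


class TestPrecomputedSilhouette:
    def test_precomputed_route_matches_euclidean_on_coordinates(self):
        from scipy.spatial.distance import pdist, squareform

        X, _ = two_blobs(n=30, sep=4, sd=0.5, seed=2)
        D = squareform(pdist(X))
        a = silhouette_profile(X, "kmeans", [2, 3], seed=0)
        b = silhouette_profile(X, "kmeans", [2, 3], seed=0, precomputed=D)
        for k in (2, 3):
            assert a[k] == pytest.approx(b[k])
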