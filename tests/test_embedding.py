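import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from phenoclust.distances import IndividualDistanceMatrix
from phenoclust.embedding import (
    laplacian_eigenmaps,
    metric_mds,
    pcoa,
    resolve_undefined,
    select_dimensions,
    stress1,
    stress_by_dimension,
)


def euclidean_D(X):
    return squareform(pdist(X))


def idm_with_nan(n=4):
    D = euclidean_D(np.arange(n, dtype=float).reshape(-1, 1))
    D[0, 1] = D[1, 0] = np.nan
    card = np.ones((n, n), dtype=int)
    card[0, 1] = card[1, 0] = 0
    return IndividualDistanceMatrix(ids=[f"i{k}" for k in range(n)], D=D,
                                    cardinality=card)


class TestResolveUndefined:
    def test_clean_matrix_unchanged(self):
        D = euclidean_D(np.random.default_rng(0).normal(size=(5, 2)))
        idm = IndividualDistanceMatrix(ids=list("abcde"), D=D,
                                       cardinality=np.ones((5, 5), dtype=int))
        out = resolve_undefined(idm, "error")
        np.testing.assert_array_equal(out.D, D)

    def test_error_policy_names_pair(self):
        with pytest.raises(ValueError, match=r"\('i0', 'i1'\)"):
            resolve_undefined(idm_with_nan(), "error")

    def test_mean_impute_uses_off_diagonal_mean(self):
        idm = idm_with_nan()
        out = resolve_undefined(idm, "mean_impute")
        iu = np.triu_indices(4, k=1)
        expected = np.nanmean(idm.D[iu])
        assert out.D[0, 1] == pytest.approx(expected)
        assert not np.isnan(out.D).any()


class TestPCoA:
    def test_reconstructs_planar_distances(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(5, 2))
        emb = pcoa(euclidean_D(X), k=2)
        np.testing.assert_allclose(
            euclidean_D(emb.coordinates), euclidean_D(X), atol=1e-9
        )
        assert emb.stress1 == pytest.approx(0.0, abs=1e-9)

    def test_two_points_closed_form(self):
        D = np.array([[0.0, 3.0], [3.0, 0.0]])
        emb = pcoa(D, k=1)
        np.testing.assert_allclose(
            sorted(emb.coordinates[:, 0]), [-1.5, 1.5], atol=1e-12
        )

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError, match="positive eigenvalues"):
            pcoa(np.zeros((4, 4)), k=1)

    def test_eigenvalues_non_increasing_and_negatives_reported(self):
        D = np.array(
            [[0, 3, 1, 1], [3, 0, 1, 1], [1, 1, 0, 1], [1, 1, 1, 0]], float
        )  # violates the Euclidean condition
        emb = pcoa(D, k=1)
        assert (np.diff(emb.eigenvalues) <= 1e-12).all()
        assert emb.eigenvalues.min() < -1e-6

    def test_matches_skbio_reconstruction(self):
        from skbio import DistanceMatrix
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(8)
        X = rng.normal(size=(12, 3))
        D = euclidean_D(X)
        ours = pcoa(D, k=3).coordinates
        ref = skbio_pcoa(DistanceMatrix(D), method="eigh").samples.values[:, :3]
        np.testing.assert_allclose(
            euclidean_D(ours), euclidean_D(ref), atol=1e-8
        )

    def test_positive_eigenvalues_sum_to_centred_variance(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 3))
        emb = pcoa(euclidean_D(X), k=3)
        Xc = X - X.mean(axis=0)
        assert emb.eigenvalues[emb.eigenvalues > 0].sum() == pytest.approx(
            (Xc ** 2).sum(), rel=1e-9
        )


class TestStress1:
    def test_exact_embedding_gives_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 2))
        assert stress1(euclidean_D(X), X) == pytest.approx(0.0, abs=1e-12)

    def test_coincident_coordinates_give_one(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 2))
        assert stress1(euclidean_D(X), np.zeros((6, 2))) == pytest.approx(1.0)

    def test_single_pair_half(self):
        D = np.array([[0.0, 2.0], [2.0, 0.0]])
        coords = np.array([[0.0], [1.0]])  # embedded distance 1
        assert stress1(D, coords) == pytest.approx(0.5)

    def test_all_zero_distances_error(self):
        with pytest.raises(ValueError, match="zero"):
            stress1(np.zeros((3, 3)), np.zeros((3, 1)))

    def test_invariance_under_rigid_motions(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 2))
        D = euclidean_D(rng.normal(size=(8, 2)))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        base = stress1(D, X)
        assert stress1(D, X @ R) == pytest.approx(base)
        assert stress1(D, X + [5.0, -2.0]) == pytest.approx(base)
        assert stress1(D, X * [-1, 1]) == pytest.approx(base)  # reflection


class TestMetricMDS:
    def test_exactly_embeddable_input(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 3))
        emb = metric_mds(euclidean_D(X), k=3, seed=0)
        assert emb.stress1 < 0.01

    def test_colinear_one_dimensional(self):
        x = np.array([0.0, 1.0, 2.5, 4.0]).reshape(-1, 1)
        emb = metric_mds(euclidean_D(x), k=1, seed=0)
        assert emb.stress1 == pytest.approx(0.0, abs=1e-3)

    def test_seed_determinism(self):
        rng = np.random.default_rng(6)
        D = euclidean_D(rng.normal(size=(15, 4)))
        a = metric_mds(D, k=2, seed=42)
        b = metric_mds(D, k=2, seed=42)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)

    def test_stress_non_increasing_in_k(self):
        rng = np.random.default_rng(7)
        D = euclidean_D(rng.normal(size=(25, 4)))
        series = stress_by_dimension(D, range(1, 5), seed=0)
        assert (np.diff(series.values) <= 1e-9).all()


class TestLaplacianEigenmaps:
    def test_two_blobs_bipartition_in_one_component(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0, 0.1, size=(15, 2)),
                       rng.normal(5, 0.1, size=(15, 2))])
        emb = laplacian_eigenmaps(euclidean_D(X), k=1)
        signs = np.sign(emb.coordinates[:, 0])
        assert len(set(signs[:15])) == 1 and len(set(signs[15:])) == 1
        assert signs[0] != signs[15]

    def test_identical_points_zero_embedding(self):
        emb = laplacian_eigenmaps(np.zeros((5, 5)), k=2)
        assert (emb.coordinates == 0).all()

    def test_median_bandwidth_rule(self):
        rng = np.random.default_rng(9)
        D = euclidean_D(rng.normal(size=(10, 2)))
        sigma = float(np.median(D[np.triu_indices(10, 1)]))
        auto = laplacian_eigenmaps(D, k=2)
        manual = laplacian_eigenmaps(D, k=2, bandwidth=sigma)
        np.testing.assert_allclose(auto.coordinates, manual.coordinates)

    def test_matches_sklearn_spectral_embedding(self):
        # needs well-separated eigenvalues: near-degenerate spectra leave the
        # eigenvectors free to rotate within their eigenspace
        from sklearn.manifold import spectral_embedding

        rng = np.random.default_rng(10)
        X = np.vstack([rng.normal(c, 0.2, size=(5, 2))
                       for c in (0.0, 3.0, 7.0)])
        D = euclidean_D(X)
        emb = laplacian_eigenmaps(D, k=2)
        sigma = float(np.median(D[np.triu_indices(15, 1)]))
        W = np.exp(-(D ** 2) / (2 * sigma ** 2))
        ref = spectral_embedding(W, n_components=2, drop_first=True,
                                 random_state=0)
        for j in range(2):
            r = ref[:, j] / np.linalg.norm(ref[:, j])
            o = emb.coordinates[:, j] / np.linalg.norm(emb.coordinates[:, j])
            assert min(np.abs(o - r).max(), np.abs(o + r).max()) < 1e-5

    def test_eigenvalues_reported_for_scree(self):
        rng = np.random.default_rng(11)
        D = euclidean_D(rng.normal(size=(10, 2)))
        emb = laplacian_eigenmaps(D, k=3)
        assert emb.eigenvalues is not None and len(emb.eigenvalues) == 9


class TestSelectDimensions:
    def test_threshold_rule(self):
        assert select_dimensions(
            {1: 0.4, 2: 0.25, 3: 0.19, 4: 0.15}
        ) == 3
        assert select_dimensions({1: 0.1}) == 1

    def test_no_k_satisfies_threshold(self):
        with pytest.raises(ValueError, match="more dimensions"):
            select_dimensions({1: 0.5, 2: 0.4})

    def test_report_only_returns_series(self):
        series = select_dimensions({1: 0.5, 2: 0.4}, rule="report_only")
        assert list(series.values) == [0.5, 0.4]
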