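import numpy as np
import pytest

from conftest import binary_matrix, random_mixed_dataset
from phenoclust.dataset import Dataset, IndividualRecord, VariableSpec
from phenoclust.distances import (
    gower_distance_matrix,
    quantitative_scales,
    semantic_distance_matrix,
    semantic_pair_distance,
)
from phenoclust.modality import ModalityDistanceMatrix, normalise


def qual(name, weight=1.0):
    return VariableSpec(name=name, kind="qualitative", source="ontology_file",
                        source_path="s.csv", weight=weight)


def make_matrix(name, labels, values):
    return normalise(ModalityDistanceMatrix(name, labels, np.asarray(values)))


def gower_oracle(dataset):
    """Independent route: dummy coding (+ missing indicator), Dice per
    qualitative variable, Manhattan/range per quantitative one, masked
    element-wise mean.  Pure loops, no shared code with the implementation."""
    from scipy.spatial.distance import dice

    n = len(dataset.individuals)
    per_var = []
    for spec in dataset.specs:
        col = dataset.column(spec.name)
        mat = np.full((n, n), np.nan)
        if spec.kind == "qualitative":
            mods = sorted({v for v in col if v is not None})
            dummies = []
            for v in col:
                vec = [v == m for m in mods] + [v is None]  # missing indicator
                dummies.append(np.array(vec, dtype=bool))
            for i in range(n):
                for j in range(n):
                    if col[i] is None or col[j] is None:
                        continue  # flagged by the missing indicator
                    if dummies[i].any() or dummies[j].any():
                        mat[i, j] = 0.0 if (dummies[i] == dummies[j]).all() \
                            else dice(dummies[i], dummies[j])
        else:
            obs = [v for v in col if v is not None]
            rng_ = max(obs) - min(obs) if len(obs) > 1 else 0.0
            for i in range(n):
                for j in range(n):
                    if col[i] is None or col[j] is None:
                        continue
                    d = abs(col[i] - col[j])
                    mat[i, j] = d / rng_ if rng_ > 0 else 0.0
        per_var.append(mat)
    stack = np.stack(per_var)
    counts = (~np.isnan(stack)).sum(axis=0)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        D = np.nanmean(stack, axis=0)
    D[counts == 0] = np.nan
    np.fill_diagonal(D, 0.0)
    return D, counts


class TestSemanticPairDistance:
    def test_identical_complete_records(self):
        specs = [qual("a"), qual("b")]
        matrices = {n: binary_matrix(n, ["x", "y"]) for n in ("a", "b")}
        r = IndividualRecord("i", {"a": "x", "b": "y"})
        d, m = semantic_pair_distance(r, r, specs, matrices)
        assert d == 0.0 and m == 2

    def test_weighted_mean_of_observed(self):
        specs = [qual("a"), qual("b"), qual("c")]
        matrices = {
            "a": make_matrix("a", ["x", "y"], [[0, 100], [100, 0]]),
            "b": make_matrix("b", ["x", "y"], [[0, 100], [100, 0]]),
            "c": make_matrix("c", ["x", "y"], [[0, 100], [100, 0]]),
        }
        # shared variables a (distance 0) and b (distance 50 via half-weight
        # matrix is not possible -> craft a 3-modality matrix instead)
        matrices["b"] = make_matrix("b", ["x", "y", "z"],
                                    [[0, 50, 100], [50, 0, 50], [100, 50, 0]])
        r1 = IndividualRecord("1", {"a": "x", "b": "x", "c": None})
        r2 = IndividualRecord("2", {"a": "x", "b": "y", "c": "x"})
        d, m = semantic_pair_distance(r1, r2, specs, matrices)
        assert m == 2
        assert d == pytest.approx(25.0)  # mean of 0 and 50

    def test_disjoint_records_undefined(self):
        specs = [qual("a"), qual("b")]
        matrices = {n: binary_matrix(n, ["x"]) for n in ("a", "b")}
        r1 = IndividualRecord("1", {"a": "x", "b": None})
        r2 = IndividualRecord("2", {"a": None, "b": "x"})
        d, m = semantic_pair_distance(r1, r2, specs, matrices)
        assert np.isnan(d) and m == 0

    def test_weights_reweight_the_mean(self):
        specs = [qual("a", weight=3.0), qual("b", weight=1.0)]
        matrices = {n: binary_matrix(n, ["x", "y"]) for n in ("a", "b")}
        r1 = IndividualRecord("1", {"a": "x", "b": "x"})
        r2 = IndividualRecord("2", {"a": "y", "b": "x"})
        d, _ = semantic_pair_distance(r1, r2, specs, matrices)
        assert d == pytest.approx(3 * 100 / 4)


class TestSemanticMatrix:
    def test_structure_and_pairwise_agreement(self):
        rng = np.random.default_rng(7)
        ds, matrices = random_mixed_dataset(rng, n=12, missing_rate=0.25)
        idm = semantic_distance_matrix(ds, matrices, warn_undefined=False)
        np.testing.assert_allclose(idm.D, idm.D.T)
        assert np.allclose(np.diag(idm.D), 0.0)
        scales = quantitative_scales(ds)
        for i in range(12):
            for j in range(i + 1, 12):
                d, m = semantic_pair_distance(
                    ds.individuals[i], ds.individuals[j], ds.specs, matrices,
                    quant_scales=scales,
                )
                assert idm.cardinality[i, j] == m
                if m == 0:
                    assert np.isnan(idm.D[i, j])
                else:
                    assert idm.D[i, j] == pytest.approx(d)

    def test_equal_weight_equals_mean_of_observed_distances(self):
        rng = np.random.default_rng(11)
        ds, matrices = random_mixed_dataset(rng, n=10, missing_rate=0.3)
        idm = semantic_distance_matrix(ds, matrices, warn_undefined=False)
        scales = quantitative_scales(ds)
        for i in range(10):
            for j in range(i + 1, 10):
                per_var = []
                for s in ds.specs:
                    va = ds.individuals[i].values[s.name]
                    vb = ds.individuals[j].values[s.name]
                    if va is None or vb is None:
                        continue
                    if s.kind == "qualitative":
                        per_var.append(matrices[s.name].lookup(va, vb))
                    else:
                        sc = scales[s.name]
                        per_var.append(abs(va - vb) * 100 / sc if sc else 0.0)
                if per_var:
                    assert idm.D[i, j] == pytest.approx(np.mean(per_var))

    def test_all_missing_individual_is_undefined_off_diagonal(self):
        specs = [qual("a")]
        matrices = {"a": binary_matrix("a", ["x", "y"])}
        ds = Dataset(
            individuals=[
                IndividualRecord("1", {"a": "x"}),
                IndividualRecord("2", {"a": None}),
            ],
            specs=specs,
        )
        with pytest.warns(UserWarning, match="UNDEFINED"):
            idm = semantic_distance_matrix(ds, matrices)
        assert np.isnan(idm.D[0, 1])
        assert idm.D[1, 1] == 0.0

    def test_range_in_0_100(self):
        rng = np.random.default_rng(3)
        ds, matrices = random_mixed_dataset(rng, n=15, missing_rate=0.2)
        idm = semantic_distance_matrix(ds, matrices, warn_undefined=False)
        vals = idm.D[~np.isnan(idm.D)]
        assert vals.min() >= 0 and vals.max() <= 100 + 1e-9


class TestGower:
    def test_all_qualitative_extremes(self):
        specs = [qual("a"), qual("b")]
        ds = Dataset(
            individuals=[
                IndividualRecord("1", {"a": "x", "b": "u"}),
                IndividualRecord("2", {"a": "y", "b": "v"}),
                IndividualRecord("3", {"a": "x", "b": "u"}),
            ],
            specs=specs,
        )
        idm = gower_distance_matrix(ds)
        assert idm.D[0, 1] == 1.0  # differ on every variable
        assert idm.D[0, 2] == 0.0  # identical

    def test_half_matching_qualitative(self):
        specs = [qual(f"v{i}") for i in range(4)]
        ds = Dataset(
            individuals=[
                IndividualRecord("1", {"v0": "a", "v1": "a", "v2": "a", "v3": "a"}),
                IndividualRecord("2", {"v0": "a", "v1": "a", "v2": "b", "v3": "b"}),
            ],
            specs=specs,
        )
        assert gower_distance_matrix(ds).D[0, 1] == pytest.approx(0.5)

    def test_simple_matching_on_complete_qualitative_data(self):
        rng = np.random.default_rng(13)
        ds, _ = random_mixed_dataset(rng, n=10, n_qual=5, n_quant=0)
        idm = gower_distance_matrix(ds)
        for i in range(10):
            for j in range(10):
                mism = sum(
                    ds.individuals[i].values[s.name]
                    != ds.individuals[j].values[s.name]
                    for s in ds.specs
                )
                assert idm.D[i, j] == pytest.approx(mism / 5)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_against_dummy_dice_oracle_with_missing(self, seed):
        rng = np.random.default_rng(seed)
        ds, _ = random_mixed_dataset(rng, n=20, n_qual=3, n_quant=2,
                                     missing_rate=0.3)
        idm = gower_distance_matrix(ds)
        D_ref, counts_ref = gower_oracle(ds)
        np.testing.assert_allclose(idm.D, D_ref, equal_nan=True)
        off = ~np.eye(20, dtype=bool)
        np.testing.assert_array_equal(idm.cardinality[off], counts_ref[off])

    def test_binary_semantic_reduces_to_gower(self):
        # when every modality matrix is {0, 100} and weights are equal,
        # semantic D / 100 equals Gower D on complete qualitative data
        rng = np.random.default_rng(17)
        ds, _ = random_mixed_dataset(rng, n=12, n_qual=4, n_quant=0)
        matrices = {
            s.name: binary_matrix(s.name, [f"m{i}" for i in range(4)])
            for s in ds.specs
        }
        sem = semantic_distance_matrix(ds, matrices, warn_undefined=False)
        gow = gower_distance_matrix(ds)
        np.testing.assert_allclose(sem.D / 100.0, gow.D, atol=1e-12)

    def test_gower_range_and_symmetry(self):
        rng = np.random.default_rng(19)
        ds, _ = random_mixed_dataset(rng, n=15, missing_rate=0.3)
        idm = gower_distance_matrix(ds)
        np.testing.assert_allclose(idm.D, idm.D.T, equal_nan=True)
        vals = idm.D[~np.isnan(idm.D)]
        assert vals.min() >= 0 and vals.max() <= 1 + 1e-12

    def test_raw_manhattan_flag(self):
        specs = [VariableSpec(name="x", kind="quantitative", source="numeric")]
        ds = Dataset(
            individuals=[IndividualRecord("1", {"x": 0.0}),
                         IndividualRecord("2", {"x": 5.0})],
            specs=specs,
        )
        assert gower_distance_matrix(ds).D[0, 1] == 1.0  # range-normalised
        assert gower_distance_matrix(ds, range_normalise=False).D[0, 1] == 5.0
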