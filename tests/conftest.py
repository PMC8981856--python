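import numpy as np
import pytest

from phenoclust.fixtures import PRICKLES_ORDER, materialize_demo, prickles_graph
from phenoclust.modality import ModalityDistanceMatrix, normalise
from phenoclust.dataset import Dataset, IndividualRecord, VariableSpec
from phenoclust.ontology import expert_distance_matrix

# The printed expert distance matrix for the quantity-of-prickles variable
# (reference hand-tailored values), in canonical modality order.
PRICKLES_TABLE = np.array(
    [
        [0, 1, 5, 6],
        [1, 0, 4, 5],
        [5, 4, 0, 1],
        [6, 5, 1, 0],
    ],
    dtype=float,
)


@pytest.fixture(scope="session")
def prickles():
    return prickles_graph("normal")


@pytest.fixture(scope="session")
def prickles_matrix(prickles):
    return expert_distance_matrix(prickles, variable="prickles",
                                  order=PRICKLES_ORDER)


@pytest.fixture()
def demo_workspace(tmp_path):
    """Materialised demo workspace; returns the config path."""
    return materialize_demo(tmp_path / "demo")


def binary_matrix(name, labels):
    """A {0, 100} modality matrix: 0 iff identical, 100 otherwise."""
    n = len(labels)
    values = np.full((n, n), 100.0)
    np.fill_diagonal(values, 0.0)
    return ModalityDistanceMatrix(variable=name, labels=list(labels),
                                  values=values, normalised=True)


def random_mixed_dataset(rng, n, n_qual=3, n_quant=1, n_modalities=4,
                         missing_rate=0.0):
    """A small ad-hoc mixed dataset plus normalised ordinal modality matrices."""
    labels = [f"m{i}" for i in range(n_modalities)]
    specs = [
        VariableSpec(name=f"q{v}", kind="qualitative", source="ontology_file",
                     source_path="levels.csv")
        for v in range(n_qual)
    ] + [
        VariableSpec(name=f"x{v}", kind="quantitative", source="numeric")
        for v in range(n_quant)
    ]
    base = np.abs(np.subtract.outer(np.arange(n_modalities),
                                    np.arange(n_modalities))).astype(float)
    matrices = {
        f"q{v}": normalise(
            ModalityDistanceMatrix(variable=f"q{v}", labels=labels,
                                   values=base.copy())
        )
        for v in range(n_qual)
    }
    individuals = []
    for i in range(n):
        values = {}
        for s in specs:
            if rng.random() < missing_rate:
                values[s.name] = None
            elif s.kind == "qualitative":
                values[s.name] = labels[rng.integers(n_modalities)]
            else:
                values[s.name] = float(rng.normal())
        individuals.append(IndividualRecord(id=f"i{i}", values=values))
    return Dataset(individuals=individuals, specs=specs), matrices
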