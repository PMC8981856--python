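"""Synthetic mixed datasets with planted clusters and missingness.

The generator emulates the structure of a passport + trait table: a few
hundred individuals in a handful of latent groups, described by ordinal
qualitative variables (each backed by a small expert-style ontology with
distances |i - j| between modality ranks) and a couple of quantitative
variables, with values knocked out completely at random (MCAR).

Defaults are the package's reference study conditions: 300 individuals in
3 equally likely clusters, described by 11 variables — the width of a
typical passport + trait table — of which 9 are qualitative with 4 ordinal
modalities (each cluster concentrates 85% of its mass on a cluster-specific
modality) and 2 are quantitative with cluster means 3 standard deviations
apart, under a 30% MCAR missing rate per variable.  Ground-truth labels are
returned so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .dataset import Dataset, IndividualRecord, VariableSpec, write_dataset
from .modality import ModalityDistanceMatrix, normalise
from .ontology import ConceptGraph, write_concept_graph

LEVELS_FILE = "levels_synthetic.csv"


def ordinal_levels_graph(n_modalities: int = 4) -> ConceptGraph:
    """An ordinal 'levels' ontology: distance between ranks i, j is |i - j|."""
    labels = [f"level_{i}" for i in range(n_modalities)]
    distances = {
        (labels[i], labels[j]): float(j - i)
        for i in range(n_modalities)
        for j in range(i + 1, n_modalities)
    }
    return ConceptGraph(concepts=labels, is_a=set(), distances=distances)


@dataclass
class SyntheticSpec:
    """Generative model for a planted-cluster mixed dataset."""

    n: int = 300
    n_clusters: int = 3
    proportions: list | None = None  # default: equal
    n_qualitative: int = 9
    n_modalities: int = 4
    dominant_prob: float = 0.85
    n_quantitative: int = 2
    quant_separation: float = 3.0  # cluster mean spacing, in SD units
    quant_sd: float = 1.0
    missing_rate: float | list = 0.3  # MCAR, per variable
    seed: int = 0

    def __post_init__(self) -> None:
        if self.proportions is None:
            self.proportions = [1.0 / self.n_clusters] * self.n_clusters
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("cluster proportions must sum to 1")
        rates = self.missing_rates()
        if any(not 0 <= r < 1 for r in rates):
            raise ValueError("missing rates must be in [0, 1)")
        if not 1.0 / self.n_modalities <= self.dominant_prob <= 1.0:
            raise ValueError("dominant_prob must be >= the uniform probability")

    @property
    def n_variables(self) -> int:
        return self.n_qualitative + self.n_quantitative

    def missing_rates(self) -> list:
        if np.isscalar(self.missing_rate):
            return [float(self.missing_rate)] * self.n_variables
        rates = list(self.missing_rate)
        if len(rates) != self.n_variables:
            raise ValueError("one missing rate per variable required")
        return rates

    def variable_specs(self) -> list:
        specs = [
            VariableSpec(
                name=f"trait_{v + 1}", kind="qualitative",
                source="ontology_file", source_path=LEVELS_FILE,
            )
            for v in range(self.n_qualitative)
        ]
        specs += [
            VariableSpec(name=f"measure_{q + 1}", kind="quantitative",
                         source="numeric")
            for q in range(self.n_quantitative)
        ]
        return specs

    def modality_probabilities(self, cluster: int, variable: int) -> np.ndarray:
        """Cluster-specific categorical distribution over modality ranks.

        Each cluster concentrates ``dominant_prob`` on rank
        (cluster + variable) mod n_modalities, so every pair of clusters is
        separated on every variable, at varying ordinal distances.
        """
        m = self.n_modalities
        probs = np.full(m, (1.0 - self.dominant_prob) / (m - 1))
        probs[(cluster + variable) % m] = self.dominant_prob
        return probs


def generate_dataset(spec: SyntheticSpec) -> tuple:
    """Draw a dataset from the generative model; returns (Dataset, labels)."""
    rng = np.random.default_rng(spec.seed)
    labels = rng.choice(spec.n_clusters, size=spec.n, p=spec.proportions)
    rates = spec.missing_rates()
    modality_names = [f"level_{i}" for i in range(spec.n_modalities)]

    columns: dict = {}
    for v in range(spec.n_qualitative):
        probs = np.stack(
            [spec.modality_probabilities(c, v) for c in range(spec.n_clusters)]
        )
        draws = np.array(
            [rng.choice(spec.n_modalities, p=probs[c]) for c in labels]
        )
        columns[f"trait_{v + 1}"] = [modality_names[d] for d in draws]
    for q in range(spec.n_quantitative):
        means = labels * spec.quant_separation * spec.quant_sd
        columns[f"measure_{q + 1}"] = list(
            rng.normal(means, spec.quant_sd)
        )

    specs = spec.variable_specs()
    individuals = []
    for row in range(spec.n):
        values = {}
        for j, s in enumerate(specs):
            if rng.random() < rates[j]:
                values[s.name] = None
            else:
                values[s.name] = columns[s.name][row]
        individuals.append(
            IndividualRecord(id=f"ind_{row + 1:04d}", values=values)
        )
    return Dataset(individuals=individuals, specs=specs), labels


def modality_matrices(spec: SyntheticSpec) -> dict:
    """Normalised modality matrices for the synthetic qualitative variables."""
    from .ontology import expert_distance_matrix

    graph = ordinal_levels_graph(spec.n_modalities)
    base = expert_distance_matrix(graph)
    return {
        f"trait_{v + 1}": normalise(
            ModalityDistanceMatrix(
                variable=f"trait_{v + 1}", labels=list(base.labels),
                values=base.values.copy(),
            )
        )
        for v in range(spec.n_qualitative)
    }


def materialize(spec: SyntheticSpec, directory: str | Path,
                config_overrides: dict | None = None) -> tuple:
    """Write a ready-to-run workspace: trait table, ontology, YAML config.

    Returns (config_path, true_labels).  The config drives the full
    pipeline with the package defaults (semantic distance, PCoA, k-means at
    the planted cluster count).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dataset, labels = generate_dataset(spec)

    write_concept_graph(
        ordinal_levels_graph(spec.n_modalities), directory / LEVELS_FILE, "csv"
    )
    write_dataset(dataset, directory / "traits_synthetic.csv")
    np.savetxt(directory / "true_labels.csv", labels, fmt="%d")

    config = {
        "dataset": "traits_synthetic.csv",
        "variables": [
            {
                "name": s.name, "kind": s.kind, "source": s.source,
                **({"path": s.source_path} if s.source_path else {}),
            }
            for s in dataset.specs
        ],
        "distance": "semantic",
        "reduction": {"method": "pcoa", "n_dims": 4,
                      "undefined_policy": "mean_impute"},
        "clustering": {"algorithms": ["kmeans"], "k": [spec.n_clusters]},
        "archetypes": {"mode": "multiple", "fraction": 0.05},
        "seed": spec.seed,
        "output_dir": "out",
    }
    config.update(config_overrides or {})
    config_path = directory / "config.yaml"
    with open(config_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return config_path, labels
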