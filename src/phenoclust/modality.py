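"""Per-variable modality distance matrices and their [0-100] normalisation.

Each qualitative variable gets one symmetric, zero-diagonal matrix of
distances between its modalities, built from the variable's source (expert
ontology, colour table, geographic table or period table).  Because the raw
scales differ wildly between variables (ΔE units vs kilometres vs years vs
expert scores), every matrix is rescaled linearly so that its largest entry
is 100 before entering the individual-level distance; this keeps any single
variable from out-weighting the others.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd


@dataclass
class ModalityDistanceMatrix:
    """Symmetric labelled distance matrix between a variable's modalities."""

    variable: str
    labels: list
    values: np.ndarray
    normalised: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"{self.variable}: matrix shape {self.values.shape} does not "
                f"match {n} labels"
            )
        if n and not np.allclose(np.diag(self.values), 0.0):
            raise ValueError(f"{self.variable}: diagonal must be zero")
        if not np.allclose(self.values, self.values.T):
            raise ValueError(f"{self.variable}: matrix must be symmetric")
        if n and self.values.min() < 0:
            raise ValueError(f"{self.variable}: negative distances")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def lookup(self, a, b) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def build_modality_matrix(spec, source) -> ModalityDistanceMatrix:
    """Build the raw (unnormalised) modality matrix for one variable.

    ``source`` is a :class:`~phenoclust.ontology.ConceptGraph` for
    ``ontology_file`` variables, or a label -> measurement mapping (from
    :func:`~phenoclust.measures.read_lookup_table`) for colour / geo /
    period variables.  Label order follows the source (leaf order for
    ontologies, table order for lookups).
    """
    from . import measures
    from .ontology import ConceptGraph, expert_distance_matrix

    if spec.source == "ontology_file":
        if not isinstance(source, ConceptGraph):
            raise TypeError(f"{spec.name}: expected a ConceptGraph source")
        return expert_distance_matrix(source, variable=spec.name)

    if spec.source == "numeric":
        raise ValueError(
            f"{spec.name}: quantitative variables have no modality matrix"
        )

    pairwise = {
        "colour_table": measures.delta_e,
        "geo_table": measures.geo_distance,
        "period_table": measures.period_distance,
    }.get(spec.source)
    if pairwise is None:
        raise ValueError(f"{spec.name}: unknown source {spec.source!r}")

    labels = list(source)
    n = len(labels)
    values = np.zeros((n, n), dtype=float)
    for i, j in combinations(range(n), 2):
        d = float(pairwise(source[labels[i]], source[labels[j]]))
        values[i, j] = values[j, i] = d
    return ModalityDistanceMatrix(
        variable=spec.name, labels=labels, values=values, normalised=False
    )


def resolve_modalities(matrix: ModalityDistanceMatrix, observed) -> list:
    """Return observed modality labels missing from the matrix (for errors)."""
    known = set(matrix.labels)
    return sorted(v for v in set(observed) if v not in known)


def normalise(matrix: ModalityDistanceMatrix) -> ModalityDistanceMatrix:
    """Rescale a modality matrix linearly onto [0, 100].

    The map is x -> 100 x / max(x): the diagonal pins the minimum at 0, so
    max-scaling is the simplest linear map onto the target range.  It
    preserves entry ratios and ordering, is idempotent, and leaves an
    all-zero matrix unchanged.
    """
    m = matrix.values.max() if matrix.values.size else 0.0
    if m == 0.0:
        return replace(matrix, values=matrix.values.copy(), normalised=True)
    return replace(matrix, values=matrix.values * (100.0 / m), normalised=True)
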