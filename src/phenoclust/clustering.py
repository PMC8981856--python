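"""Clustering in the reduced space, silhouette guidance and concordance.

Six algorithms are wrapped behind one call signature (Birch, Gaussian
mixture, Ward hierarchical, k-means, k-medoids, spectral).  All consume the
embedding coordinates; silhouettes use Euclidean distances in that space by
default, with an opt-in precomputed-distance route for k-medoids users.
Partitions from different algorithms (or different distances) are compared
by concordance matrices — plain contingency tables over the individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, Birch, KMeans, SpectralClustering
from sklearn.metrics import silhouette_samples, silhouette_score
from sklearn.mixture import GaussianMixture

ALGORITHMS = ("birch", "gmm", "ward", "kmeans", "kmedoids", "spectral")


@dataclass
class Partition:
    """A clustering of the individuals into k groups labelled 0..k-1."""

    ids: list
    labels: np.ndarray
    algorithm: str
    k: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.ids):
            raise ValueError("label count does not match id count")
        present = set(self.labels.tolist())
        if present != set(range(self.k)):
            raise ValueError(
                f"labels must be exactly 0..{self.k - 1}, got {sorted(present)}"
            )

    def members(self, cluster: int) -> list:
        return [i for i, lab in zip(self.ids, self.labels) if lab == cluster]

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "algorithm": self.algorithm, "k": self.k,
             "label": self.labels}
        )


def _relabel_first_appearance(raw: np.ndarray) -> np.ndarray:
    """Map arbitrary labels to 0..k-1 in order of first appearance."""
    mapping: dict = {}
    out = np.empty_like(raw, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def _pam_kmedoids(dist: np.ndarray, k: int) -> np.ndarray:
    """Partitioning Around Medoids: greedy BUILD then best-improvement SWAP.

    Fully deterministic (no random initialisation); O(k n²) per sweep, which
    is ample at the scales this package targets.
    """
    n = dist.shape[0]
    # BUILD: first medoid minimises total distance, then greedy additions
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - dist, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)

    def cost(meds: list) -> float:
        return float(dist[:, meds].min(axis=1).sum())

    best = cost(medoids)
    improved = True
    while improved:
        improved = False
        for mi in range(k):
            for h in range(n):
                if h in medoids:
                    continue
                trial = sorted(medoids[:mi] + medoids[mi + 1:] + [h])
                c = cost(trial)
                if c < best - 1e-12:
                    best, medoids, improved = c, trial, True
    return np.argmin(dist[:, medoids], axis=1)


def cluster(
    coordinates: np.ndarray,
    algorithm: str,
    k: int,
    seed: int = 0,
    ids=None,
) -> Partition:
    """Cluster embedded individuals into k groups; deterministic under seed."""
    X = np.asarray(coordinates, dtype=float)
    n = X.shape[0]
    ids = list(ids) if ids is not None else list(range(n))
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of individuals ({n})")
    if k == 1:
        return Partition(ids=ids, labels=np.zeros(n, dtype=int),
                         algorithm=algorithm, k=1, seed=seed)

    if algorithm == "birch":
        raw = Birch(n_clusters=k).fit_predict(X)
    elif algorithm == "gmm":
        raw = GaussianMixture(
            n_components=k, covariance_type="full", random_state=seed
        ).fit_predict(X)
    elif algorithm == "ward":
        raw = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)
    elif algorithm == "kmeans":
        raw = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)
    elif algorithm == "kmedoids":
        from scipy.spatial.distance import pdist, squareform

        raw = _pam_kmedoids(squareform(pdist(X)), k)
    else:  # spectral
        raw = SpectralClustering(
            n_clusters=k, affinity="rbf", gamma=1.0, random_state=seed,
            assign_labels="kmeans",
        ).fit_predict(X)

    labels = _relabel_first_appearance(raw)
    if len(set(labels.tolist())) != k:
        raise ValueError(
            f"{algorithm} produced fewer than k={k} distinct clusters "
            f"(degenerate input?)"
        )
    return Partition(ids=ids, labels=labels, algorithm=algorithm, k=k, seed=seed)


def silhouette_profile(
    coordinates: np.ndarray,
    algorithm: str,
    k_range,
    seed: int = 0,
    precomputed: np.ndarray | None = None,
) -> dict:
    """Mean silhouette per candidate k (Euclidean in the reduced space).

    ``precomputed`` switches the silhouette (not the clustering) to a given
    distance matrix, for users clustering on k-medoids with the original
    distances in mind.
    """
    X = np.asarray(coordinates, dtype=float)
    n = X.shape[0]
    if np.allclose(X, X[0]):
        raise ValueError("silhouette undefined: all coordinates are identical")
    out = {}
    for k in k_range:
        if not 2 <= k <= n - 1:
            raise ValueError(f"k={k} outside the valid silhouette range [2, {n - 1}]")
        part = cluster(X, algorithm, k, seed=seed)
        if precomputed is not None:
            out[k] = float(
                silhouette_score(precomputed, part.labels, metric="precomputed")
            )
        else:
            out[k] = float(silhouette_score(X, part.labels))
    return out


def silhouette_individuals(
    coordinates: np.ndarray, partition: Partition
) -> pd.DataFrame:
    """Per-individual silhouette values, grouped by cluster for plotting.

    Members of singleton clusters get silhouette 0 (the usual convention).
    Columns: id, cluster, silhouette; rows ordered by (cluster, value desc).
    """
    X = np.asarray(coordinates, dtype=float)
    n = X.shape[0]
    if not 2 <= partition.k <= n - 1:
        raise ValueError(
            f"k={partition.k} outside the valid silhouette range [2, {n - 1}]"
        )
    values = silhouette_samples(X, partition.labels)
    df = pd.DataFrame(
        {"id": partition.ids, "cluster": partition.labels, "silhouette": values}
    )
    return df.sort_values(
        ["cluster", "silhouette"], ascending=[True, False]
    ).reset_index(drop=True)


@dataclass
class ConcordanceTable:
    """Contingency counts between a reference partition and another."""

    reference: str
    other: str
    counts: pd.DataFrame  # rows: reference clusters, cols: other clusters

    @property
    def n(self) -> int:
        return int(self.counts.values.sum())


def concordance(reference: Partition, other: Partition) -> ConcordanceTable:
    """Cross-tabulate two partitions of the same individuals.

    ``counts[r][o]`` = number of individuals in reference cluster r and
    other cluster o.  Raw counts are the data; see
    :func:`align_for_display` for the diagonal-maximising display aid.
    """
    if list(reference.ids) != list(other.ids):
        raise ValueError("partitions cover different individuals")
    counts = pd.crosstab(
        pd.Series(reference.labels, name=reference.algorithm),
        pd.Series(other.labels, name=other.algorithm),
    ).reindex(
        index=range(reference.k), columns=range(other.k), fill_value=0
    )
    return ConcordanceTable(
        reference=reference.algorithm, other=other.algorithm, counts=counts
    )


def align_for_display(table: ConcordanceTable) -> ConcordanceTable:
    """Greedily reorder the columns so large counts sit on the diagonal."""
    counts = table.counts.copy()
    remaining = list(counts.columns)
    order = []
    for r in counts.index:
        if not remaining:
            break
        best = max(remaining, key=lambda c: counts.loc[r, c])
        order.append(best)
        remaining.remove(best)
    order += remaining
    return ConcordanceTable(
        reference=table.reference, other=table.other, counts=counts[order]
    )
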