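"""Archetype selection: real individuals that stand in for a cluster.

Two strategies, suited to different cluster structures: with many small
clusters, one individual per cluster (the member nearest the cluster
centroid) is enough; with few large clusters, a seeded 5% random sample per
cluster better conveys within-cluster diversity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .clustering import Partition


@dataclass
class ArchetypeSet:
    mode: str  # 'single' | 'multiple'
    members: dict  # cluster label -> list of individual ids
    fraction: float | None = None
    seed: int | None = None

    def all_ids(self) -> list:
        return [i for ids in self.members.values() for i in ids]

    def to_records(self) -> list:
        return [
            {"cluster": c, "id": i, "mode": self.mode}
            for c in sorted(self.members)
            for i in self.members[c]
        ]


def single_archetype(coordinates: np.ndarray, partition: Partition) -> ArchetypeSet:
    """One archetype per cluster: the member closest to the cluster centroid.

    The centroid is the mean coordinate of the members; ties are broken by
    id order (first member in the dataset ordering wins), for determinism.
    """
    X = np.asarray(coordinates, dtype=float)
    members: dict = {}
    for c in range(partition.k):
        idx = np.flatnonzero(partition.labels == c)
        if idx.size == 0:
            raise ValueError(f"cluster {c} is empty")
        centroid = X[idx].mean(axis=0)
        dists = np.linalg.norm(X[idx] - centroid, axis=1)
        members[c] = [partition.ids[idx[int(np.argmin(dists))]]]
    return ArchetypeSet(mode="single", members=members)


def multiple_archetypes(
    partition: Partition, fraction: float = 0.05, seed: int = 0
) -> ArchetypeSet:
    """Per cluster, a uniform sample (without replacement) of
    ceil(fraction * size) members, never fewer than one."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    members: dict = {}
    for c in range(partition.k):
        ids = partition.members(c)
        n_take = max(1, math.ceil(fraction * len(ids)))
        chosen = rng.choice(len(ids), size=n_take, replace=False)
        members[c] = [ids[i] for i in sorted(chosen)]
    return ArchetypeSet(
        mode="multiple", members=members, fraction=fraction, seed=seed
    )
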