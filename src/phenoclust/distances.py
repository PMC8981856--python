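"""Individual-level distances: the semantic distance and a Gower variant.

The semantic distance between two individuals A and B is the weighted mean
of per-variable distances over M, the set of variables observed in *both*
records:

    D(A, B) = sum_{i in M} w(i) d_AB(i) / sum_{i in M} w(i)

Qualitative per-variable distances d_AB(i) are looked up in the variable's
normalised modality matrix (so each lives on [0, 100]); quantitative ones
are |a - b| rescaled so the largest observed pairwise difference maps to
100.  Missing values are ignored, never imputed: when M is empty the pair's
distance is UNDEFINED (NaN) — a value, not an error.  Alongside D the
cardinality |M| is kept for every pair, since a distance computed from more
variables is more trustworthy.

The Gower variant mirrors the same missing-value handling: quantitative
variables contribute range-normalised Manhattan terms; qualitative ones are
dummy-coded (with an extra missing indicator) and compared with the Dice
dissimilarity, masking any pair flagged by the missing indicator.  The
final distance is the element-wise mean of the per-variable matrices over
defined entries, on [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import MISSING, Dataset, IndividualRecord

UNDEFINED = float("nan")


@dataclass
class IndividualDistanceMatrix:
    """Pairwise distances D plus per-pair variable counts |M|.

    ``D`` holds NaN for UNDEFINED pairs (no shared observed variable).
    Off-diagonal, D[i, j] is defined iff cardinality[i, j] >= 1; the
    diagonal is fixed at 0 with cardinality = the individual's number of
    observed variables (which may be 0 for an all-missing record).
    """

    ids: list
    D: np.ndarray
    cardinality: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.D = np.asarray(self.D, dtype=float)
        self.cardinality = np.asarray(self.cardinality, dtype=int)
        if self.D.shape != (n, n) or self.cardinality.shape != (n, n):
            raise ValueError("matrix shapes do not match id count")

    @property
    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(len(self.ids), k=1)
        return int(np.isnan(self.D[iu]).sum())

    def undefined_pairs(self) -> list:
        iu, ju = np.triu_indices(len(self.ids), k=1)
        mask = np.isnan(self.D[iu, ju])
        return [(self.ids[i], self.ids[j])
                for i, j in zip(iu[mask], ju[mask])]

    def to_frames(self) -> tuple:
        d = pd.DataFrame(self.D, index=self.ids, columns=self.ids)
        m = pd.DataFrame(self.cardinality, index=self.ids, columns=self.ids)
        return d, m


def quantitative_scales(dataset: Dataset) -> dict:
    """Max observed pairwise |difference| per quantitative variable.

    This is the normalisation constant mapping quantitative differences onto
    the same [0, 100] scale as the qualitative modality matrices.
    """
    scales = {}
    for spec in dataset.specs:
        if spec.kind != "quantitative":
            continue
        vals = np.array(
            [v for v in dataset.column(spec.name) if v is not MISSING],
            dtype=float,
        )
        scales[spec.name] = (
            float(vals.max() - vals.min()) if vals.size >= 2 else 0.0
        )
    return scales


def semantic_pair_distance(
    a: IndividualRecord,
    b: IndividualRecord,
    specs,
    matrices: dict,
    quant_scales: dict | None = None,
) -> tuple:
    """Semantic distance between two individuals: ``(D, |M|)``.

    ``matrices`` maps qualitative variable names to *normalised* modality
    matrices; ``quant_scales`` maps quantitative variable names to the
    dataset-wide max pairwise |difference| (see :func:`quantitative_scales`).
    Returns ``(nan, 0)`` when no variable is observed in both records.
    """
    quant_scales = quant_scales or {}
    num = 0.0
    den = 0.0
    m = 0
    for spec in specs:
        va = a.values.get(spec.name, MISSING)
        vb = b.values.get(spec.name, MISSING)
        if va is MISSING or vb is MISSING:
            continue
        if spec.kind == "qualitative":
            matrix = matrices[spec.name]
            if not matrix.normalised:
                raise ValueError(
                    f"{spec.name}: modality matrix must be normalised"
                )
            d = matrix.lookup(va, vb)
        else:
            scale = quant_scales.get(spec.name, 0.0)
            d = abs(float(va) - float(vb)) * 100.0 / scale if scale > 0 else 0.0
        num += spec.weight * d
        den += spec.weight
        m += 1
    if m == 0 or den == 0.0:
        return UNDEFINED, m
    return num / den, m


def _qualitative_codes(dataset: Dataset, name: str, labels: list) -> np.ndarray:
    """Integer codes per individual for one qualitative variable; -1 = missing."""
    index = {lab: i for i, lab in enumerate(labels)}
    codes = np.empty(len(dataset.individuals), dtype=int)
    for row, v in enumerate(dataset.column(name)):
        if v is MISSING:
            codes[row] = -1
        else:
            try:
                codes[row] = index[v]
            except KeyError:
                raise ValueError(
                    f"variable {name!r}: value {v!r} not in modality matrix"
                ) from None
    return codes


def semantic_distance_matrix(
    dataset: Dataset, matrices: dict, warn_undefined: bool = True
) -> IndividualDistanceMatrix:
    """Semantic distance over all pairs (vectorised form of Eq. above)."""
    n = len(dataset.individuals)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    card = np.zeros((n, n), dtype=int)
    scales = quantitative_scales(dataset)

    for spec in dataset.specs:
        if spec.kind == "qualitative":
            matrix = matrices[spec.name]
            if not matrix.normalised:
                raise ValueError(
                    f"{spec.name}: modality matrix must be normalised"
                )
            codes = _qualitative_codes(dataset, spec.name, matrix.labels)
            obs = codes >= 0
            both = np.outer(obs, obs)
            safe = np.where(obs, codes, 0)
            d = matrix.values[np.ix_(safe, safe)]
        else:
            vals = np.array(
                [np.nan if v is MISSING else float(v)
                 for v in dataset.column(spec.name)]
            )
            obs = np.isfinite(vals)
            both = np.outer(obs, obs)
            scale = scales[spec.name]
            diff = np.abs(np.subtract.outer(vals, vals))
            d = diff * (100.0 / scale) if scale > 0 else np.zeros((n, n))
            d = np.nan_to_num(d)
        num += np.where(both, spec.weight * d, 0.0)
        den += np.where(both, spec.weight, 0.0)
        card += both.astype(int)

    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    np.fill_diagonal(D, 0.0)

    idm = IndividualDistanceMatrix(ids=dataset.ids, D=D, cardinality=card)
    if warn_undefined and idm.n_undefined_pairs:
        warnings.warn(
            f"{idm.n_undefined_pairs} individual pairs share no observed "
            f"variable; their distance is UNDEFINED: "
            f"{idm.undefined_pairs()[:10]}",
            stacklevel=2,
        )
    return idm


def gower_distance_matrix(
    dataset: Dataset, range_normalise: bool = True
) -> IndividualDistanceMatrix:
    """Missing-aware Gower dissimilarity on [0, 1].

    Per variable: quantitative -> Manhattan |a-b| divided by the variable's
    observed range (``range_normalise=False`` keeps raw Manhattan);
    qualitative -> one-hot dummies plus a missing indicator, Dice
    dissimilarity on the dummies (0 if the modalities match, 1 otherwise),
    with pairs flagged by the missing indicator set to UNDEFINED.  The final
    D is the element-wise mean of per-variable matrices over defined
    entries; both-missing qualitative pairs stay UNDEFINED rather than
    counting as agreement.
    """
    n = len(dataset.individuals)
    total = np.zeros((n, n))
    card = np.zeros((n, n), dtype=int)

    for spec in dataset.specs:
        col = dataset.column(spec.name)
        if spec.kind == "qualitative":
            labels = sorted({v for v in col if v is not MISSING})
            codes = np.array(
                [-1 if v is MISSING else labels.index(v) for v in col]
            )
            obs = codes >= 0
            defined = np.outer(obs, obs)
            d = (codes[:, None] != codes[None, :]).astype(float)
        else:
            vals = np.array(
                [np.nan if v is MISSING else float(v) for v in col]
            )
            obs = np.isfinite(vals)
            defined = np.outer(obs, obs)
            d = np.abs(np.subtract.outer(vals, vals))
            d = np.nan_to_num(d)
            if range_normalise:
                finite = vals[obs]
                rng = float(finite.max() - finite.min()) if finite.size else 0.0
                d = d / rng if rng > 0 else np.zeros((n, n))
        total += np.where(defined, d, 0.0)
        card += defined.astype(int)

    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(card > 0, total / np.where(card > 0, card, 1), np.nan)
    np.fill_diagonal(D, 0.0)
    return IndividualDistanceMatrix(ids=dataset.ids, D=D, cardinality=card)
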