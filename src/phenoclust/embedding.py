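"""Projection of an individual distance matrix into coordinate space.

Three reductions are offered, mirroring common practice for distance-only
data:

* PCoA (classical MDS): eigendecomposition of the double-centred squared
  distance matrix.  Negative eigenvalues (non-Euclidean input) are reported
  but excluded from coordinates; no Cailliez/Lingoes correction is applied.
* metric MDS: SMACOF stress majorisation from several random starts.
* Laplacian eigenmaps: spectral embedding of a Gaussian affinity built from
  the distances, bandwidth = the median off-diagonal distance by default.

Quality is quantified with Kruskal's stress-1,

    stress1 = sqrt( sum_{j>i} (d̂_ij - d_ij)^2 / sum_{j>i} d_ij^2 ),

where d̂ are Euclidean distances between embedded rows; values below 0.2
are conventionally read as a good representation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist
from sklearn.manifold import smacof

from .distances import IndividualDistanceMatrix

logger = logging.getLogger("phenoclust")

_EIG_TOL = 1e-10


@dataclass
class Embedding:
    method: str  # 'pcoa' | 'mmds' | 'laplacian'
    coordinates: np.ndarray  # n x k
    ids: list
    eigenvalues: np.ndarray | None = None
    stress1: float | None = None
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        k = self.coordinates.shape[1]
        df = pd.DataFrame(
            self.coordinates,
            index=self.ids,
            columns=[f"dim_{i + 1}" for i in range(k)],
        )
        df.index.name = "id"
        return df


def resolve_undefined(
    idm: IndividualDistanceMatrix, policy: str = "error"
) -> IndividualDistanceMatrix:
    """Turn UNDEFINED pairs into usable observed distances.

    ``error`` refuses to proceed and lists the offending pairs;
    ``mean_impute`` substitutes the mean of the defined off-diagonal
    entries and logs how many entries were filled.
    """
    n_undef = idm.n_undefined_pairs
    if n_undef == 0:
        return idm
    if policy == "error":
        raise ValueError(
            f"{n_undef} UNDEFINED pairs (no shared observed variable): "
            f"{idm.undefined_pairs()[:20]}"
        )
    if policy == "mean_impute":
        D = idm.D.copy()
        iu = np.triu_indices(len(idm.ids), k=1)
        off = D[iu]
        fill = float(np.nanmean(off))
        mask = np.isnan(D)
        D[mask] = fill
        np.fill_diagonal(D, 0.0)
        logger.info(
            "resolve_undefined: imputed %d pairs with mean %.6g", n_undef, fill
        )
        return replace(idm, D=D)
    raise ValueError(f"unknown undefined policy {policy!r}")


def _check_observed(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains UNDEFINED entries; "
                         "apply resolve_undefined first")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    return D


def _unwrap(D, ids) -> tuple:
    """Accept an IndividualDistanceMatrix or a plain array; return (array, ids)."""
    if ids is None and hasattr(D, "ids"):
        ids = D.ids
    arr = _check_observed(getattr(D, "D", D))
    return arr, (list(ids) if ids is not None else list(range(arr.shape[0])))


def stress1(D_obs: np.ndarray, coordinates: np.ndarray) -> float:
    """Kruskal stress-1 between observed distances and embedded coordinates."""
    D_obs = np.asarray(D_obs, dtype=float)
    delta = D_obs[np.triu_indices(D_obs.shape[0], k=1)]
    denom = float((delta ** 2).sum())
    if denom == 0.0:
        raise ValueError("stress1 undefined: all observed distances are zero")
    delta_hat = pdist(np.asarray(coordinates, dtype=float))
    return float(np.sqrt(((delta_hat - delta) ** 2).sum() / denom))


def pcoa(D, k: int, ids=None) -> Embedding:
    """Principal Coordinates Analysis of a distance matrix.

    Double-centres -1/2 D∘D, eigendecomposes, and scales the top-k
    eigenvectors by the square roots of their (positive) eigenvalues.
    Raises if fewer than ``k`` positive eigenvalues exist.
    """
    D, ids = _unwrap(D, ids)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]

    tol = _EIG_TOL * max(abs(vals).max(), 1.0)
    n_pos = int((vals > tol).sum())
    if k > n_pos:
        raise ValueError(
            f"requested k={k} axes but only {n_pos} positive eigenvalues"
        )
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    emb = Embedding(
        method="pcoa",
        coordinates=coords,
        ids=ids,
        eigenvalues=vals,
    )
    emb.stress1 = stress1(D, coords)
    return emb


def metric_mds(
    D,
    k: int,
    seed: int = 0,
    n_init: int = 4,
    max_iter: int = 300,
    tol: float = 1e-6,
    ids=None,
) -> Embedding:
    """Metric MDS by SMACOF stress majorisation (best of ``n_init`` starts)."""
    D, ids = _unwrap(D, ids)
    coords, _, n_iter = smacof(
        D,
        metric=True,
        n_components=k,
        n_init=n_init,
        max_iter=max_iter,
        eps=tol,
        random_state=seed,
        return_n_iter=True,
        normalized_stress=False,
    )
    if n_iter >= max_iter:
        warnings.warn(
            f"metric MDS did not converge within {max_iter} iterations; "
            f"returning the best iterate",
            stacklevel=2,
        )
    return Embedding(
        method="mmds",
        coordinates=coords,
        ids=ids,
        stress1=stress1(D, coords),
        seed=seed,
    )


def laplacian_eigenmaps(
    D, k: int, bandwidth: float | None = None, ids=None
) -> Embedding:
    """Spectral embedding of the Gaussian affinity W = exp(-D² / 2σ²).

    σ defaults to the median off-diagonal distance (scale-adaptive and
    parameter-light).  Coordinates are the first k non-trivial generalised
    eigenvectors of the normalised Laplacian; the ascending non-trivial
    eigenvalue spectrum is reported for the scree diagnostic.
    """
    D, ids = _unwrap(D, ids)
    n = D.shape[0]
    if k > n - 1:
        raise ValueError(f"k={k} too large for {n} individuals")

    off = D[np.triu_indices(n, k=1)]
    if off.size and off.max() == 0.0:
        # identical points: degenerate zero-variance embedding
        return Embedding(
            method="laplacian",
            coordinates=np.zeros((n, k)),
            ids=ids,
            eigenvalues=np.zeros(n - 1),
        )

    sigma = bandwidth if bandwidth is not None else float(np.median(off))
    if sigma <= 0:
        sigma = float(off[off > 0].min())
    W = np.exp(-(D ** 2) / (2 * sigma ** 2))
    np.fill_diagonal(W, 0.0)  # self-loops play no role in the graph Laplacian

    n_comp, _ = connected_components(W > 1e-12, directed=False)
    if n_comp > 1:
        raise ValueError(
            f"affinity graph is disconnected ({n_comp} components); "
            f"increase the bandwidth"
        )

    deg = W.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    L_sym = np.eye(n) - (W * d_inv_sqrt[:, None]) * d_inv_sqrt[None, :]
    vals, vecs = eigh((L_sym + L_sym.T) / 2)
    # drop the trivial constant eigenvector (eigenvalue ~ 0)
    coords = (vecs * d_inv_sqrt[:, None])[:, 1 : k + 1]
    # deterministic sign: largest-magnitude entry of each axis is positive
    for j in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return Embedding(
        method="laplacian",
        coordinates=coords,
        ids=ids,
        eigenvalues=vals[1:],
    )


def select_dimensions(
    diagnostics, rule: str = "stress_threshold", threshold: float = 0.2
):
    """Choose (or report) the number of embedding dimensions.

    ``diagnostics`` maps k -> stress1 (dict or Series) for the
    ``stress_threshold`` rule, or is any series for ``report_only``.
    ``stress_threshold`` returns the smallest k with stress1 < threshold;
    ``report_only`` returns the series untouched — scree/stress elbows are
    read by eye, and automating that would invent a criterion.
    """
    series = pd.Series(dict(diagnostics)) if not isinstance(
        diagnostics, pd.Series
    ) else diagnostics
    if series.empty:
        raise ValueError("empty diagnostic series")
    if rule == "report_only":
        return series
    if rule == "stress_threshold":
        ok = series[series < threshold]
        if ok.empty:
            raise ValueError(
                f"no dimensionality reaches stress1 < {threshold}; "
                f"try more dimensions (best: {series.min():.3f})"
            )
        return int(ok.index.min())
    raise ValueError(f"unknown rule {rule!r}")


def stress_by_dimension(
    D, k_values, method: str = "mmds", seed: int = 0, **kwargs
) -> pd.Series:
    """stress1 as a function of embedding dimensionality (for Fig.-style
    diagnostics and the 0.2-threshold rule)."""
    out = {}
    for k in k_values:
        if method == "mmds":
            emb = metric_mds(D, k, seed=seed, **kwargs)
        elif method == "pcoa":
            emb = pcoa(D, k)
        else:
            raise ValueError(f"unsupported method {method!r} for stress series")
        out[k] = emb.stress1
    return pd.Series(out, name="stress1")
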