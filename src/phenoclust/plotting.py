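"""Decluttered scatterplot matrices and heatmaps.

The scatterplot matrix splits the usual symmetric grid in two: the lower
triangle shows the full population (cluster-coloured, transparent dots,
dot size growing with an individual's missing-value count as an uncertainty
cue), while the upper triangle shows only the archetypes plus per-cluster
kernel-density contours — a sparse view of the group envelopes.  The
default palette is legible under most colour-vision deficiencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from .archetypes import ArchetypeSet
from .clustering import ConcordanceTable, Partition
from .dataset import DEFAULT_PALETTE
from .embedding import Embedding


@dataclass
class PlotStyle:
    palette: list = field(default_factory=lambda: list(DEFAULT_PALETTE))
    alpha: float = 0.45
    size_base: float = 12.0
    size_step: float = 8.0  # strictly increasing in the missing count

    def size(self, n_missing: int) -> float:
        return self.size_base + self.size_step * n_missing


def _as_paths(out_path: str | Path) -> list:
    out = Path(out_path)
    stem = out.with_suffix("")
    return [stem.with_suffix(".png"), stem.with_suffix(".svg")]


def scatterplot_matrix(
    embedding: Embedding,
    partition: Partition,
    archetypes: ArchetypeSet,
    missing_counts,
    style: PlotStyle | None = None,
    out_path: str | Path = "scatterplot_matrix.png",
) -> list:
    """Render the dual-triangle scatterplot matrix; writes PNG and SVG.

    ``missing_counts`` maps individual id -> number of missing variables.
    Requires at least two embedding dimensions.
    """
    X = embedding.coordinates
    n, k_dims = X.shape
    if k_dims < 2:
        raise ValueError("scatterplot matrix needs at least 2 dimensions")
    style = style or PlotStyle()
    if len(style.palette) < partition.k:
        raise ValueError(
            f"palette has {len(style.palette)} colours for {partition.k} clusters"
        )

    mc = pd.Series(missing_counts)
    sizes = np.array([style.size(int(mc.get(i, 0))) for i in embedding.ids])
    colours = np.array([style.palette[lab] for lab in partition.labels])
    arch_idx = {
        c: [embedding.ids.index(i) for i in ids]
        for c, ids in archetypes.members.items()
    }

    fig, axes = plt.subplots(
        k_dims, k_dims, figsize=(2.4 * k_dims, 2.4 * k_dims), squeeze=False
    )
    for r in range(k_dims):
        for c in range(k_dims):
            ax = axes[r][c]
            if r == c:
                for lab in range(partition.k):
                    vals = X[partition.labels == lab, r]
                    if len(vals) > 1 and vals.std() > 0:
                        sns.kdeplot(
                            x=vals, ax=ax, color=style.palette[lab],
                            fill=False, warn_singular=False,
                        )
                ax.set_ylabel("")
            elif r > c:  # lower triangle: everyone
                ax.scatter(
                    X[:, c], X[:, r], c=colours, s=sizes, alpha=style.alpha,
                    linewidths=0,
                )
            else:  # upper triangle: archetypes + KDE contours
                for lab in range(partition.k):
                    mem = partition.labels == lab
                    if mem.sum() >= 3:
                        sub = X[mem][:, [c, r]]
                        if np.linalg.matrix_rank(np.cov(sub.T)) == 2:
                            sns.kdeplot(
                                x=sub[:, 0], y=sub[:, 1], ax=ax,
                                color=style.palette[lab], levels=4,
                                warn_singular=False,
                            )
                    idx = arch_idx.get(lab, [])
                    if idx:
                        ax.scatter(
                            X[idx, c], X[idx, r],
                            color=style.palette[lab], s=style.size_base * 2,
                            edgecolors="black", linewidths=0.5, zorder=3,
                        )
            if r == k_dims - 1:
                ax.set_xlabel(f"dim {c + 1}")
            if c == 0:
                ax.set_ylabel(f"dim {r + 1}")

    # legend: clusters + the dot-size <-> missing-count key
    handles = [
        plt.Line2D([], [], marker="o", linestyle="", color=style.palette[lab],
                   label=f"cluster {lab}")
        for lab in range(partition.k)
    ]
    for m in sorted({int(v) for v in mc.values})[:4]:
        handles.append(
            plt.Line2D([], [], marker="o", linestyle="", color="grey",
                       markersize=np.sqrt(style.size(m)),
                       label=f"{m} missing")
        )
    fig.legend(handles=handles, loc="upper left", fontsize="small",
               bbox_to_anchor=(1.0, 1.0))
    fig.tight_layout()

    paths = _as_paths(out_path)
    for p in paths:
        fig.savefig(p, bbox_inches="tight")
    plt.close(fig)
    return paths


def heatmap(matrix, labels=None, out_path: str | Path = "heatmap.png",
            title: str = "") -> list:
    """Colour-mapped image of a labelled matrix (distance or concordance)."""
    if isinstance(matrix, ConcordanceTable):
        df = matrix.counts
    elif isinstance(matrix, pd.DataFrame):
        df = matrix
    else:
        arr = np.asarray(matrix, dtype=float)
        if labels is not None:
            df = pd.DataFrame(arr, index=labels, columns=labels)
        else:
            df = pd.DataFrame(arr)
    if df.size == 0:
        raise ValueError("cannot draw a heatmap of an empty matrix")

    annotate = df.shape[0] <= 12
    fig, ax = plt.subplots(
        figsize=(max(3.0, 0.5 * df.shape[1] + 2), max(2.5, 0.5 * df.shape[0] + 1.5))
    )
    sns.heatmap(df, ax=ax, cmap="viridis", annot=annotate,
                fmt=".3g" if annotate else "", square=False)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    paths = _as_paths(out_path)
    for p in paths:
        fig.savefig(p, bbox_inches="tight")
    plt.close(fig)
    return paths


def diagnostic_plot(series: pd.Series, ylabel: str,
                    out_path: str | Path) -> list:
    """Scree / stress-versus-dimensions line plot for eyeballing elbows."""
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(list(series.index), list(series.values), marker="o")
    ax.set_xlabel("components")
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    paths = _as_paths(out_path)
    for p in paths:
        fig.savefig(p, bbox_inches="tight")
    plt.close(fig)
    return paths
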