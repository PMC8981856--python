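"""End-to-end orchestration: one YAML config drives the whole analysis.

Stages run in order — modality matrices, individual distances, embedding,
clustering, archetypes, figures — with every stage logged and all artifacts
written as plain files under the run's output directory.  Each stage reads
its inputs back from the artifacts of the previous one, so running the
stages one at a time (via the CLI subcommands) produces byte-identical
numeric artifacts to a single full run with the same config and seed.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import archetypes as arch
from . import clustering as clu
from . import embedding as emb
from . import plotting
from .dataset import (
    PipelineConfig,
    export_matrices,
    load_config,
    log_stage,
    read_dataset,
    read_matrix_csv,
    start_run_log,
)
from .distances import (
    IndividualDistanceMatrix,
    gower_distance_matrix,
    semantic_distance_matrix,
)
from .measures import read_lookup_table
from .modality import build_modality_matrix, normalise
from .ontology import read_concept_graph

# fixed per-stage seed offsets: one config seed, deterministic sub-seeds
_STAGE_SEED_OFFSET = {
    "distances": 101,
    "embed": 211,
    "cluster": 307,
    "archetypes": 401,
    "plot": 503,
}

_LOOKUP_KINDS = {
    "colour_table": "colour",
    "geo_table": "geo",
    "period_table": "period",
}

STAGES = ("distances", "embed", "cluster", "archetypes", "plot")


@dataclass
class RunArtifacts:
    """Where a run put its outputs."""

    output_dir: Path
    files: dict = field(default_factory=dict)

    def path(self, key: str) -> Path:
        return self.files[key]


class PipelineRun:
    """Stage-wise executor bound to one validated configuration."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = config.resolve(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        for sub in ("matrices", "distances", "embedding", "clustering",
                    "archetypes", "figures"):
            (self.out / sub).mkdir(exist_ok=True)
        self.logger = start_run_log(self.out / "run.log")
        self.artifacts = RunArtifacts(output_dir=self.out)

    def _stage_seed(self, stage: str) -> int:
        return (self.config.seed + _STAGE_SEED_OFFSET[stage]) % (2 ** 31)

    def _distances_requested(self) -> list:
        if self.config.distance == "both":
            return ["semantic", "gower"]
        return [self.config.distance]

    # -- stage 1: modality matrices + individual distance matrices ---------

    def stage_distances(self) -> None:
        cfg = self.config
        with log_stage(self.logger, "distances", distance=cfg.distance,
                       seed=cfg.seed):
            dataset = read_dataset(
                cfg.resolve(cfg.dataset), cfg.specs, base_dir=cfg.base_dir
            )
            matrices = {}
            for spec in cfg.specs:
                if spec.kind != "qualitative":
                    continue
                path = cfg.resolve(spec.source_path)
                if spec.source == "ontology_file":
                    source = read_concept_graph(path)
                else:
                    source = read_lookup_table(path, _LOOKUP_KINDS[spec.source])
                matrices[spec.name] = normalise(
                    build_modality_matrix(spec, source)
                )
            export_matrices(
                matrices, self.out / "matrices" / "modality_matrices.xlsx",
                self.out / "matrices",
            )

            exports = {}
            if "semantic" in self._distances_requested():
                idm = semantic_distance_matrix(dataset, matrices,
                                               warn_undefined=False)
                if idm.n_undefined_pairs:
                    self.logger.warning(
                        "semantic distance: %d UNDEFINED pairs",
                        idm.n_undefined_pairs,
                    )
                d, m = idm.to_frames()
                exports["semantic_D"], exports["semantic_M"] = d, m
            if "gower" in self._distances_requested():
                idm = gower_distance_matrix(dataset)
                d, m = idm.to_frames()
                exports["gower_D"], exports["gower_M"] = d, m
            export_matrices(
                exports, self.out / "distances" / "distances.xlsx",
                self.out / "distances",
            )
            dataset.missing_counts().rename("n_missing").to_csv(
                self.out / "distances" / "missing_counts.csv"
            )

    # -- stage 2: embedding + diagnostics -----------------------------------

    def _load_idm(self, name: str) -> IndividualDistanceMatrix:
        d = read_matrix_csv(self.out / "distances" / f"{name}_D.csv")
        m = read_matrix_csv(self.out / "distances" / f"{name}_M.csv")
        return IndividualDistanceMatrix(
            ids=[str(i) for i in d.index], D=d.values,
            cardinality=m.values.astype(int),
        )

    def stage_embed(self) -> None:
        cfg = self.config
        seed = self._stage_seed("embed")
        for name in self._distances_requested():
            with log_stage(self.logger, "embed", distance=name,
                           method=cfg.reduction_method, n_dims=cfg.n_dims,
                           seed=seed):
                idm = self._load_idm(name)
                observed = emb.resolve_undefined(idm, cfg.undefined_policy)
                if cfg.reduction_method == "pcoa":
                    e = emb.pcoa(observed, cfg.n_dims)
                elif cfg.reduction_method == "mmds":
                    e = emb.metric_mds(observed, cfg.n_dims, seed=seed)
                else:
                    e = emb.laplacian_eigenmaps(observed, cfg.n_dims)
                e.to_frame().to_csv(
                    self.out / "embedding" / f"coordinates_{name}.csv"
                )
                if e.eigenvalues is not None:
                    pd.Series(
                        e.eigenvalues, name="eigenvalue",
                        index=pd.RangeIndex(1, len(e.eigenvalues) + 1,
                                            name="component"),
                    ).to_csv(self.out / "embedding" / f"eigenvalues_{name}.csv")
                if cfg.reduction_method == "mmds":
                    series = emb.stress_by_dimension(
                        observed, range(1, cfg.n_dims + 1), seed=seed
                    )
                    series.rename_axis("k").to_csv(
                        self.out / "embedding" / f"stress_by_k_{name}.csv"
                    )
                if e.stress1 is not None:
                    self.logger.info("embed %s stress1=%.6f", name, e.stress1)

    # -- stage 3: clustering, silhouettes, concordances ---------------------

    def _load_coords(self, name: str) -> tuple:
        df = read_matrix_csv(self.out / "embedding" / f"coordinates_{name}.csv")
        return df.values, [str(i) for i in df.index]

    def stage_cluster(self) -> None:
        cfg = self.config
        seed = self._stage_seed("cluster")
        label_rows = []
        partitions: dict = {}
        for name in self._distances_requested():
            X, ids = self._load_coords(name)
            with log_stage(self.logger, "cluster", distance=name,
                           algorithms=",".join(cfg.algorithms),
                           k=",".join(map(str, cfg.k_values)), seed=seed):
                for algorithm in cfg.algorithms:
                    for k in cfg.k_values:
                        part = clu.cluster(X, algorithm, k, seed=seed, ids=ids)
                        partitions[(name, algorithm, k)] = part
                        df = part.to_frame()
                        df.insert(0, "distance", name)
                        label_rows.append(df)
                if cfg.silhouette_k_range:
                    prof_rows = []
                    for algorithm in cfg.algorithms:
                        prof = clu.silhouette_profile(
                            X, algorithm, cfg.silhouette_k_range, seed=seed
                        )
                        for k, v in prof.items():
                            prof_rows.append(
                                {"distance": name, "algorithm": algorithm,
                                 "k": k, "mean_silhouette": v}
                            )
                    pd.DataFrame(prof_rows).to_csv(
                        self.out / "clustering" / f"silhouette_profile_{name}.csv",
                        index=False,
                    )
        pd.concat(label_rows, ignore_index=True).to_csv(
            self.out / "clustering" / "labels.csv", index=False
        )

        # concordances: reference algorithm (kmeans when present) vs others
        ref_alg = "kmeans" if "kmeans" in cfg.algorithms else cfg.algorithms[0]
        for name in self._distances_requested():
            for k in cfg.k_values:
                ref = partitions[(name, ref_alg, k)]
                for algorithm in cfg.algorithms:
                    if algorithm == ref_alg:
                        continue
                    table = clu.concordance(ref, partitions[(name, algorithm, k)])
                    table.counts.to_csv(
                        self.out / "clustering" /
                        f"concordance_{name}_{ref_alg}_vs_{algorithm}_k{k}.csv"
                    )
        if cfg.distance == "both":
            for algorithm in cfg.algorithms:
                for k in cfg.k_values:
                    table = clu.concordance(
                        partitions[("semantic", algorithm, k)],
                        partitions[("gower", algorithm, k)],
                    )
                    table.counts.to_csv(
                        self.out / "clustering" /
                        f"concordance_semantic_vs_gower_{algorithm}_k{k}.csv"
                    )

    # -- stage 4: archetypes -------------------------------------------------

    def _load_partition(self, name: str, algorithm: str, k: int) -> clu.Partition:
        df = pd.read_csv(self.out / "clustering" / "labels.csv",
                         dtype={"id": str})
        sel = df[(df["distance"] == name) & (df["algorithm"] == algorithm)
                 & (df["k"] == k)]
        if sel.empty:
            raise ValueError(
                f"no stored labels for {name}/{algorithm}/k={k}; "
                f"run the cluster stage first"
            )
        return clu.Partition(ids=list(sel["id"]),
                             labels=sel["label"].to_numpy(),
                             algorithm=algorithm, k=k)

    def stage_archetypes(self) -> None:
        cfg = self.config
        seed = self._stage_seed("archetypes")
        primary_alg = cfg.algorithms[0]
        rows = []
        for name in self._distances_requested():
            X, ids = self._load_coords(name)
            with log_stage(self.logger, "archetypes", distance=name,
                           mode=cfg.archetype_mode, seed=seed):
                for k in cfg.k_values:
                    part = self._load_partition(name, primary_alg, k)
                    if cfg.archetype_mode == "single":
                        aset = arch.single_archetype(X, part)
                    else:
                        aset = arch.multiple_archetypes(
                            part, fraction=cfg.archetype_fraction, seed=seed
                        )
                    for rec in aset.to_records():
                        rec.update(distance=name, algorithm=primary_alg, k=k)
                        rows.append(rec)
        pd.DataFrame(rows).to_csv(
            self.out / "archetypes" / "archetypes.csv", index=False
        )

    # -- stage 5: figures ------------------------------------------------------

    def stage_plot(self) -> None:
        cfg = self.config
        primary_alg = cfg.algorithms[0]
        k = cfg.k_values[0]
        style = plotting.PlotStyle(palette=list(cfg.palette))
        missing = pd.read_csv(
            self.out / "distances" / "missing_counts.csv", index_col=0,
            dtype={0: str},
        )["n_missing"]
        missing.index = missing.index.astype(str)
        for name in self._distances_requested():
            with log_stage(self.logger, "plot", distance=name):
                d = read_matrix_csv(self.out / "distances" / f"{name}_D.csv")
                plotting.heatmap(
                    d.fillna(d.stack().mean()),
                    out_path=self.out / "figures" / f"heatmap_{name}_D.png",
                    title=f"{name} distance",
                )
                X, ids = self._load_coords(name)
                part = self._load_partition(name, primary_alg, k)
                adf = pd.read_csv(self.out / "archetypes" / "archetypes.csv",
                                  dtype={"id": str})
                sel = adf[(adf["distance"] == name) & (adf["k"] == k)]
                aset = arch.ArchetypeSet(
                    mode=cfg.archetype_mode,
                    members={c: list(g["id"]) for c, g in sel.groupby("cluster")},
                )
                e = emb.Embedding(method=cfg.reduction_method, coordinates=X,
                                  ids=ids)
                if X.shape[1] >= 2:
                    plotting.scatterplot_matrix(
                        e, part, aset, missing, style=style,
                        out_path=self.out / "figures" / f"scatter_{name}.png",
                    )
                eig_path = self.out / "embedding" / f"eigenvalues_{name}.csv"
                if eig_path.exists():
                    s = pd.read_csv(eig_path, index_col=0)["eigenvalue"]
                    plotting.diagnostic_plot(
                        s, "eigenvalue",
                        self.out / "figures" / f"scree_{name}.png",
                    )
                stress_path = self.out / "embedding" / f"stress_by_k_{name}.csv"
                if stress_path.exists():
                    s = pd.read_csv(stress_path, index_col=0)["stress1"]
                    plotting.diagnostic_plot(
                        s, "stress1",
                        self.out / "figures" / f"stress_{name}.png",
                    )
        for path in (self.out / "clustering").glob("concordance_*.csv"):
            plotting.heatmap(
                read_matrix_csv(path),
                out_path=self.out / "figures" / f"{path.stem}.png",
                title=path.stem.replace("_", " "),
            )

    def run(self, stages=STAGES) -> RunArtifacts:
        for stage in stages:
            getattr(self, f"stage_{stage}")()
        self.artifacts.files = {
            p.relative_to(self.out).as_posix(): p
            for p in sorted(self.out.rglob("*")) if p.is_file()
        }
        return self.artifacts


def run_pipeline(config: PipelineConfig | str | Path,
                 stages=STAGES) -> RunArtifacts:
    """Execute the pipeline (or a subset of stages) for a config or YAML path."""
    if not isinstance(config, PipelineConfig):
        path = Path(config)
        cfg = load_config(path)
        run = PipelineRun(cfg)
        shutil.copy(path, run.out / "config_echo.yaml")
        return run.run(stages)
    return PipelineRun(config).run(stages)
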