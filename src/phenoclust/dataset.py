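"""Trait-table and configuration I/O: the package's data model.

A dataset is a table of individuals (rows) by typed variables (columns),
with explicit missing values.  Qualitative variables take modality labels
validated against the variable's distance source; quantitative variables
take finite reals.  Missingness is first-class: an empty cell or the
literal token ``NA`` (case-sensitive) means MISSING, anything else in a
qualitative column must be a declared modality.
"""

from __future__ import annotations

import logging
import math
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

MISSING = None  # internal encoding of a missing cell
_MISSING_TOKENS = {"", "NA"}

QUALITATIVE_SOURCES = ("ontology_file", "colour_table", "geo_table", "period_table")


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one variable: its kind, distance source and weight."""

    name: str
    kind: str  # 'qualitative' | 'quantitative'
    source: str  # 'ontology_file' | 'colour_table' | 'geo_table' | 'period_table' | 'numeric'
    source_path: str = ""
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("qualitative", "quantitative"):
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")
        if self.weight < 0:
            raise ValueError(f"{self.name}: weight must be non-negative")
        if self.kind == "quantitative":
            if self.source != "numeric":
                raise ValueError(
                    f"{self.name}: quantitative variables must have source "
                    f"'numeric', got {self.source!r}"
                )
        else:
            if self.source not in QUALITATIVE_SOURCES:
                raise ValueError(
                    f"{self.name}: qualitative source must be one of "
                    f"{QUALITATIVE_SOURCES}, got {self.source!r}"
                )
            if not self.source_path:
                raise ValueError(
                    f"{self.name}: qualitative variables must name a source file"
                )


@dataclass(frozen=True)
class IndividualRecord:
    """One individual: an id and an ordered variable -> value mapping."""

    id: str
    values: dict

    def observed(self) -> list:
        return [k for k, v in self.values.items() if v is not MISSING]

    def n_missing(self) -> int:
        return sum(1 for v in self.values.values() if v is MISSING)


@dataclass
class Dataset:
    """Individuals x typed variables, with explicit missingness."""

    individuals: list  # list[IndividualRecord]
    specs: list  # list[VariableSpec]

    def __post_init__(self) -> None:
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicated individual ids: {dupes}")
        names = {s.name for s in self.specs}
        for ind in self.individuals:
            unknown = set(ind.values) - names
            if unknown:
                raise ValueError(
                    f"individual {ind.id!r} has undeclared variables: "
                    f"{sorted(unknown)}"
                )

    @property
    def ids(self) -> list:
        return [ind.id for ind in self.individuals]

    def spec(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def column(self, name: str) -> list:
        return [ind.values.get(name, MISSING) for ind in self.individuals]

    def missing_counts(self) -> pd.Series:
        return pd.Series(
            [ind.n_missing() for ind in self.individuals], index=self.ids
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view; missing cells become empty strings (lossless for
        non-missing cells under the package's missing-token convention)."""
        rows = {}
        for ind in self.individuals:
            rows[ind.id] = {
                s.name: ("" if ind.values.get(s.name) is MISSING
                         else ind.values[s.name])
                for s in self.specs
            }
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "id"
        return df


def _modality_sets(specs, base_dir: Path) -> dict:
    """Load the declared modality set of each qualitative variable."""
    from .measures import read_lookup_table
    from .ontology import read_concept_graph

    kinds = {"colour_table": "colour", "geo_table": "geo", "period_table": "period"}
    out = {}
    for s in specs:
        if s.kind != "qualitative":
            continue
        path = Path(s.source_path)
        if not path.is_absolute():
            path = base_dir / path
        if s.source == "ontology_file":
            out[s.name] = set(read_concept_graph(path).leaves)
        else:
            out[s.name] = set(read_lookup_table(path, kinds[s.source]))
    return out


def read_dataset(
    table_path: str | Path,
    specs: list,
    validate: bool = True,
    base_dir: str | Path | None = None,
) -> Dataset:
    """Read a CSV/TSV trait table (header row, first column = individual id).

    Empty cells and the token ``NA`` become MISSING.  Row order is
    preserved.  With ``validate=True`` every qualitative value is checked
    against the variable's modality set, loaded from its distance source
    (paths resolved relative to ``base_dir``, default: the table's folder).
    """
    table_path = Path(table_path)
    sep = "\t" if table_path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(table_path, sep=sep, dtype=str, keep_default_na=False)

    id_col = df.columns[0]
    declared = [s.name for s in specs]
    unknown = [c for c in df.columns[1:] if c not in declared]
    if unknown:
        raise ValueError(f"{table_path.name}: unknown columns {unknown}")
    absent = [n for n in declared if n not in df.columns[1:]]
    if absent:
        raise ValueError(f"{table_path.name}: missing columns {absent}")

    base = Path(base_dir) if base_dir is not None else table_path.parent
    modality_sets = _modality_sets(specs, base) if validate else {}

    by_name = {s.name: s for s in specs}
    individuals = []
    for _, row in df.iterrows():
        ind_id = str(row[id_col])
        values = {}
        for name in declared:
            raw = row[name].strip()
            if raw in _MISSING_TOKENS:
                values[name] = MISSING
                continue
            spec = by_name[name]
            if spec.kind == "quantitative":
                try:
                    v = float(raw)
                except ValueError:
                    raise ValueError(
                        f"individual {ind_id!r}, variable {name!r}: "
                        f"non-numeric value {raw!r}"
                    ) from None
                if not math.isfinite(v):
                    raise ValueError(
                        f"individual {ind_id!r}, variable {name!r}: "
                        f"non-finite value {raw!r}"
                    )
                values[name] = v
            else:
                if validate and raw not in modality_sets[name]:
                    raise ValueError(
                        f"individual {ind_id!r}, variable {name!r}: value "
                        f"{raw!r} is not a declared modality"
                    )
                values[name] = raw
        individuals.append(IndividualRecord(id=ind_id, values=values))
    return Dataset(individuals=individuals, specs=list(specs))


def write_dataset(dataset: Dataset, path: str | Path) -> Path:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    dataset.to_frame().to_csv(path, sep=sep)
    return path


def export_matrices(
    matrices: dict, xlsx_path: str | Path, csv_dir: str | Path
) -> dict:
    """Export named square labelled matrices to one workbook + one CSV each.

    Accepts ``pandas.DataFrame`` or objects exposing ``to_frame()``.
    Re-reading the CSVs reproduces values to full printed precision.
    """
    if not matrices:
        raise ValueError("no matrices to export")
    frames = {}
    for name, m in matrices.items():
        df = m if isinstance(m, pd.DataFrame) else m.to_frame()
        if df.shape[0] != df.shape[1]:
            raise ValueError(f"matrix {name!r} is not square: {df.shape}")
        frames[name] = df

    xlsx_path = Path(xlsx_path)
    csv_dir = Path(csv_dir)
    csv_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    with pd.ExcelWriter(xlsx_path, engine="openpyxl") as writer:
        for name, df in frames.items():
            df.to_excel(writer, sheet_name=str(name)[:31])
            csv_path = csv_dir / f"{name}.csv"
            df.to_csv(csv_path)
            paths[name] = csv_path
    paths["__workbook__"] = xlsx_path
    return paths


def read_matrix_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


# ---------------------------------------------------------------------------
# Run tracing


def start_run_log(log_path: str | Path, name: str = "phenoclust",
                  level: int = logging.INFO) -> logging.Logger:
    """Set up an append-only per-run log file and return the logger."""
    logger = logging.getLogger(name)
    logger.setLevel(level)
    handler = logging.FileHandler(log_path, mode="a", encoding="utf-8")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    logger.addHandler(handler)
    return logger


@contextmanager
def log_stage(logger: logging.Logger, stage: str, **params):
    """Emit start/end lines around a pipeline stage; log failures before exit."""
    detail = " ".join(f"{k}={v}" for k, v in params.items())
    logger.info("stage %s start %s", stage, detail)
    try:
        yield
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise
    logger.info("stage %s end", stage)


# ---------------------------------------------------------------------------
# Pipeline configuration

DEFAULT_PALETTE = [  # 8-colour set legible under most colour-vision deficiencies
    "#000000", "#E69F00", "#56B4E9", "#009E73",
    "#F0E442", "#0072B2", "#D55E00", "#CC79A7",
]

ALGORITHMS = ("birch", "gmm", "ward", "kmeans", "kmedoids", "spectral")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (one YAML file drives a whole run)."""

    dataset: Path
    specs: list
    distance: str = "semantic"  # 'semantic' | 'gower' | 'both'
    reduction_method: str = "pcoa"  # 'pcoa' | 'mmds' | 'laplacian'
    n_dims: int = 4
    undefined_policy: str = "error"  # 'error' | 'mean_impute'
    algorithms: list = field(default_factory=lambda: ["kmeans"])
    k_values: list = field(default_factory=lambda: [3])
    silhouette_k_range: list | None = None
    archetype_mode: str = "single"  # 'single' | 'multiple'
    archetype_fraction: float = 0.05
    seed: int = 0
    palette: list = field(default_factory=lambda: list(DEFAULT_PALETTE))
    output_dir: Path = Path("phenoclust_run")
    base_dir: Path = Path(".")

    def __post_init__(self) -> None:
        if self.distance not in ("semantic", "gower", "both"):
            raise ValueError(f"unknown distance {self.distance!r}")
        if self.reduction_method not in ("pcoa", "mmds", "laplacian"):
            raise ValueError(f"unknown reduction {self.reduction_method!r}")
        if self.n_dims < 1:
            raise ValueError("n_dims must be >= 1")
        if not 0 < self.archetype_fraction <= 1:
            raise ValueError("archetype fraction must be in (0, 1]")
        if self.archetype_mode not in ("single", "multiple"):
            raise ValueError(f"unknown archetype mode {self.archetype_mode!r}")
        for a in self.algorithms:
            if a not in ALGORITHMS:
                raise ValueError(f"unknown clustering algorithm {a!r}")
        if not self.k_values or any(k < 1 for k in self.k_values):
            raise ValueError("clustering k values must be positive")

    def resolve(self, p: str | Path) -> Path:
        p = Path(p)
        return p if p.is_absolute() else self.base_dir / p


def _spec_from_mapping(m: dict) -> VariableSpec:
    return VariableSpec(
        name=m["name"],
        kind=m["kind"],
        source=m.get("source", "numeric" if m["kind"] == "quantitative" else ""),
        source_path=m.get("path", m.get("source_path", "")),
        weight=float(m.get("weight", 1.0)),
    )


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML pipeline configuration.

    Top-level keys: ``dataset``, ``variables``, ``distance``, ``reduction``,
    ``clustering``, ``archetypes``, ``seed``, ``palette``, ``output_dir``.
    Relative paths are resolved against the config file's folder.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}

    base = path.parent
    specs = [_spec_from_mapping(m) for m in raw.get("variables", [])]
    if not specs:
        raise ValueError(f"{path.name}: no variables declared")

    reduction = raw.get("reduction", {}) or {}
    clustering = raw.get("clustering", {}) or {}
    archetypes = raw.get("archetypes", {}) or {}
    ks = clustering.get("k", 3)
    if isinstance(ks, int):
        ks = [ks]
    sil = clustering.get("silhouette_k_range")

    return PipelineConfig(
        dataset=Path(raw["dataset"]),
        specs=specs,
        distance=raw.get("distance", "semantic"),
        reduction_method=reduction.get("method", "pcoa"),
        n_dims=int(reduction.get("n_dims", 4)),
        undefined_policy=reduction.get("undefined_policy", "error"),
        algorithms=list(clustering.get("algorithms", ["kmeans"])),
        k_values=[int(k) for k in ks],
        silhouette_k_range=[int(k) for k in sil] if sil else None,
        archetype_mode=archetypes.get("mode", "single"),
        archetype_fraction=float(archetypes.get("fraction", 0.05)),
        seed=int(raw.get("seed", 0)),
        palette=list(raw.get("palette", DEFAULT_PALETTE)),
        output_dir=Path(raw.get("output_dir", "phenoclust_run")),
        base_dir=base,
    )
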