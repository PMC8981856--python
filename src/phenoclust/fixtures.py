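"""Bundled fixtures: printed ontology variants and synthetic lookup tables.

The three "Quantity of prickles" ontology variants carry the published
expert distance matrices (the reference hand-tailored values, an ordinal
variant with no subgroup separation, and an all-equidistant variant).  The
colour, geographic-region and trait-table fixtures are *synthetic*
stand-ins constructed for demonstration and testing (the original rosebush
dataset is available only on request); the breeding-period table uses the
published open-ended bound conventions (<1700 starts at 1600, >1920 ends at
2020) around reconstructed intermediate period labels.
"""

from __future__ import annotations

import shutil
from importlib import resources
from pathlib import Path

from .ontology import ConceptGraph, read_concept_graph, write_concept_graph

PRICKLES_VARIANTS = ("normal", "no_separation", "equidistant")

_FILES = {
    "prickles_normal": "prickles_normal.csv",
    "prickles_no_separation": "prickles_no_separation.csv",
    "prickles_equidistant": "prickles_equidistant.csv",
    "prickles_owl": "prickles.owl",
    "colours": "colours_synthetic.csv",
    "regions": "regions_synthetic.csv",
    "periods": "periods_synthetic.csv",
    "demo_dataset": "traits_demo_synthetic.csv",
    "demo_config": "demo_config.yaml",
}

# Canonical modality order of the prickles variable, as printed.
PRICKLES_ORDER = ["Low", "Medium", "High", "Very high"]


def fixture_path(name: str) -> Path:
    """Filesystem path of a bundled fixture (see ``builtin_fixtures``)."""
    if name not in _FILES:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(_FILES)}")
    return Path(resources.files("phenoclust.data") / _FILES[name])


def builtin_fixtures() -> dict:
    """Name -> path mapping of every bundled fixture file."""
    return {name: fixture_path(name) for name in _FILES}


def prickles_graph(variant: str = "normal") -> ConceptGraph:
    """The prickles concept graph in one of its three published variants."""
    if variant not in PRICKLES_VARIANTS:
        raise ValueError(
            f"unknown variant {variant!r}; choose from {PRICKLES_VARIANTS}"
        )
    return read_concept_graph(fixture_path(f"prickles_{variant}"), "csv")


def materialize_demo(directory: str | Path) -> Path:
    """Copy the demo workspace (table, sources, config) into ``directory``.

    Returns the path of the YAML config, ready for
    :func:`phenoclust.pipeline.run_pipeline`.  The OWL form of the prickles
    ontology is written on the fly from the normal variant.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in ("colours", "regions", "periods", "demo_dataset", "demo_config"):
        shutil.copy(fixture_path(name), directory / _FILES[name])
    write_concept_graph(prickles_graph("normal"), directory / "prickles.owl", "owl")
    return directory / _FILES["demo_config"]
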