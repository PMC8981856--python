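"""Ontologies carrying expert pairwise distances between concepts.

For qualitative variables with no measurable interpretation (e.g. quantity
of prickles) the modalities are organised by domain experts as a small
concept graph, and the distance between every pair of *leaf* concepts is a
hand-tailored expert judgement stored alongside the graph.  Two on-disk
dialects are supported:

OWL (RDF/XML)
    Concepts are ``owl:Class`` nodes with ``rdfs:label``; the hierarchy is
    ``rdfs:subClassOf``.  A distance is an object-property assertion
    ``A has_distance B`` annotated (via an ``owl:Axiom`` node) with a real
    ``distance`` data property.  A reified alternative is also read: an
    individual of class ``ConceptDistance`` with ``source``, ``target`` and
    ``distance`` properties.  Writing always emits the annotated-assertion
    form.

CSV edge list
    Header ``concept_a,concept_b,distance``.  A numeric third field is an
    expert distance; the literal ``is_a`` marks a hierarchy edge
    (parent, child); an empty ``concept_b`` declares a bare concept (used
    to preserve concept order and isolated concepts on round trips).

Distances are stored one-directional and mirrored on read; storing the same
pair twice is only an error when the values conflict.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from urllib.parse import quote, unquote

import networkx as nx
from rdflib import Graph, Literal, Namespace, RDF, RDFS, OWL, URIRef
from rdflib.namespace import XSD

from .modality import ModalityDistanceMatrix

NS = Namespace("http://phenoclust.org/onto#")

import numpy as np


def _pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class ConceptGraph:
    """Concept labels, is_a hierarchy and expert leaf-pair distances."""

    concepts: list[str] = field(default_factory=list)
    is_a: set = field(default_factory=set)  # set[(parent, child)]
    distances: dict = field(default_factory=dict)  # {(a, b) sorted: float}

    def __post_init__(self) -> None:
        if len(set(self.concepts)) != len(self.concepts):
            dupes = [c for c in set(self.concepts) if self.concepts.count(c) > 1]
            raise ValueError(f"duplicate concept labels: {dupes}")
        known = set(self.concepts)
        for parent, child in self.is_a:
            if parent not in known or child not in known:
                raise ValueError(f"is_a edge ({parent}, {child}) names unknown concept")
        for (a, b), d in self.distances.items():
            if (a, b) != _pair(a, b):
                raise ValueError(f"distance key ({a}, {b}) not in canonical order")
            if a not in known or b not in known:
                raise ValueError(f"distance pair ({a}, {b}) names unknown concept")
            if d < 0:
                raise ValueError(f"negative distance {d} for pair ({a}, {b})")

    def __eq__(self, other) -> bool:
        # structural equality: concept declaration order is presentation,
        # not semantics (RDF files are statement sets)
        if not isinstance(other, ConceptGraph):
            return NotImplemented
        return (
            set(self.concepts) == set(other.concepts)
            and self.is_a == other.is_a
            and self.distances == other.distances
        )

    @property
    def leaves(self) -> list[str]:
        """Concepts that are not the parent of any is_a edge, in declared order."""
        parents = {p for p, _ in self.is_a}
        return [c for c in self.concepts if c not in parents]

    def distance(self, a: str, b: str):
        if a == b:
            return 0.0
        return self.distances.get(_pair(a, b))


class _DistanceAccumulator:
    """Collects (pair, value) statements, rejecting conflicting duplicates."""

    def __init__(self) -> None:
        self.values: dict[tuple[str, str], float] = {}

    def add(self, a: str, b: str, d: float) -> None:
        if d < 0:
            raise ValueError(f"negative distance {d} between {a!r} and {b!r}")
        key = _pair(a, b)
        if key in self.values and self.values[key] != d:
            raise ValueError(
                f"conflicting distances for pair {key}: "
                f"{self.values[key]} vs {d}"
            )
        self.values[key] = d


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    if path.suffix.lower() in {".owl", ".rdf", ".xml"}:
        return "owl"
    if path.suffix.lower() == ".csv":
        return "csv"
    raise ValueError(f"cannot infer ontology format from {path.name!r}")


def read_concept_graph(path: str | Path, format: str | None = None) -> ConceptGraph:
    """Read a concept graph with expert distances from OWL or CSV."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "owl":
        return _read_owl(path)
    if fmt == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown ontology format {format!r}")


def _read_csv(path: Path) -> ConceptGraph:
    concepts: list[str] = []
    seen: set[str] = set()
    is_a: set[tuple[str, str]] = set()
    acc = _DistanceAccumulator()

    def declare(label: str) -> None:
        if label and label not in seen:
            seen.add(label)
            concepts.append(label)

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"concept_a", "concept_b", "distance"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"{path.name}: header must contain columns {sorted(required)}"
            )
        for row in reader:
            a = row["concept_a"].strip()
            b = (row["concept_b"] or "").strip()
            raw = (row["distance"] or "").strip()
            declare(a)
            declare(b)
            if not b:
                continue  # bare concept declaration
            if raw == "is_a":
                is_a.add((a, b))
            else:
                try:
                    d = float(raw)
                except ValueError:
                    raise ValueError(
                        f"{path.name}: malformed distance {raw!r} "
                        f"for pair ({a}, {b})"
                    ) from None
                acc.add(a, b, d)
    return ConceptGraph(concepts=concepts, is_a=is_a, distances=acc.values)


def _uri(label: str) -> URIRef:
    return NS[quote(label, safe="")]


def _label_of(g: Graph, node) -> str:
    lab = g.value(node, RDFS.label)
    if lab is not None:
        return str(lab)
    return unquote(str(node).rsplit("#", 1)[-1])


def _read_owl(path: Path) -> ConceptGraph:
    g = Graph()
    g.parse(path, format="xml")

    class_nodes = [
        s
        for s in g.subjects(RDF.type, OWL.Class)
        if isinstance(s, URIRef) and s != NS["ConceptDistance"]
    ]
    labels = {node: _label_of(g, node) for node in class_nodes}
    # rdflib iteration order is not guaranteed stable across statement
    # permutations -> sort alphabetically for order-stable extraction.
    concepts = sorted(labels.values())

    is_a = set()
    for child, parent in g.subject_objects(RDFS.subClassOf):
        if child in labels and parent in labels:
            is_a.add((labels[parent], labels[child]))

    acc = _DistanceAccumulator()
    # Form 1: annotated object-property assertions (owl:Axiom).
    for ax in g.subjects(RDF.type, OWL.Axiom):
        if g.value(ax, OWL.annotatedProperty) != NS["has_distance"]:
            continue
        src = g.value(ax, OWL.annotatedSource)
        tgt = g.value(ax, OWL.annotatedTarget)
        lit = g.value(ax, NS["distance"])
        if src in labels and tgt in labels and lit is not None:
            acc.add(labels[src], labels[tgt], float(lit))
    # Form 2: reified ConceptDistance individuals.
    for node in g.subjects(RDF.type, NS["ConceptDistance"]):
        src = g.value(node, NS["source"])
        tgt = g.value(node, NS["target"])
        lit = g.value(node, NS["distance"])
        if src in labels and tgt in labels and lit is not None:
            acc.add(labels[src], labels[tgt], float(lit))

    return ConceptGraph(concepts=concepts, is_a=is_a, distances=acc.values)


def write_concept_graph(
    graph: ConceptGraph, path: str | Path, format: str | None = None
) -> Path:
    """Write a concept graph; ``read_concept_graph`` round-trips it.

    For OWL, concept order is alphabetical on re-read (the RDF model is a
    statement set); CSV preserves the declared order exactly.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["concept_a", "concept_b", "distance"])
            for c in graph.concepts:
                w.writerow([c, "", ""])
            for parent, child in sorted(graph.is_a):
                w.writerow([parent, child, "is_a"])
            for (a, b), d in sorted(graph.distances.items()):
                w.writerow([a, b, repr(d)])
        return path
    if fmt == "owl":
        g = Graph()
        g.bind("", NS)
        g.bind("owl", OWL)
        g.add((NS["has_distance"], RDF.type, OWL.ObjectProperty))
        g.add((NS["distance"], RDF.type, OWL.DatatypeProperty))
        for c in graph.concepts:
            node = _uri(c)
            g.add((node, RDF.type, OWL.Class))
            g.add((node, RDFS.label, Literal(c)))
        for parent, child in sorted(graph.is_a):
            g.add((_uri(child), RDFS.subClassOf, _uri(parent)))
        for i, ((a, b), d) in enumerate(sorted(graph.distances.items())):
            g.add((_uri(a), NS["has_distance"], _uri(b)))
            ax = NS[f"axiom_{i}"]
            g.add((ax, RDF.type, OWL.Axiom))
            g.add((ax, OWL.annotatedSource, _uri(a)))
            g.add((ax, OWL.annotatedProperty, NS["has_distance"]))
            g.add((ax, OWL.annotatedTarget, _uri(b)))
            g.add((ax, NS["distance"], Literal(d, datatype=XSD.double)))
        g.serialize(destination=str(path), format="xml")
        return path
    raise ValueError(f"unknown ontology format {format!r}")


def expert_distance_matrix(
    graph: ConceptGraph,
    variable: str = "",
    order: list[str] | None = None,
    path_fallback: bool = False,
) -> ModalityDistanceMatrix:
    """Extract the leaf-pair expert distance matrix of a concept graph.

    Every unordered leaf pair must carry an expert distance.  With
    ``path_fallback=True`` a missing pair may instead be filled with the sum
    of expert distances along the unique is_a tree path between the leaves,
    provided every edge on that path is itself annotated; this is off by
    default because hand-tailored leaf-pair distances are the reference.
    """
    labels = order if order is not None else graph.leaves
    unknown = [l for l in labels if l not in graph.concepts]
    if unknown:
        raise ValueError(f"order names unknown concepts: {unknown}")

    tree = None
    if path_fallback:
        tree = nx.Graph()
        tree.add_nodes_from(graph.concepts)
        tree.add_edges_from((p, c) for p, c in graph.is_a)

    n = len(labels)
    values = np.zeros((n, n), dtype=float)
    missing = []
    for i in range(n):
        for j in range(i + 1, n):
            d = graph.distance(labels[i], labels[j])
            if d is None and path_fallback:
                d = _path_sum(graph, tree, labels[i], labels[j])
            if d is None:
                missing.append(_pair(labels[i], labels[j]))
            else:
                values[i, j] = values[j, i] = d
    if missing:
        raise ValueError(
            f"no expert distance for leaf pairs: {sorted(set(missing))}"
        )
    return ModalityDistanceMatrix(
        variable=variable, labels=list(labels), values=values, normalised=False
    )


def _path_sum(graph: ConceptGraph, tree: nx.Graph, a: str, b: str):
    try:
        nodes = nx.shortest_path(tree, a, b)
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        return None
    total = 0.0
    for u, v in zip(nodes, nodes[1:]):
        d = graph.distance(u, v)
        if d is None:
            return None
        total += d
    return total
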