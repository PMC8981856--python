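"""Build per-variable modality distance matrices from their sources.

Reads the bundled expert ontology for the quantity-of-prickles variable and
the synthetic colour lookup table, builds the raw distance matrices, and
normalises them onto the common [0, 100] scale that keeps variables with
wildly different units (expert scores vs ΔE) comparable.
"""

from phenoclust import (
    VariableSpec,
    build_modality_matrix,
    expert_distance_matrix,
    normalise,
    read_lookup_table,
)
from phenoclust.fixtures import PRICKLES_ORDER, fixture_path, prickles_graph

graph = prickles_graph("normal")
raw = expert_distance_matrix(graph, variable="prickles", order=PRICKLES_ORDER)
print("Expert distance matrix (raw units, hand-tailored):")
print(raw.to_frame().round(1), "\n")

norm = normalise(raw)
print("Normalised onto [0, 100] (largest expert distance -> 100):")
print(norm.to_frame().round(2), "\n")

colours = read_lookup_table(fixture_path("colours"), "colour")
spec = VariableSpec(name="petal_colour", kind="qualitative",
                    source="colour_table", source_path="colours.csv")
colour_matrix = normalise(build_modality_matrix(spec, colours))
print("Colour matrix (ΔE in L*a*b*, normalised), first rows:")
print(colour_matrix.to_frame().round(1).iloc[:4, :4])
print("\nEach entry is the perceptual distance between two petal-colour "
      "modalities; 100 marks the most dissimilar pair in the table.")
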