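"""Project a distance matrix and judge how many dimensions to keep.

Embeds a synthetic planted-cluster distance matrix with PCoA and metric
MDS, prints the eigenvalue scree and the stress-1 curve, and applies the
conventional stress1 < 0.2 rule for choosing the dimensionality.
"""

from phenoclust import (
    SyntheticSpec,
    generate_dataset,
    metric_mds,
    modality_matrices,
    pcoa,
    resolve_undefined,
    select_dimensions,
    semantic_distance_matrix,
    stress_by_dimension,
)

spec = SyntheticSpec(n=120, seed=5)
dataset, _ = generate_dataset(spec)
idm = semantic_distance_matrix(dataset, modality_matrices(spec),
                               warn_undefined=False)
observed = resolve_undefined(idm, "mean_impute")

emb = pcoa(observed, k=4)
print("PCoA leading eigenvalues (drop-out point suggests the intrinsic "
      "dimensionality):")
print([round(float(v), 1) for v in emb.eigenvalues[:8]], "\n")

stress = stress_by_dimension(observed, range(1, 6), method="mmds", seed=5)
print("Metric MDS stress1 by dimensionality:")
print(stress.round(4), "\n")

k = select_dimensions(stress, rule="stress_threshold", threshold=0.2)
print(f"Smallest k with stress1 < 0.2: {k}")
print(f"mMDS at k={k}: stress1 = "
      f"{metric_mds(observed, k, seed=5).stress1:.4f} "
      "(below 0.2 is conventionally a good representation)")
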