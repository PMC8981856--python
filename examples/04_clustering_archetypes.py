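"""Cluster embedded individuals, pick k by silhouette, select archetypes.

Runs several clustering algorithms on a planted-structure embedding,
compares them against k-means through concordance matrices, and picks both
kinds of archetypes (nearest-to-centroid and seeded 5% samples).
"""

from sklearn.metrics import adjusted_rand_score

from phenoclust import (
    SyntheticSpec,
    cluster,
    concordance,
    generate_dataset,
    modality_matrices,
    multiple_archetypes,
    pcoa,
    resolve_undefined,
    semantic_distance_matrix,
    silhouette_profile,
    single_archetype,
)

spec = SyntheticSpec(n=150, seed=11)
dataset, truth = generate_dataset(spec)
idm = semantic_distance_matrix(dataset, modality_matrices(spec),
                               warn_undefined=False)
emb = pcoa(resolve_undefined(idm, "mean_impute"), k=4)

profile = silhouette_profile(emb.coordinates, "kmeans", range(2, 7), seed=0)
print("Mean silhouette by k (k-means):",
      {k: round(v, 3) for k, v in profile.items()})
best_k = max(profile, key=profile.get)
print(f"Silhouette favours k = {best_k} (3 clusters were planted)\n")

kmeans = cluster(emb.coordinates, "kmeans", best_k, seed=0, ids=emb.ids)
print(f"k-means recovery vs planted labels: "
      f"ARI = {adjusted_rand_score(truth, kmeans.labels):.3f}\n")

for algorithm in ("ward", "kmedoids", "spectral"):
    other = cluster(emb.coordinates, algorithm, best_k, seed=0, ids=emb.ids)
    table = concordance(kmeans, other)
    print(f"Concordance k-means vs {algorithm} "
          f"(rows = k-means clusters, columns = {algorithm}):")
    print(table.counts.to_string(), "\n")

singles = single_archetype(emb.coordinates, kmeans)
samples = multiple_archetypes(kmeans, fraction=0.05, seed=0)
print("Single archetypes (member nearest each centroid):",
      {c: ids[0] for c, ids in singles.members.items()})
print("Multiple archetypes (5% per cluster, min 1):",
      {c: len(ids) for c, ids in samples.members.items()},
      "individuals per cluster")
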