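# phenoclust

Ontology-backed semantic distances, clustering and archetype visualisation
for mixed, incomplete trait datasets.

## The problem

Phenotypic and passport tables — germplasm collections, trait surveys,
ecological inventories — typically mix qualitative and quantitative
variables and are riddled with missing values. Classical multivariate
analysis struggles on such data, and the usual dissimilarities for mixed
data (Gower and relatives) treat every pair of distinct categories as
equally different, ignoring that *pink* is closer to *red* than to
*yellow*, that Brittany is closer to Normandy than to China, and that
1840–1849 is closer to 1850–1859 than to 1700–1749. Displaying thousands of
individuals at once also produces cluttered, unreadable scatterplots.

`phenoclust` addresses both problems:

1. **A semantic distance for individuals.** Each qualitative variable gets a
   distance matrix between its modalities, built from what the modalities
   mean: expert-annotated ontologies (an OWL/CSV dialect carrying
   `has_distance` assertions between concepts), colour coordinates in
   CIE L\*a\*b\* (ΔE), geographic coordinates (great-circle km), or year
   intervals (midpoint distance). Every matrix is normalised onto [0, 100],
   and two individuals `A`, `B` are compared by the weighted mean

   ```
   D(A, B) = ( Σ_{i∈M} w(i) · d_AB(i) ) / Σ_{i∈M} w(i)
   ```

   where `M` is the set of variables observed in *both* records — missing
   values are ignored, never imputed — and the per-pair cardinality `|M|`
   is kept as a measure of how trustworthy each distance is. A bespoke
   missing-aware Gower variant (Dice on dummy-coded categories, range-scaled
   Manhattan on numbers) is provided for comparison.

2. **A decluttered view.** The distance matrix is embedded (PCoA, metric
   MDS/SMACOF, or Laplacian eigenmaps, with eigenvalue screes and Kruskal
   stress-1 diagnostics), clustered (Birch, Gaussian mixture, Ward,
   k-means, k-medoids, spectral; silhouette analysis for k; concordance
   matrices between partitions), and summarised by **archetypes** — real
   individuals that stand in for their cluster, either the member nearest
   the centroid or a seeded 5% sample. The scatterplot matrix shows the
   whole population below the diagonal (transparent dots, size encoding an
   individual's missing-value count) and only archetypes plus per-cluster
   density envelopes above it.

## A worked example

```python
from phenoclust import expert_distance_matrix, normalise
from phenoclust.fixtures import PRICKLES_ORDER, prickles_graph

m = normalise(expert_distance_matrix(prickles_graph("normal"),
                                     order=PRICKLES_ORDER))
print(m.to_frame().round(2))
```

```
             Low  Medium    High  Very high
Low         0.00   16.67   83.33     100.00
Medium     16.67    0.00   66.67      83.33
High       83.33   66.67    0.00      16.67
Very high 100.00   83.33   16.67       0.00
```

The expert judged *Low* and *Medium* (and *High* and *Very high*) to be one
step apart within their subgroup, but put a large gap between the
subgroups; normalisation maps the largest expert distance to 100.

Downstream, on a generated 150-individual dataset with three planted
groups and missing values (`examples/04_clustering_archetypes.py`):

```
Mean silhouette by k (k-means): {2: 0.457, 3: 0.493, 4: 0.444, 5: 0.328, 6: 0.276}
Silhouette favours k = 3 (3 clusters were planted)
k-means recovery vs planted labels: ARI = 0.966
```

The silhouette profile peaks at the planted cluster count and k-means on
the PCoA coordinates of the semantic distance matrix recovers the planted
labels almost perfectly despite the missing data.

Each script in `examples/` demonstrates one capability end to end:
modality matrices (01), individual distances (02), embedding diagnostics
(03), clustering and archetypes (04), and the full config-driven pipeline
(05). The pipeline is also exposed as a CLI:

```bash
phenoclust run --config demo_config.yaml        # whole pipeline
phenoclust distances --config demo_config.yaml  # one stage at a time
```

Stage subcommands composed manually write artifacts byte-identical to a
single `run` with the same config and seed.

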