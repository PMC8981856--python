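# Demo pipeline configuration for the bundled 12-individual trait table.
dataset: traits_demo_synthetic.csv
variables:
  - name: prickles
    kind: qualitative
    source: ontology_file
    path: prickles.owl
    weight: 1
  - name: petal_colour
    kind: qualitative
    source: colour_table
    path: colours_synthetic.csv
    weight: 1
  - name: origin
    kind: qualitative
    source: geo_table
    path: regions_synthetic.csv
    weight: 1
  - name: breeding_period
    kind: qualitative
    source: period_table
    path: periods_synthetic.csv
    weight: 1
  - name: flowers_per_volume
    kind: quantitative
    source: numeric
    weight: 1
distance: both
reduction:
  method: pcoa
  n_dims: 3
  undefined_policy: mean_impute
clustering:
  algorithms: [kmeans, ward]
  k: [3]
  silhouette_k_range: [2, 3, 4]
archetypes:
  mode: single
seed: 7
output_dir: out
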