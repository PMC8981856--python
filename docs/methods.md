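# Methods

## The semantic distance

Each individual is a vector of variable values; variables are qualitative
(categorical modalities) or quantitative (finite reals), with explicit
missing values. The distance between individuals `A` and `B` is

    D(A, B) = ( Σ_{i∈M} w(i) · d_AB(i) ) / Σ_{i∈M} w(i)

where `M` is the set of variables observed in both records, `w(i) ≥ 0` is a
per-variable weight (default 1, i.e. an unweighted mean), and `d_AB(i)` is
the per-variable distance. The defining assumption is that missingness is
handled by *restriction*, not imputation: a variable missing in either
record simply drops out of `M`. When `M` is empty the pair's distance is
UNDEFINED — carried as a value (NaN) with cardinality 0, never silently
coerced. The per-pair cardinality `|M|` is retained throughout because a
distance computed from more variables is more trustworthy; the
visualisation encodes each individual's missing-value count as dot size for
the same reason.

### Per-variable distances

Qualitative variables draw `d_AB(i)` from a modality distance matrix built
from the variable's source:

* **Expert ontology** (`ontology_file`) — a small concept graph whose leaf
  pairs carry hand-tailored numeric distances. On disk this is either an
  OWL (RDF/XML) file — concepts as `owl:Class`, hierarchy as
  `rdfs:subClassOf`, distances as `has_distance` object-property assertions
  annotated (via `owl:Axiom`) with a real `distance` property, with a
  reified `ConceptDistance`-individual form also accepted on read — or a
  CSV edge list `concept_a,concept_b,distance` (the literal `is_a` in the
  distance column marks a hierarchy edge, an empty `concept_b` declares a
  bare concept). Distances may be stored one-directionally; only
  conflicting duplicates are errors. An optional fallback can fill a
  missing leaf pair by summing annotated edges along the unique tree path,
  but it is off by default: hand-tailored leaf-pair values are the
  reference.
* **Colour** (`colour_table`) — modalities map to CIE L\*a\*b\* coordinates;
  the distance is ΔE. The default is the Euclidean (CIE76-form) ΔE; the
  CIEDE2000 revision is available as `method="ciede2000"` (via
  scikit-image) but is not the default because it is not a metric and the
  plain Euclidean form is the analytically testable ground truth.
* **Geography** (`geo_table`) — modalities map to latitude/longitude; the
  distance is the haversine great-circle distance on a sphere of radius
  6371 km. Composite regions are represented by the arithmetic mean of
  their sub-areas' coordinates (adequate away from the antimeridian;
  regions straddling ±180° are a documented limitation).
* **Time periods** (`period_table`) — modalities map to year intervals
  `[S, E]`; the distance is `floor(|mid₁ − mid₂|)` with
  `mid = S + (E − S)/2`, in whole years. Open-ended labels are resolved to
  explicit bounds *in the table* (the bundled table uses 1600 as the start
  of "<1700" and 2020 as the end of ">1920"); bounds are data, not code.

All lookups are offline CSV tables; the core never performs network access.

### Normalisation

Raw per-variable scales are incommensurable (expert scores vs ΔE vs km vs
years), so every modality matrix is rescaled by `x → 100·x / max(x)` before
entering `D`. Max-scaling is the simplest linear map onto [0, 100] given
that the diagonal pins the minimum at 0; it preserves entry ratios and
ordering, is idempotent, and leaves an all-zero matrix unchanged.
Quantitative variables have no modality matrix; their contribution is
`|a − b| · 100 / max observed pairwise |difference|`, computed dataset-wide
over non-missing pairs, which puts them on the same [0, 100] scale.

### The Gower variant

For comparison, a missing-aware Gower dissimilarity on [0, 1]: per
qualitative variable, one-hot dummies plus a missing indicator and the Dice
dissimilarity on the dummies (0 for matching modalities, 1 otherwise), with
pairs flagged by the missing indicator — including both-missing pairs —
masked as UNDEFINED; per quantitative variable, Manhattan `|a − b|` divided
by the variable's observed range (a flag restores raw Manhattan; the
range-normalised form is the default so one wide-ranged variable cannot
dominate). The final distance is the element-wise mean over defined
per-variable entries. On complete all-qualitative data this reduces to
simple matching, and if every modality matrix is binary {0, 100} with equal
weights, the semantic distance is exactly 100 × the Gower distance — the
sense in which Gower is "more binary".

## Embedding

UNDEFINED pairs must be resolved before embedding: the default policy is an
error listing the pairs; `mean_impute` substitutes the mean defined
off-diagonal distance and logs the count. Three reductions are provided:

* **PCoA** — eigendecomposition of `−½ J D∘D J`; coordinates are the top-k
  eigenvectors scaled by √eigenvalue. Negative eigenvalues (non-Euclidean
  input) are reported in the scree but excluded from coordinates; no
  Cailliez/Lingoes correction is applied. Requesting more axes than there
  are positive eigenvalues is an error.
* **Metric MDS** — SMACOF stress majorisation (best of `n_init = 4` random
  starts, `max_iter = 300`, `tol = 1e−6`, seeded); a fixed seed gives
  bit-identical coordinates.
* **Laplacian eigenmaps** — Gaussian affinity `W = exp(−D²/2σ²)` with
  σ = median off-diagonal distance by default (scale-adaptive,
  parameter-light), self-loops dropped, symmetric normalised Laplacian,
  first k non-trivial generalised eigenvectors; the ascending non-trivial
  spectrum is reported for the scree. A disconnected affinity graph is an
  error; an all-zero distance matrix yields the degenerate zero embedding.

Quality is Kruskal's stress-1,
`√( Σ_{j>i}(δ̂_ij − δ_ij)² / Σ_{j>i} δ_ij² )` with δ̂ the embedded Euclidean
distances; values below 0.2 are conventionally a good representation, and
`select_dimensions` returns the smallest k beating that threshold. Scree
elbows are deliberately left to the analyst (`report_only`): automating the
elbow would invent a criterion.

## Clustering, silhouettes, concordance

Six algorithms behind one signature: Birch, Gaussian mixture (full
covariances), Ward agglomerative, k-means (`n_init = 10`), k-medoids, and
spectral clustering (RBF affinity, γ = 1, k-means label assignment). All
are seeded and deterministic; k-medoids is a deterministic PAM
(greedy BUILD + best-improvement SWAP), so its seed argument is inert.
Labels are relabelled to 0..k−1 by first appearance; producing fewer than k
distinct clusters (degenerate input) is an error, and k = 1 short-circuits
to a single cluster for every algorithm.

Silhouettes are computed on reduced-space Euclidean distances — the space
the clustering actually consumed — with an opt-in precomputed-distance
route; singleton clusters get silhouette 0, the common convention.
Partitions are compared by concordance matrices (contingency counts, rows =
reference); a greedy column reordering is available purely as a display aid
— raw counts are the data.

## Archetypes and visualisation

Single mode picks, per cluster, the member nearest the cluster's mean
coordinate (ties broken by dataset order, for determinism). Multiple mode
draws a uniform seeded sample without replacement of `⌈fraction·size⌉`
members (default fraction 0.05) with a floor of one so no cluster is ever
unrepresented. The scatterplot matrix uses the lower triangle for the full
population (cluster colours, transparency, dot size strictly increasing in
the missing-value count — any strictly monotone map satisfies the intent;
the default is `12 + 8·n_missing` points²) and the upper triangle for
archetypes plus per-cluster 2-D KDE contours (Scott's-rule bandwidth;
clusters with fewer than three points or singular covariance skip the KDE).
The default 8-colour palette is legible under most colour-vision
deficiencies and is a config parameter.

## Pipeline and reproducibility

One YAML config drives a run; a single seed deterministically derives fixed
per-stage sub-seeds, so re-running a config reproduces every numeric
artifact bit-identically, and stage subcommands composed manually equal one
full run (each stage reads its inputs back from the previous stage's
artifacts). Every stage logs start/end lines with its parameters and seed
to an append-only run log; artifacts are plain files (CSV + one XLSX
workbook for the matrices, PNG + SVG for figures).

## Synthetic data: what it does and does not emulate

The generator plants clusters in a mixed table shaped like a passport +
trait survey: 300 individuals in 3 equally likely clusters, 9 qualitative
variables with 4 ordinal modalities (rank distance |i − j| in the backing
ontology) plus 2 quantitative variables — 11 variables, the width of the
motivating use case — with 30% MCAR missingness per variable by default.
Cluster c concentrates 85% of its mass on modality (c + v) mod 4 of
variable v, and quantitative cluster means sit 3 SD apart; these sharpness
values are the package's reading of "distinct modality profiles", chosen
once as the reference study conditions. Under them the full semantic
pipeline recovers the planted labels with ARI > 0.9.

What passing these tests does **not** show about real data: missingness in
real trait tables is structural/observational rather than MCAR; real
modality distance matrices are not uniform rank distances; real clusters
are neither equally sized nor equally separated on every variable; and no
attempt is made to simulate breeding history. The synthetic suite validates
the machinery (the |M| bookkeeping, normalisation, recovery power), not
domain conclusions.

## Numerical choices and degenerate inputs

* Missing tokens in raw tables: empty cell or literal `NA` (case-sensitive);
  anything else in a qualitative column must be a declared modality.
  Duplicate individual ids are an error.
* Modality matrices must be symmetric, zero-diagonal and non-negative;
  positive-eigenvalue tests in PCoA use a relative tolerance of 1e−10.
* All-zero modality matrices normalise to themselves; zero quantitative
  range contributes distance 0.
* Expert-distance conflicts are exact-value comparisons: the same pair may
  be stored twice only with the identical value.
* Problem sizes in tests and examples (tens to a few hundred individuals)
  are chosen to exercise every code path at desk scale; all algorithms are
  O(n²)–O(n³) in the individual count and comfortably handle thousands.

## Known limitations

* Arithmetic longitude means misbehave for composite regions straddling
  ±180°.
* CIEDE2000 violates the triangle inequality; downstream methods assume
  only symmetry and non-negativity, but metric-dependent interpretations
  (e.g. PCoA eigenvalue signs) are affected.
* Mean imputation of UNDEFINED pairs biases those pairs toward the global
  average; with heavy structured missingness a different policy may be
  warranted.
* No non-metric MDS, no imputation of trait values, no interactive
  graphics, and no automatic "best algorithm" choice — comparisons are
  reported, the analyst decides.
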