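# Methods

## Input model

The package consumes gene-catalog mapper output: a genes × samples matrix
of mapped-read counts, three gene-level annotation tables (length in bp,
species taxon, vaginal orthologous gene [VOG] identifier) and a species →
expected protein-coding gene count table. The expected gene count is a
required input rather than a remote taxonomy-database lookup so that runs
are hermetic; any genome-size source can be used to populate it. All
tables are plain TSV, gzip accepted transparently.

## Presence calling

Fold coverage of gene *g* in sample *s* is
`counts[g,s] × read_length / length_bp[g]` with `read_length` a parameter
(default 150 bp, the common short-read length). Presence uses a fixed
coverage threshold (default 0.5); a VOG is present when at least one
member gene is present. All threshold comparisons in the package — the
100,000 mapped-read sample filter, the presence threshold, the 80% genome
fraction, the ≥10-eligible-sample candidacy rule, the 30-read transcript
filter, the 90% zero-fraction species filter, the half-cluster prevalence
rule — are **inclusive** (`>=`), a single convention chosen so boundary
cases are reproducible. The genome-coverage eligibility rule has two
defensible parameterizations in circulation (fraction of expected genes
vs fraction of samples at a genome-size fraction); the default here is:
eligible when present genes / expected genes ≥ 0.8, candidate when
eligible in ≥ 10 samples, with both numbers exposed as parameters so the
other variant can be configured.

Eligibility states partition (species, sample) pairs: `eligible` (genome
sufficiently covered), `mgss0` (≥1 VOG present but below the bar; the
species is kept as the `species::mgSs_0` unit so partially observed taxa
stay represented), `absent` (no VOG present; such reads are excluded
before composition normalization).

## Subspecies clustering

Samples are clustered per species on binary VOG profiles using Jaccard
distance (two empty profiles are at distance 0) and Ward linkage. Ward on
a non-Euclidean distance is the Lance–Williams update applied directly to
the distance matrix — standard practice in community ecology tooling, and
documented here as an approximation rather than a Euclidean embedding.

### Hybrid dynamic tree cut

The dendrogram is cut with an in-package implementation of hybrid dynamic
tree cutting (`vagitype.treecut`). A branch attaching to the rest of the
tree at height *h* is *distinct* when

* its size is ≥ `min_cluster_size`, and
* `(h − core_scatter) / h_max ≥ min_gap(deep_split)`,

where `core_scatter` is the mean of the branch's lowest merge heights (its
first `min_cluster_size` leaves to agglomerate), `h_max` the tree height,
and `min_gap` takes the values 0.27, 0.2025, 0.135, 0.0675, 0.0375 for
`deep_split` 0–4 (three quarters of one minus the conventional
core-scatter presets). The tree is split top-down while both sides stay
distinct; an undersized offshoot of a distinct branch is left unassigned
by the tree stage and reattached afterwards to the cluster at minimal
average distance (PAM-like stage), so every sample is labeled. Cluster
numbering is by decreasing size with ties broken by smallest leaf index.
The criterion compares a branch's attachment height with its internal
tightness rather than with its children's heights: with k > 2 balanced
clusters the top few merges occur at nearly equal heights and a
parent–child gap test cannot see them, while the attachment-vs-core test
can. At high `deep_split` the cut will report clusters in unstructured
data; that is intentional, because the randomized-table validation below
is the method's guard against spurious structure. The number of clusters
is non-decreasing in `deep_split`.

### Parameter sweep and validation

`min_cluster_size` ∈ {10..20} × `deep_split` ∈ {0..4} are searched
jointly, keeping the labeling with the highest average silhouette width on
the Jaccard distances (singleton clusters score 0; single-cluster
labelings score −∞ and are returned, with silhouette 0.0, only when the
whole grid collapses). Ties go to the lexicographically lowest grid point.
Ten randomized tables per species — exactly `round(0.10 × cells)` distinct
cells bit-flipped, uniformly without replacement — are re-swept with the
same grid (the stricter null, since the alternative of scoring them at the
observed parameters can only lower their silhouettes). If the observed
silhouette does not strictly exceed every randomized one, the observed
dendrogram is flat-cut at k−1, k−2, … until it does or k = 2. The floor is
2: a species that still fails at k = 2 is flagged `weak_structure` rather
than collapsed, so downstream stages keep a defined labeling while the
diagnostic records the failure. "Reduce by one" is operationalized as a
flat cut of the existing dendrogram because it is deterministic and
monotone; merging nearest clusters or re-running the dynamic cut at other
parameters would be equally consistent with the description but less
predictable.

Randomness: one master seed; each species' stream is seeded by a 32-bit
BLAKE2 hash of `"{seed}:{species}"`, so adding or removing a species never
perturbs the others, and every randomized-table sequence is reproducible.

## Community state types

Sample compositions are mapped-read proportions per unit, where a unit is
a species, one of its mgSs (for eligible samples of candidate species), or
`species::mgSs_0`. Read mass is the standard abundance proxy for
gene-catalog mapping and matches the high-abundance emphasis of the
downstream similarity measure. Between-sample dissimilarity is
Bray–Curtis on untransformed proportions (the ecology default; Euclidean
and Jaccard are selectable), clustered with Ward and cut at
`deep_split = 4` with `min_cluster_size` swept 10..20 by silhouette.
Centroids are per-mgCST means of unit relative abundances, renormalized.

## Classification

Per-species random forests (scikit-learn, 500 trees, √m features per
split, bootstrap) are trained on binary VOG features; the out-of-bag error
is recorded at fit time and a stratified 10-fold cross-validated
misclassification rate is available alongside. New samples are assigned to
the mgCST with the highest Yue–Clayton θ against the centroids; ties break
to the lowest index and are flagged; the runner-up and its θ are always
reported. θ is reported raw — no reliability cutoff is imposed, since any
threshold would be dataset-dependent; users can filter on the reported
value. Units unseen at training time cannot be scored by any centroid, so
they are dropped and the sample renormalized before θ is computed.

Concordance between hierarchical labels and centroid assignment uses
stratified 10-fold cross-validation: centroids rebuilt per training fold,
test samples assigned, confusion pooled. Misclassification error is the
mean per-fold error rate; kappa is computed on the pooled table with
linear weights on the integer mgCST indices (mgCST indices are nominal, so
the unweighted Cohen kappa and per-fold kappas are reported alongside for
transparency). Classes smaller than the fold count shrink the fold count
(with a warning) rather than failing.

## Metatranscriptome companion

Transcript counts pass a 30-read total filter, then TPM normalization
using catalog gene lengths (no effective-length correction — the catalog
length is the mapping target). Species activity is the per-species TPM
sum; species zero in ≥ 90% of samples, or absent from the matched
metagenome, are dropped; a top-N (default 70) selection and log2(x+1)
transform are options. Target-gene expression can be expressed relative to
the single-copy recA housekeeping ortholog (default VOG0190358); a sample
with zero recA expression yields a missing value, never a 0. Ortholog
presence comparisons between two sample groups report a VOG when its
prevalence is ≥ 50% in one group and its absence is strictly > 75% in the
other; VOG-cluster prevalence counts samples carrying ≥ half of a named
cluster's VOGs. Differential-expression inference itself is out of scope;
these functions prepare its inputs.

## Synthetic scenario

The generator plants ground truth for every stage. Each species has core
VOGs shared by all subspecies plus accessory VOGs, of which a fraction
1 − d is shared and the rest split into k equal private blocks
(divergence d = 0.8 by default, so subspecies differ in 40–80% of their
accessory repertoire depending on k — comfortably separated, as the
scenario is meant to represent recoverable structure). Gene lengths are
uniform on 500–1500 bp (bacterial CDS scale; the default is narrower than
the full 200–3000 bp range to keep per-gene coverage even at modest read
depth, and is overridable). Communities come from four templates — one
Lactobacillus-like-dominated, two polymicrobial, one intermediate — with
30 samples each; compositions are Dirichlet draws (concentration 100 ×
template proportions) and 400,000 reads per sample are allocated
multinomially with weight ∝ species proportion × gene length / species
genome length, so a species' expected read share equals its drawn
proportion and a present gene's expected coverage is well above the
presence threshold at default depth. A per-(sample, species, VOG)
membership flip rate of 0.01 adds presence noise.

What the scenario does **not** emulate: uneven within-genome coverage,
read-mapping ambiguity between paralogs, shared orthologs between species,
strain mixtures within one sample (each sample carries exactly one
subspecies per species), compositional zero-inflation, and batch effects.
Passing the planted-recovery tests therefore shows the pipeline is correct
and self-consistent at realistic sizes, not that real vaginal metagenomes
will yield equally clean silhouettes or error rates.

## Problem sizes and numerical choices

The shipped scenario (6 species × ~140 VOGs × 2 genes each, 120 samples)
runs the full pipeline — including 10 randomized-table sweeps per species —
in well under a minute on one CPU; it is the size at which every
acceptance property is measured. Silhouettes come from scikit-learn on
precomputed distances; Ward from SciPy; exact flat cuts via
`fcluster(..., criterion="maxclust")`. Degenerate inputs are defined
explicitly: empty-vs-empty Jaccard is 0, a zero-height tree is one
cluster, a k = 1 labeling has silhouette 0.0 by convention, Shannon
diversity of an empty unit subset is an error, and model files from a
different schema version are rejected whole rather than partially loaded.
Model serialization is a JSON container plus TSV sidecars written with
`%.17g` and parsed with round-trip float precision, so reloaded matrices
are bitwise identical; trained forests are stored as (features, labels,
hyperparameters, seed) and retrained deterministically on load, keeping
model files text-only.

## Known limitations

* Ward-on-Jaccard is a Lance–Williams approximation, not a Euclidean
  Ward; dendrogram heights have no variance interpretation.
* The hybrid tree cut is this package's implementation of the published
  algorithm family, not a port; parameter-for-parameter agreement with
  other implementations is not guaranteed, only the documented behavior.
* The k-reduction floor of 2 means a truly structureless species is
  reported as two weak clusters with a `weak_structure` flag instead of
  one; consumers should honor the flag.
* mgCST indices are arbitrary (size-ordered); linear-weighted kappa on
  them penalizes index distance, which is why the unweighted kappa is
  reported alongside.
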