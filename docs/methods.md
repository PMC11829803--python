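# Methods

## Pipeline overview

`ccitraj` reconstructs differentiation trajectories from a cells × genes
expression matrix on a normalised (FPKM/CPM-like) scale in six stages:
preprocessing, ligand–receptor communication scoring, fuzzy kNN graph
construction with communication-augmented edge weights, Louvain partitioning
with partition-graph abstraction, entropy-based lineage orientation with a
maximum spanning arborescence, and diffusion pseudotime. Each stage is an
estimator or function usable on its own; `CCITrajectory` chains them.

## Preprocessing

Cells whose expressed-gene count (genes > 1) falls below 0.75 × the 10th
percentile of the per-cell counts are removed, then genes expressed in at
most 5 % of cells. Percentiles interpolate linearly between order
statistics. Cells are optionally scaled to the median library size
(`normalize=True` by default; the scaling method is a free choice — median
library size is the simplest scheme that leaves the expression scale
interpretable against the validity threshold). Values are transformed as
log2(x + 1). Both filters preserve cell/gene order; the gene filter is
exactly idempotent, the cell filter practically so (its cutoff is
re-estimated from survivors).

## Communication scoring

Groups for communication analysis come from user labels when available,
otherwise from k-means with the cluster number chosen by the Gap statistic
(Tibshirani's one-standard-error rule, 20 uniform reference draws over the
bounding box of the 50-PC scores, W_k = k-means inertia). Communication for
pair k = (L, R) from group i to group j is a saturating mass-action score
with arithmetic group means, C = L̄R̄/(k_h + L̄R̄), k_h = 0.5 — interaction
strength proportional to reactant abundance with receptor saturation. Genes
absent from the matrix score zero. The half-saturation constant and the
mean are configurable; results depend on them only through the relative
ordering of edge boosts.

The per-cell matrix P sums pair scores over pairs validly expressed
(strictly > 1, the same threshold on the log scale as the preprocessing
filters) in the sender (ligand) and the receiver (receptor); the diagonal
is zero. Because graph edges are undirected, P is symmetrised by the mean
of the two directions and min–max scaled by its global maximum, so the CCI
weight K (grid 0–10) has a comparable meaning across datasets. Scaling can
be disabled.

## Cell graph

Distances are Euclidean in the space of the top 50 principal components
(exact full-matrix kNN; datasets at the intended scale have at most a few
thousand cells). Per-cell memberships over the k = 10 nearest neighbours
are p_{i|j} = exp(−max(0, d − ρ_i)/σ_i) with ρ_i the distance to the
nearest neighbour — which therefore always has membership exactly 1,
keeping every cell locally attached — and σ_i set by binary search (64
iterations, bracket doubling) so the membership sum equals log2(k), the
standard smooth-kNN calibration (2^Σ = k). When the sum cannot reach the
target (all neighbours equidistant) the search saturates and the best σ is
kept with a warning. Directed memberships combine by probabilistic union
p_ij = p_{i|j} + p_{j|i} − p_{i|j}p_{j|i}, and the CCI term is added as
p̂ = p + K·S **on the existing edge support only** — communication
reinforces expression-based neighbourhoods rather than creating edges
between arbitrary distant cells (a flagged alternative would densify the
graph; it is off because it can bridge unrelated lineages).

## Partition abstraction

Louvain community detection (networkx implementation, resolution-scaled
modularity, seeded for determinism; communities relabelled by smallest
member so labels are stable). Partition connectivity is
θ_ij = e_ij/ê_ij clipped to [0, 1], where e_ij counts inter-partition edges
on the binary support of p̂ and ê_ij = E·n_i n_j/C(n, 2) is the count
expected under uniform random edge placement. Counting binary edges (not
weights) matches the abstraction's interpretation as a connectivity test;
a weighted variant is available behind a flag. The default resolution is
1.0; like any graph-abstraction method the right resolution depends on
dataset size and structure — too low merges branches, too high produces
small partitions whose entropy summaries are noisy (see Limitations).

## Entropy and lineage

Cell entropy is the Shannon entropy (natural log) of the normalised
functional-group activation distribution: with a gene→group annotation,
group activation is the fraction of its genes expressed above the
threshold; without one, every gene is its own group and the entropy
reduces to ln(expressed-gene count). This deterministic activation entropy
replaces ontology-bootstrap entropy schemes: the pipeline only needs a
potency *ordering*, and the activation entropy is reproducible without
external annotation downloads. It is invariant to gene order and to joint
rescaling of expression and threshold.

A partition's stable-state entropy is the mean over its core — the
⌈0.25·n⌉ cells of lowest entropy (ties broken by cell index); the core
screens out transition-state cells whose incomplete activation deflates
entropy. Undirected partition edges are directed from higher to lower
stable-state entropy (exact ties: lower id → higher id), and per weakly
connected component the maximum-weight spanning arborescence rooted at the
component's highest-entropy partition is extracted with a
Chu–Liu/Edmonds implementation (best in-edge selection, cycle contraction,
recursive expansion). On an entropy-oriented graph with strict ordering no
cycle can arise and the result equals the per-node best in-edge; the
general algorithm is kept because ties and orphan handling create general
digraphs. A partition unreachable from its component root (a local entropy
maximum) becomes the root of its own subtree, with a warning.

## Pseudotime

The root cell is the highest-entropy cell inside the highest-entropy
partition. From the symmetric weights W, the kernel is density-normalised
(Q = W/(d_i d_j)), row-normalised to a transition matrix, and
eigendecomposed through its symmetric conjugate. The accumulated operator
uses the top 10 non-stationary components ψ_s (unit-normalised, making
pseudotime invariant to uniform edge-weight scaling) weighted by
λ_s/(1 − λ_s); pseudotime is the Euclidean distance to the root's row.
Cells outside the root's connected component receive +∞ (serialised as
"inf"); the accuracy score treats ∞-vs-∞ pairs as ties. Eigenvalues within
1e−10 of 1 are treated as stationary.

## Accuracy score and weight sweep

PAS = (concordant − discordant)/comparable over unordered cell pairs with
distinct external ordinal labels; pairs tied in pseudotime score zero. The
score equals Kendall's τ-a restricted to label-distinct pairs, hence it is
invariant to monotone transforms of pseudotime and antisymmetric under
order reversal. The sign convention with the 1/D normalisation and the
subsequent division by the maximal score are equivalent to this direct
ratio. The CCI-weight sweep reuses the cached kNN skeleton and CCI matrix
and reruns partitioning → lineage → pseudotime → PAS per K; the default
grid is 0 to 10 inclusive in steps of 0.1 (101 points), ties going to the
smallest K. Groups, communication and the kNN skeleton are computed once:
K only reweights edges.

## Seeding

One user seed fans out to fixed per-stage offsets (group k-means, PCA
solver, Louvain scan order), so stages rerun in isolation reproduce their
in-pipeline results and two runs with the same configuration are
bit-identical.

## Synthetic lineages

The generator emulates an FPKM-scale snapshot of asynchronous
differentiation along a rooted segment tree (one trunk; b ≥ 2 terminal
branches split at t = 0.5), with cells uniform on t ∈ [0, 1]:

- **Potency pool** (65 % of genes): expressed early, switched off sharply
  at gene-specific uniform times, so the expressed-gene count — and the
  activation entropy — declines from t = 0 at a rate of roughly the pool
  size per unit time.
- **Markers** : trunk markers ramp up smoothly inside the trunk; each child
  marker ramps **linearly from exactly zero** at a staggered onset inside
  its segment, so expression is continuous across the branch point while
  the siblings diverge from commitment onwards. Each child-marker
  activation is paired with the fast (but continuous) repression of a
  still-active shared potency gene in that child — commitment activates
  the fate program and shuts down the alternative one — which keeps the
  expressed-gene count monotone through branch entry.
- **Ligand–receptor genes**: per trunk→child adjacency, ligands follow a
  stage bump around the branch point shared by all lineages (peaking in
  late-trunk cells) and receptors ramp on inside the child only; both are
  continuous at the boundary. Communication therefore links trunk-end
  senders to committed-child receivers — informative about lineage
  adjacency, which is what the CCI term is supposed to exploit.
- **Housekeeping genes** (6 %) keep library complexity bounded away from
  zero, and all expression carries multiplicative lognormal noise
  (sd 0.2 by default on the natural-log scale).

Amplitudes are lognormal around 20 (sd 0.3 in log), putting typical
expressed values far above the validity threshold of 1. The default study
scale is 600 cells × 200 genes × 2 branches; tests and the acceptance
script use it with 5 replicate seeds. The generator does **not** model UMI
counting noise, dropout, library-size variation beyond the lognormal term,
batch effects, or doublets — results on it validate the pipeline's logic,
not robustness to droplet-specific artefacts. The null generator emits an
i.i.d. lognormal matrix with uniform stage labels as a negative control.

External evaluation labels are quartiles of true time, mimicking ordinal
developmental-stage annotations. Planted-topology recovery maps each
partition to the set of segments with substantial presence (≥ 5 cells and
≥ 20 % of the partition — partitions straddling the branch point carry
several segments legitimately) and requires every tree edge to be
compatible with the segment tree and every planted adjacency to be
realised by an edge or inside a partition.

## Numerical choices and degenerate inputs

- Strict inequalities everywhere a threshold is compared (expression
  validity, gene prevalence), so values exactly at the threshold do not
  count.
- σ search bracket [1e−12, doubling from 1]; convergence |Σ − target| <
  1e−5; non-convergence keeps the best value with a warning.
- Empty matrices, all-filtered cells, empty groups, empty graphs, k < 2,
  all-equal external labels and negative weights raise `ValueError` with
  stage-specific messages.
- Cells with no expressed gene get entropy 0 with a warning.
- Min–max CCI scaling is skipped for an all-zero matrix.

## Known limitations

- Cyclic trajectories are out of scope: the arborescence step cannot
  represent cycles.
- Right after a branch point, sibling branches are still similar and
  stable-state entropy is locally flat; on some replicates this misdirects
  a branch-entry edge (an early sibling–sibling edge, or a branch-start
  partition orphaned as its own root). This is inherent to ordering
  partitions by an entropy summary and is visible in the recovery rate of
  the acceptance script varying with the seed.
- The Gap-statistic cluster number is computed on PCA scores; for very
  small datasets (< ~40 cells) the uniform reference is unreliable.
- Multi-subunit receptor complexes, cofactors and pathway-level
  aggregation of ligand–receptor scores are not modelled; the LR table is
  flat.
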