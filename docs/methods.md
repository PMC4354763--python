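# Methods

This note documents the models and procedures implemented in `wfclust`, the
choices made where a design was genuinely open, and what the synthetic data
do and do not show about real workflow collections.

## Workflow model

A workflow is a directed acyclic graph of *task instances* over a shared
task pool, plus typed workflow-level input/output ports. Instances, not
task types, are graph nodes, so a method appearing twice in one pipeline
(e.g. two tree-inference runs feeding one comparison step) is representable.
Ports carry multiplicity by repetition: a workflow consuming two trees lists
the `Tree` input port twice. Validation is structural (acyclicity, resolved
task references, non-negative execution times) and returns all violations
at once rather than stopping at the first.

The built-in five-workflow collection (`figure1_fixture`) is a set of
alignment → tree-inference → HGT-detection pipelines whose four encodings
are fully determined; the test suite freezes them as expected values. One
cell of the originally published pair-of-tasks matrix for this collection
("Probcons → PhyML" in W4) contradicts the occurrence encodings of the same
workflows (W4 contains neither task); the fixture uses the self-consistent
value (the pair occurs only in W3).

## Encodings

Each encoder produces a variables × workflows count matrix `W` and a
non-negative weight vector `y` (one weight per variable, no sum
constraint):

| Type | Variables | Entries | Weights |
|------|-----------|---------|---------|
| I | task-instance slots (`"Name (k)"` for repeats) | presence 0/1 | task execution time |
| II | task types | occurrence counts | keyword rule (1.0 match / 0.1 default) |
| III | directed task pairs + terminal singletons | edge / terminal counts | sum of member times / own time |
| IV | Type III variables + `INPUT_*`/`OUTPUT_*` ports | as III + port counts | keyword rule; ports always `match_weight` |

Open points resolved here:

* **Type III singleton variables** are the task types that are *terminal*
  (no outgoing edge to another task) in at least one workflow. This is the
  unique rule consistent with every singleton row of the published example
  (the HGT-detection step is terminal in four workflows; the two
  disconnected comparison tasks are terminal in the fifth).
* **Keyword matching** is a case-insensitive substring test over the task
  name and its annotations.
* **Variable order** is lexicographic by name, and repeated-instance slots
  are named `"Task (1)"`, `"Task (2)"`, so matrices are bit-reproducible.
* Only workflow-level (primary) ports are encoded; intermediate data types
  do not generate port variables.

## Distances

Weighted Euclidean `d_ij = sqrt(Σ_p y_p (w_ip − w_jp)²)` and weighted
cosine `d_ij = 1 − Σ y w_i w_j / (‖w_i‖_y ‖w_j‖_y)`. For non-negative data
the cosine distance lies in [0, 1]. Columns of zero weighted norm use a
total, symmetric convention (0 between two zero columns, 1 otherwise);
the weighted Euclidean distance equals the plain Euclidean distance after
scaling each variable by `sqrt(y_p)`, which the tests use as an oracle.

## Partitioning

Both algorithms heuristically minimize the within-cluster dispersion

    Σ_k [ Σ_{i,j ∈ k} d_ij² ] / n_k        (ordered pairs)

* **Weighted k-means** (Lloyd iterations): a random start is a random
  initial *partition* (uniform labels repaired to non-empty clusters), the
  centroid is the arithmetic mean of member columns, and reassignment uses
  the chosen weighted distance to the centroids — for the cosine metric the
  centroid is still the arithmetic mean and assignment applies the weighted
  cosine against it. Convergence is an unchanged assignment; `max_iter`
  defaults to 300 and is never reached on the collection sizes used here.
* **k-medoids** (Voronoi iteration, not PAM): random distinct initial
  medoids, assignment to the nearest medoid, medoid update to the member
  minimizing the within-cluster distance sum (ties → lowest index).
* **Empty-cluster repair**: the element farthest from its current center
  moves into the empty cluster (ties → lowest index), keeping K fixed.
* **Multi-start**: starts are drawn sequentially from one seeded generator,
  and the best run by the dispersion objective is kept, so the
  best-of-`s` objective is non-increasing in `s` for a fixed seed. On the
  five-workflow collection, best-of-1000-starts provably attains the global
  optimum (all set partitions of n = 5 are enumerable, which the tests
  exploit).

## Validity indices and K selection

CH, logSS and Silhouette are computed with metric-consistent squared
distances to the centers (centroids for k-means, medoids for k-medoids;
overall center = grand centroid resp. global medoid). The scan range is
K ∈ [2, n − 1]: K = 1 leaves CH and the Silhouette undefined and K = n
forces zero within-cluster variance. Numerical conventions:

* A scanned partition with SS_W = 0 (perfect separation) is treated as
  CH/logSS = +∞ during selection; ties break toward the smaller K. This
  matters for collections containing duplicated workflows.
* logSS uses the natural log (only differences matter for selection) and
  its chooser minimizes the *signed* consecutive difference
  logSS(K+1) − logSS(K), as published; an absolute-difference variant is
  available behind a flag.
* The Silhouette is macro-averaged over clusters, as published, with
  s(i) = 0 for singleton clusters; the per-point mean is available behind
  a flag. Both lie in [−1, 1].

## Stability (PS / PSG)

Over Q independent randomized runs — each run draws one random start per
candidate K, re-selects K with the validity index and records the resulting
partition — the pairwise support PS(w_i, w_j) is the co-clustering
frequency and the diagonal PS(w_i) the singleton frequency. The aggregate
scores are

    PSG(W)   = (2 Σ_{i<j} max(PS_ij, 1−PS_ij) + Σ_i max(PS_i, 1−PS_i)) / n²
    PSG(w_i) = (Σ_{j≠i} max(PS_ij, 1−PS_ij) + max(PS_i, 1−PS_i)) / n

with the doubling applied to the pairwise sum only: the normalization then
yields exactly the documented range [0.5, 1] (0.5 when every frequency is
1/2, 1 when every pair is decisive), which a doubled singleton sum would
violate. Property tests check the range over arbitrary run collections and
the consistency "always singleton ⇒ zero pairwise row".

A caution for interpreting PSG on small collections: when several pairwise
distances are nearly tied, single-start runs spread over the corresponding
local optima and the affected supports approach 1/2; PSG is then sensitive
to tiny distance differences (on the built-in collection, three cosine
distances within 0.11 of each other dominate the score).

## Hierarchical classification

UPGMA (size-weighted average linkage, merge height d/2, output ultrametric
to 1e-9) and canonical neighbor joining (rate-corrected Q criterion,
standard branch lengths, unrooted trifurcating output) are implemented over
`dendropy` tree containers; both break ties toward the lexicographically
smallest leaf pair. NJ recovers additive matrices and UPGMA ultrametric
matrices exactly, which the tests verify on randomly generated instances.
Negative NJ branch lengths (possible on non-additive input) are preserved
and can be detected with `has_negative_lengths`, keeping distance
reproduction exact.

The least-squares fit score Σ_{i<j} (δ_ij − d_ij)²/d_ij^p (p = 2 default,
unordered pairs; a factor of 2 does not affect ranking) scores *any* leaf-
labelled tree against a distance matrix, so trees produced by external
topology-search programs can be evaluated; topology search itself is out of
scope. Robinson–Foulds distances are computed on unrooted non-trivial
bipartitions via `dendropy`; reference trees place one multifurcating node
per class under the root with unit edge lengths (lengths are arbitrary —
only the topology enters RF comparisons).

## Synthetic collections

`simulate_workflows` emulates a curated multi-class repository: a task
pool split into `n_classes` disjoint sub-pools (defaults: 4 classes × 4
tasks ≈ the 17-task pool of the motivating dataset), round-robin class
assignment, task counts uniform on 1..8, chain-with-branching topologies
(every instance after the first is wired from a uniformly chosen earlier
instance — the pipeline shapes of the worked example), log-normal execution
times (μ = −0.7, σ = 0.6 on the log scale, matching the 0.1–1.2 time-unit
range of the built-in collection), and one annotation keyword per class.
The mixing probability ε draws a task slot from a uniformly chosen foreign
pool. Tasks within a workflow are distinct (sampled without replacement;
the drawn count is capped by the distinct tasks reachable under the sampled
pools), so at ε = 0 class supports are exactly disjoint and the classes are
perfectly recoverable — the tests verify Rand index 1.0 there and a
monotone decline of the mean Rand index as ε grows.

What the generator does **not** emulate: repeated task instances inside one
workflow, heterogeneous class sizes, correlated execution times, shared
tasks between classes at ε = 0, or the metadata noise of real repositories.
Passing recovery tests therefore demonstrate correctness of the pipeline
under clean class structure, not expected performance on real collections.

## Problem sizes

The shipped experiments use the five-workflow collection (where exhaustive
enumeration is available as an oracle), random 8 × 6 matrices for formula
oracles, 6–10-leaf trees, and synthetic collections of 40 workflows with
20 replicates per mixing level — sizes chosen so every check has an
independent oracle or a statistically stable outcome.

## Known limitations

* k-medoids is Voronoi iteration; PAM's swap phase (stronger but slower)
  is not implemented.
* The dispersion objective is optimized heuristically; global optimality
  is only guaranteed where enumeration is feasible (tiny n).
* Cosine-metric CH/logSS substitute squared cosine distances to the center
  for squared norms; this keeps the indices metric-consistent but is a
  convention, not a published formula.
* The CLI covers the standard pipelines; composing meta-analyses (e.g. NJ
  over an RF matrix of result trees) is done through the library API.
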