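# Methods

## Model and assumptions

The pipeline treats a protein–protein interaction network as static
wiring whose *usage* varies in time: an interaction is considered
realizable at time point *t* only if both partner genes are expressed
above a fixed threshold at *t*. This is deliberately coarse — it
ignores translation delay, protein half-life, localization and
post-translational control — but it needs nothing beyond an expression
matrix, and it suffices to separate temporally co-expressed complexes
from the background of the static network.

Two consequences of the construction are worth keeping in mind:

- Filtering is per time point with one global threshold, not per-gene
  normalization. Genes with uniformly high expression are present in
  every time-course network; genes never crossing the threshold are
  present in none.
- Nodes enter a time-course network only as endpoints of retained
  interactions, so the networks have no isolated nodes, and every
  time-course network is an edge subgraph of the static network. This
  makes the retained-gene and retained-edge counts monotone
  nonincreasing in the threshold, which the test suite asserts across a
  sweep.

The threshold uses a strict inequality (expression must be *higher
than* the cutoff), so boundary values are excluded. When the matrix is
probe-level, probes are collapsed to genes before filtering; `max` is
the default aggregation (a gene counts as expressed if any transcript
probing it is), `mean` is available.

## Markov Clustering

MCL is implemented from scratch over `scipy.sparse` matrices:

1. self-loops with loop weight = maximum incident edge weight (1.0 for
   unweighted graphs and for isolated nodes, which then become
   singleton clusters);
2. column-stochastic normalization;
3. expansion = matrix power *e* (default 2);
4. inflation = entrywise power *r* (default 2.0) followed by column
   renormalization;
5. pruning of entries below 1e-5 with renormalization, keeping memory
   proportional to the number of nonzeros — necessary at the scale of
   real PPI networks (tens of thousands of edges);
6. convergence when no entry changes by more than 1e-6 between
   iterations, with a hard cap of 100 iterations (a warning and
   `converged=False` past the cap).

The pruning scheme and convergence metric are not canonical fixtures of
the algorithm; both are exposed as parameters with the above defaults.
Cluster extraction reads the limit matrix as attractor systems: nodes
with positive diagonal flow are attractors, each attractor's row lists
the nodes flowing to it, and attractor systems sharing any node are
merged. The merge rule turns the (rare) overlapping output of MCL into
a partition, which is how the downstream counting treats modules. Node
ordering is fixed to lexicographic ID, making the whole procedure
deterministic. The test suite checks the implementation against an
independent dense-matrix reference (plain numpy, python-loop
extraction) on every connected graph with at most six nodes.

## Matching and enrichment

The Overlap Score OS = i²/(g·h) is symmetric in the two set sizes,
bounded in [0, 1], and monotone in the shared count. Matching at
threshold τ uses OS ≥ τ, except τ = 0 where every module matches every
complex by convention (a sweep therefore always starts at perfect
sensitivity). TP/FP are counted over predicted modules and FN over
benchmark complexes — an intentionally asymmetric convention: one
module can match several complexes and vice versa, and no one-to-one
assignment is attempted. Reported tables round half-up to two decimals;
full precision is kept internally (the harmonic mean is computed from
unrounded sensitivity/specificity).

Enrichment tests every GO term carried by at least one annotated module
member, after propagating annotations up the ontology (is_a/part_of).
The upper hypergeometric tail is summed in log space (`gammaln` +
`logsumexp`), which stays stable for populations of 10^4 proteins where
direct factorials overflow. Bonferroni correction is per module per
ontology over the terms actually tested. The default population N is
the set of annotated proteins among the nodes of the network being
analyzed (the standard background of term-finder tools); a
`population_mode="all"` switch uses the full node set instead. −log
averages are reported in base 10.

## Null model

The pseudorandom arm applies double-edge swaps — (a,b),(c,d) →
(a,d),(c,b), rejecting self-loops and duplicates — for 10 accepted
swaps per edge (a conventional mixing heuristic, exposed as a flag).
This conserves |V|, |E| and every node degree exactly; connectivity is
*not* preserved, only degrees. Rigid graphs with no valid swap (e.g. a
two-edge path) are returned unchanged with a warning.

## Module cleaning

Cleaning applies, in order: drop size-1 modules; drop exact duplicates
(keeping the earliest (time point, cluster index) occurrence); drop
modules strictly contained in a surviving module. Containment is
evaluated across all time points by default (matching a pooled
evaluation), with a per-time-point switch. The pass is idempotent.
Near-duplicate *merging* — modules sharing most but not all proteins —
is deliberately not performed; whether two slightly different modules
are "the same" is an open modelling question, and silently merging them
would distort the occurrence-frequency statistics.

## Synthetic data generator

The generator emulates the features the pipeline depends on and nothing
more:

- **Network**: 10 planted complexes of 4–10 proteins, each an
  Erdős–Rényi block at p_within = 0.9, over a 100-protein background;
  all remaining pairs (background and cross-complex) at p_background =
  0.01. Mean within-complex degree then far exceeds background degree,
  as in a curated complex over a high-throughput interaction map.
- **Expression**: 36 time points with a 12-point period (three
  cycles). Members of a complex follow baseline + amplitude · max(0,
  sin(2π(t − φ)/period)) plus Gaussian noise truncated at zero
  (expression levels are nonnegative); background genes get baseline +
  noise. Complexes take one of three canonical phases a third of a
  cycle apart, imitating expression programs peaking in different
  metabolic phases. Defaults baseline 0.3, amplitude 1.6, noise 0.1
  against an activity threshold of 0.7: peaks (1.9) clear the threshold
  the way strongly periodic transcripts clear a fixed cutoff, while
  background stays below it.
- **Co-activity guarantee**: whenever the noiseless peak exceeds the
  threshold, the generator verifies that every complex has at least one
  time point with all members simultaneously above threshold, resampling
  the noise of a failing complex up to 100 times and raising if it
  cannot (at the default noise level a failure is vanishingly rare).
  Configurations whose noiseless signal never reaches the threshold
  (e.g. zero amplitude below the cutoff) are intentionally inactive and
  are returned as-is.
- **Annotations**: one private term per planted complex annotating
  exactly its members, optional noise terms on random genes, a flat DAG
  under a single root that annotates every gene (so the root's
  enrichment P is exactly 1).

What the generator does **not** emulate: microarray present/absent
calls, periodicity significance testing, probe-level redundancy,
measurement-platform noise structure, or the heavy-tailed degree
distribution of real interactomes. Passing the recovery tests therefore
shows that the pipeline's machinery is correct and that its stages
compose as intended — not that any particular biological dataset will
yield modules of comparable quality.

## Problem sizes and determinism

The test suite and the demo run on the planted fixture above
(~160 proteins, ~280 interactions, 36 time points), where the full
three-arm pipeline completes in seconds; the implementation's sparse
code paths are the same ones that handle networks of thousands of
proteins. Every stochastic component (generator, rewiring) takes an
explicit seed and is deterministic given it; MCL and all readers are
deterministic by construction, so a pipeline run is reproducible
byte-for-byte from its manifest.

## Known limitations

- A single global expression threshold treats all genes on one scale;
  data needing per-gene normalization must be normalized upstream.
- Identifier namespaces are not reconciled: network, expression,
  benchmark and annotation inputs must share one naming scheme
  (e.g. systematic ORF names), with at most one probe→gene indirection.
- The hypergeometric model assumes annotation independence between
  module members; modules assembled from co-annotated paralogs will
  look more significant than they are.
- Bonferroni is the only multiple-testing correction offered; no FDR.
- MCL granularity is controlled only by the inflation parameter; no
  automatic selection is attempted (2.0 is the default operating
  point).
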