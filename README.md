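# tcpin — time-course protein interaction networks

`tcpin` reconstructs **time-course protein interaction networks
(TC-PINs)** by combining a static protein–protein interaction (PPI)
network with a time-series gene-expression matrix, detects functional
modules in them with **Markov Clustering (MCL)**, and quantifies how
much more biologically coherent those modules are than modules from the
static network or from a degree-preserving random network. It is aimed
at systems biologists studying the temporal assembly of protein
complexes (e.g. across the yeast metabolic cycle) who have an edge list,
an expression matrix and a benchmark complex catalogue in hand.

## Method

1. **Reconstruction.** For each time point *t*, the active gene set is
   S_t = { g : expression(g, t) > θ } for a fixed threshold θ (default
   0.7; probe-level rows are first collapsed to genes by max or mean).
   An interaction (p, q) of the static network G = (V, E) belongs to
   TC-PIN_t iff p ∈ S_t and q ∈ S_t. With T time points this yields T
   subnetworks of G.
2. **Clustering.** Each network is partitioned by MCL: self-loops are
   added with the maximum incident edge weight, the matrix is made
   column-stochastic, then *expansion* (matrix squaring) alternates
   with *inflation* (entrywise power r = 2.0 followed by column
   rescaling) until convergence; clusters are the attractor systems of
   the limit matrix.
3. **Postprocessing.** Candidate modules that are singletons, exact
   repeats, or strict subsets of other modules are removed; occurrence
   frequencies across the T per-time-point module sets are reported.
4. **Matching.** A predicted module of size *g* sharing *i* proteins
   with a benchmark complex of size *h* scores

       OS = i² / (g·h)

   At a threshold τ (default 0.2), TP = modules with OS ≥ τ against at
   least one complex, FN = complexes matched by no module, and
   Sn = TP/(TP+FN), Sp = TP/(TP+FP), f = 2·Sn·Sp/(Sn+Sp).
5. **Enrichment.** Per module and GO ontology (BP/MF/CC), the
   upper-tail hypergeometric P-value

       P = Σ_{k=m}^{min(c,M)} C(M,k)·C(N−M,c−k) / C(N,c)

   for observing m carriers of a term among the c annotated members,
   given M carriers in a population of N; Bonferroni-corrected over the
   terms tested, significant at corrected P ≤ 0.01.
6. **Null model.** A pseudorandom network with identical node degrees
   is produced by repeated double-edge swaps and pushed through the
   same pipeline.

## Worked example

Simulate a planted-complex dataset (10 complexes of 4–10 proteins wired
densely over a sparse 100-protein background, periodically expressed
over 36 time points) and run the full three-arm comparison:

```sh
tcpin simulate --out demo --seed 0
tcpin run --network demo/network.tsv --expr demo/expression.tsv \
    --benchmark demo/complexes.tsv --gaf demo/annotations.gaf \
    --obo demo/ontology.obo --out demo/run --seed 0
```

prints

```
tcpin: modules=10 Mp=10 Mk=10 f=1.0
static: modules=37 Mp=10 Mk=10 f=0.43
random: modules=42 Mp=0 Mk=0 f=0.0
```

The time-course arm recovers every planted complex exactly (all 10
modules match all 10 benchmark complexes at OS ≥ 0.2, so sensitivity,
specificity and f-measure are all 1.0): at any given time point only the
genes of the co-expressed complexes are active, so background proteins
drop out of the networks before clustering. Clustering the static
network still finds all 10 complexes but buried among 27 spurious
modules (f = 0.43), and the degree-preserving random network yields
nothing (f = 0). The same ordering shows in GO enrichment
(`demo/run/report.json`): 100% of time-course modules of size ≥ 3 are
significantly enriched for their planted term, versus 45% (static) and
0% (random).

Individual stages are available as `tcpin build | cluster | postprocess
| randomize | evaluate | enrich`, and `tcpin sweep --thresholds
0.3,0.7,1.6 ...` repeats the run over a grid of expression thresholds.

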