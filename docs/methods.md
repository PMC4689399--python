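# Methods

## Problem setting

Given an undirected protein–protein interaction network and a list of known
drug targets, the package scores every protein's *network druggability*: how
closely its position in the interactome resembles the positions occupied by
existing targets, using network information only (no sequence, structure,
family or functional annotation).  Known targets are a positive set; all
other proteins are unlabeled background — never negatives, since an
undrugged protein may simply not have been drugged yet.  This is a
positive-unlabeled (PU) ranking problem on graph nodes.

## Graph model

The interactome is a simple, unweighted, undirected graph.  Input records
are cleaned in a fixed order — ambiguous complex-expansion records
(spoke/matrix expansions of n-ary complexes), self interactions,
duplicate/reciprocal pairs — and then reduced to the single largest
connected component, so that every descriptor below is defined for every
node.  Multiplicity of experimental evidence is deliberately discarded:
interactions are binary.  "Small subnetworks" are taken to mean every
component other than the largest; component ties are broken toward the
component holding the lexicographically smallest identifier so the
construction is deterministic.  Self-loops, if present in the input, are
removed (they carry no information for any descriptor used here).

## Node descriptors (142 default columns)

**Topology block (33 columns, `topo.*`).**  The classical
centrality/cohesion suite computed with igraph: degree, normalized
closeness ((n−1)/Σd), raw betweenness, eccentricity, PageRank (damping
0.85), HITS hub/authority and eigenvector centralities (scaled to max 1),
local clustering (0 for degree < 2), k-coreness; distance summaries
(harmonic closeness, mean/median distance, 2- and 3-step neighbourhood
sizes); neighbour-degree summaries; triangle and 4-cycle participation;
degree/load centralities; communicability (subgraph centrality on the
spectrally rescaled adjacency); local efficiency; a within-coreness-shell
degree z-score; incident-bridge count; plus three authored descriptors:

- *Burt's constraint* `c(i) = Σ_j (p_ij + Σ_q p_iq p_qj)²` with
  `p_xy = 1/k_x` on the unweighted graph — how redundant a node's
  neighbourhood is (structural holes).
- *Pairwise disconnectivity index* `Dis(v) = (N0 − N−v)/N0`, where `N0 =
  n(n−1)` is the number of ordered connected pairs and `N−v` the pairs
  still connected after deleting `v`.  Every non-articulation node scores
  exactly `2/n` (it loses only its own pairs); articulation points score
  more.  The metric registry is explicit and configurable; the default list
  above is this package's choice of a practical ~31-metric panel, since no
  single canonical registry exists.
- *Dice-MDS coordinates V1/V2*: Dice neighbour-sharing similarity
  `s(u,v) = 2|N(u)∩N(v)|/(|N(u)|+|N(v)|)` (self-similarity fixed at 1,
  neighbour sets exclude the node itself) converted to distance `1 − s` and
  embedded by classical (Torgerson) MDS; the two leading coordinates enter
  the feature set.  Classical MDS is defined only up to reflection, so each
  axis is sign-fixed: the lexicographically smallest node among those of
  maximal |coordinate| is made positive.  V1/V2 are counted in addition to
  the 31 scalar metrics.

**Community block (6 columns, `comm.*`).**  Two igraph community
algorithms: walktrap with walk length 4 (flat cut at maximal
Newman–Girvan modularity; deterministic) and spin glass with 50 spins as
the maximum community count (gamma 1, annealing from temperature 1 to 0.01
with cooling factor 0.99; stochastic, so the seed is always recorded and is
derived from the master seed).  Per algorithm and node: community id,
community size, and **vertex modularity** — the fraction of the node's
neighbours in its own community.  VM near 1 marks an intra-community
protein; low VM marks an inter-community communicator.  Both algorithms'
blocks are kept: no single partition is privileged, and the model is free
to use either.

**Graphlet block (103 columns, `orbit.*`, `graphlet.*`).**  For every node,
the graphlet degree vector: its participation count in each of the 73
automorphism orbits of the 30 connected 2–5-node graphlets, under induced-
subgraph semantics, plus 30 per-graphlet totals.  Orbit 0 is the degree,
orbit 3 the triangle count, orbits 65–72 the densest five-node subgraphs.
The atlas (graphlet numbering, orbit numbering, multiplicities) is
generated from automorphism groups and dumped to
`src/netdrugg/data/graphlet_atlas.txt`, which is the single source of truth
for the numbering: graphlets are ordered by node count and increasing
density following the standard scheme (edge, 3-path, triangle, …, K5);
orbits within a graphlet are ordered by an ascending neighbour-degree
refinement key (pendant positions before hubs), which reproduces the
standard anchors (path end 1 < middle 2, claw leaf 6 < centre 7, bowtie
wing 43 < hub 44, K5 = 72).

The efficient counter enumerates every connected induced vertex set of
size 2–5 exactly once (an ESU traversal compiled with numba) and
classifies it in O(1) through a precomputed table mapping each labelled
adjacency bit-mask on ≤5 vertices to the orbit of each position.  A
brute-force oracle (direct enumeration of all 2–5-subsets with explicit
isomorphism search against the atlas) is part of the public API and the
test suite asserts exact integer agreement between the two on random
graphs.  Counts are stored as 64-bit integers; hub nodes in dense regions
reach very large counts.

## PU modelling

**Degree strata.**  Most descriptors correlate strongly with degree, so
models are trained within first-neighbour strata: low (≤5), medium (6–30),
high (≥31) and "all".  A stratum with fewer than 20 positives is flagged
and refused for fitting.

**Ensemble.**  Three regressors on the 0/1 (positive/unlabeled) target:
a random forest (500 trees, √p features per split), a gradient-boosted
machine (500 stages, depth 3, learning rate 0.05) and a binomial-link GLM
(L2-penalised logistic regression, ridge 1e-3 — the penalty stabilises the
strongly collinear network features).  Raw outputs live on different
scales, so each model's outputs are min–max scaled to [0, 1] over the
scored batch before averaging; the ensemble score is therefore invariant
to monotone affine rescaling of any single member.  Constant feature
columns are dropped with a warning.  All hyperparameters are configurable.

**Evaluation.**  Because every descriptor depends on the whole graph, a
true holdout is impossible.  Two complementary devices are used:
(1) stratified k-fold cross-validation (k = 10, or 5 in the high stratum,
whose minority class is small) scored by the rank (Mann–Whitney) AUC of
held-out positives versus held-out background, reported ×100; and (2) a
structure-preserving random-label null — the same graph and features, the
same number of positives reassigned uniformly at random, the same CV —
which should sit near AUC 50 and exposes any optimistic bias of the
in-network evaluation.

**Scores.**  Every protein's final score is a rank percentile of the
averaged ensemble output: percentile = 100·(midrank − 1)/N, i.e. the
percent of proteins ranked strictly below it, with ties averaged (a score
of 78 means 78% of proteins rank lower).

## Enrichment analyses

Target set versus background: per-orbit log2 of (mean+1) ratios with
two-sided Mann–Whitney p-values (the +1 pseudocount bounds the log-fold on
sparse orbits); per-community fold enrichment (target fraction in the
community over the global target fraction) with hypergeometric p-values,
a coverage curve (cumulative fraction of targets over communities sorted
by target count), and communities of size ≤4 excluded from the ranked
report; articulation-point over-representation by one-sided Fisher's exact
test; per-feature distribution shifts by Mann–Whitney with box-plot
summaries.  Benjamini–Hochberg adjustment within each report; raw p-values
retained.  Fisher and Mann–Whitney are this package's choice of standard
nonparametric tests — the analyses they back do not prescribe a specific
test.  Radar-style *network profiles* standardize a configurable feature
panel against the background mean/sd; profile similarity is the Pearson
correlation of two z-vectors.

## Synthetic benchmark

The generator emulates the study conditions the pipeline is meant for: a
10-community stochastic-block interactome of 2000 nodes at background mean
degree ≈12 (intra-block edge probability 0.05 on 200-node blocks, inter
0.0014), with 100 planted positives.  Signatures:

- *cancer_like* (default): each positive's degree is raised to ≈3× the
  pre-planting background mean, ≥60% of planted edges cross community
  boundaries (driving vertex modularity below background), and 12
  neighbour pairs are closed into triangles around each positive (raising
  dense-orbit counts).  This mirrors the hub-like, inter-community,
  complex-graphlet profile that distinguishes cancer-drug targets.
- *noncancer_like*: 4 extra strictly intra-community edges and 4
  intra-community triangle closures per positive (vertex modularity above
  background, modest degree).
- *random*: a uniform draw; by construction carries no signal and is the
  negative control for the learnability checks.

A scale-free (preferential-attachment) background is available as an
alternative base graph.  Note that the stochastic-block background has an
essentially Poisson degree distribution at mean ~12, so it contains almost
no degree-1 periphery and hence (unlike a real interactome, where roughly
a tenth of proteins are cut vertices) practically no articulation points;
the articulation-enrichment machinery is exercised on constructed tables
in the test suite instead.  Everything is drawn from one seeded generator;
the same spec reproduces the graph, labels and truth manifest
bit-for-bit.  What the generator does *not* emulate: literature/study
bias (publication counts correlate with target status in real data),
assay-specific false negatives, and identifier-mapping noise.  Passing the
planted-signal checks therefore shows the pipeline recovers a topological
signature when one exists — not that real interactomes carry exactly this
signature.

## Validation configuration and problem sizes

The test suite and `scripts/acceptance.py` run the reference benchmark at
its full default size (n = 2000, 100 positives) once, with the ensemble at
a reduced validation size (100 trees / 100 boosting stages): on the
planted benchmarks the learnable signal saturates far below the 500/500
default, and the reduced ensemble leaves the CV AUC, top-quartile recovery
and null calibration unchanged.  Robustness across generator seeds is
checked by a ten-seed sweep at n = 600 with a 50-tree/50-stage ensemble.
Statistical calibration is verified at n = 500 with 200 label
randomizations; the Fisher check uses a 30%/50% trait/target split so the
exact test's discrete p-value lattice is fine enough to resolve uniformity
at the KS < 0.1 level (at sparse, interactome-realistic margins the exact
test is conservative — super-uniform — which a KS test against the uniform
necessarily flags).

## Numerical and design choices

- Vertex indexing is by sorted node identifier; all tabular outputs are
  written with a fixed float format — two runs with the same config and
  master seed are byte-identical, including the stochastic stages (each
  stage's seed is spawned from the master seed by hashing the stage name).
- MDS uses a dense symmetric eigensolver on the double-centred squared
  distance matrix; negative eigenvalues (the Dice distance need not be
  Euclidean) are truncated at zero, and a degenerate (all-equal) distance
  matrix yields all-zero coordinates with a warning.
- The percentile convention (strictly-lower with midranks) makes all-tied
  inputs score 49.5 at N = 100 rather than 0 or 100.
- Fold assignment retries (new shuffle seed, up to 10 attempts) if a fold
  receives no positive.
- The brute-force graphlet counter refuses graphs above 40 nodes; the
  efficient counter warns above 1e5 nodes.

## Known limitations

- The orbit numbering beyond the anchored positions follows this package's
  documented canonical ordering; other graphlet tools may permute a few
  same-size, same-density graphlet ids (the atlas dump makes any such
  discrepancy visible and testable).
- Spin-glass community detection does not scale to very large graphs;
  for interactome-scale networks the walktrap block dominates runtime far
  less than the spin-glass one.
- PU learning here makes no attempt at class-prior estimation; scores are
  ranks, not calibrated probabilities.
- Evaluation is in-network by necessity; the random-label null quantifies,
  but cannot fully remove, the optimism of evaluating on nodes whose
  features were computed on the same graph as the training nodes'.
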