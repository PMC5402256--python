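# Methods

## The model

A multiplex lexical network (MLN) is an edge-coloured multiplex: one
vocabulary of N words shared by L undirected simple-graph layers, with no
inter-layer edges. The canonical four layers encode free association
(symmetrized cue→target records), feature sharing (words linked when their
semantic feature sets intersect), co-occurrence in child-directed speech
(pairs co-occurring strictly more than 45 times; the strict `>` mirrors the
density-matching convention of the source counts), and phonological
similarity (IPA phoneme-token transcriptions at Levenshtein distance exactly
one). Edge weights and directions in the source records are read and
discarded; all analyses are functions of the unweighted edge sets. The
working vocabulary is the intersection of a CDI word list with the words
holding at least one connection on any layer, iterated to a fixed point
because removals can isolate further words.

Ingest conventions that the sources leave open: word ids are case-folded and
multiword CDI items are joined with underscores; with several transcriptions
per word the first listed is used; association records link a pair if any
record in either direction exists. The bundled co-occurrence counter (for
users starting from raw tokenized utterances) counts adjacent bigrams within
an utterance — a stated convention, since counts are properly an input
format.

## Topology against nulls

Per-layer statistics: mean degree over all N words; mean local clustering
with degree-<2 nodes contributing 0 (one convention has to be fixed for
comparability; this one keeps the average over the full vocabulary);
degree assortativity as the Pearson correlation of endpoint degrees
(reported as missing when undefined, e.g. for rigid or empty layers); share
of nodes in the largest component; and mean shortest path within that
component. Null ensembles are degree-preserving double-edge-swap
randomizations (default 100 samples, 10 swaps per edge) that keep the graph
simple; rigid degree sequences (stars) simply yield fewer effective swaps.
Cross-layer degree similarity uses Kendall tau-b over the shared vocabulary.
Edge overlap (multiplexity) between layers i and j is |E_i ∩ E_j| /
min(|E_i|, |E_j|) — the min-normalization keeps self-overlap at 1 and is
robust to the ~7× density gap between the phonological and semantic layers;
Jaccard is available behind a flag. Null overlap statistics pair the s-th
sample of each layer's independent randomization.

## Structural reducibility

Each layer's density matrix is its combinatorial Laplacian divided by its
trace; merged groups sum adjacency matrices before normalizing. Von Neumann
entropy is computed from the Laplacian spectrum (base-2; the base cancels in
the quality ratio). Layers are compared by quantum Jensen–Shannon
divergence, clustered by Ward linkage on √JSD, and each dendrogram cut is
scored by the relative-entropy quality q = 1 − H̄/h(aggregate), where H̄
averages the group entropies of the cut. The multiplex is declared
*irreducible* when q is strictly maximal at the no-merge cut: merging
duplicate layers changes no entropy, so ties must count as reducible for the
verdict to mean "keeping every layer separate is strictly necessary".

## Word scores and orderings

Closeness is harmonic centrality normalized by N−1 — three of the four
layers are heavily fragmented, and harmonic centrality is well defined
across components (classic within-component closeness is available for
sensitivity analysis). Betweenness is computed and normalized per connected
component. PageRank uses damping 0.85, tolerance 1e−10, uniform teleport;
isolated words receive teleport mass. Multiplex path metrics run on the
union graph, where an edge exists if present on any layer and layer switches
are free — the natural reading for an edge-coloured multiplex with no
inter-layer links; multiplex PageRank weights union edges by their layer
multiplicity, to which the supra-adjacency construction reduces when node
sets coincide and no coupling exists (documented approximation). With a
single layer, every multiplex metric equals its single-layer counterpart
exactly.

Normative acquisition orderings are sampled from CDI norms: a word becomes
eligible the first month its production fraction reaches 0.5 (≥, exposed as
a parameter) and stays eligible; each month, eligible unplaced words are
appended in an order drawn sequentially without replacement with probability
proportional to that month's production fraction (implemented by
exponential-race keys, which realizes exactly that law). Words never
reaching the threshold are appended after the final month by the same rule
on final-month production with a 1e−6 floor — the sampling must exhaust the
vocabulary and this is the least-structured completion. Inventory size at
month m is the number of words eligible by m.

Predicted orderings sort words by descending score. Tied blocks are handled
by the exact *expected* policy by default: the evaluator adds, for each tie
block straddling position t, the hypergeometric expectation of its
contribution to the overlap — equivalent in expectation to averaging over
all tie resolutions, which is combinatorially infeasible verbatim, and
property-tested against Monte Carlo resolutions.

## Gain statistics

For prediction τ and normative ensemble {τ_aoa}: O(τ, t) is the mean number
of words shared by the first t of τ and the first t of each τ_aoa. The
first t words of a uniformly random ordering form a uniform t-subset, so the
random overlap is Hypergeometric(N, t, t): mean t²/N, variance
t(t/N)(1−t/N)(N−t)/(N−1). Word gain g = O − t²/N, normalized gain G = g/t,
Z = g/σ. The analytic σ is the default (a Monte Carlo baseline mode exists
for cross-checks). Significance is one-sided (better-than-random is the
hypothesis): Gaussian p-values from Z once t ≥ 60 — where the random-overlap
distribution is effectively normal — and direct sampling below: the
fraction of random orderings whose ensemble-mean overlap reaches the
observed one (default 100,000 samples).

## Layer-influence optimization

Combined scores s_w = Σ_l α_l ŝ_l(w) with α on the simplex. Per-layer scores
are min-max normalized before combining (raw degree ≈ 9 and closeness ≈ 0.3
differ by orders of magnitude, making unnormalized weights meaningless);
rank and z-score normalizations are flags. Differential evolution runs over
L box-bounded coordinates normalized by their sum inside the objective
(standard DE has box constraints only); defaults: population 15·L, dithered
mutation (0.5, 1), recombination 0.7, tolerance 1e−6, up to 200 generations,
no polish, fully seeded. Robustness follows Monte Carlo hold-out: each run
removes a random 20% of words; in the default *induced* mode per-layer
scores are recomputed on the induced sub-multiplex (*masked* mode merely
restricts them), reference orderings are restricted to retained words, the
analytic baseline is recomputed for the reduced vocabulary, and stage
windows scale proportionally. Fitted influences are averaged over runs and
the averaged weights are finally evaluated on the full vocabulary. The
control replaces every layer by a degree-preserving randomization and reruns
the whole procedure.

One structural fact worth knowing: under *degree* optimization the control
cannot show smaller gains, because degree-preserving randomization preserves
every word's degree and hence every degree-based score exactly. The control
contrast is informative for global metrics (closeness, betweenness,
clustering), and on synthetic data it is smaller than on richly structured
empirical networks, since randomized layers retain degree sequences that
correlate with closeness.

## Synthetic data

The generator emulates the statistical shape of the empirical study: four
layers over N = 529 words by default, mean degrees 9.3 / 9.0 / 8.1 / 1.31,
heavy-tailed (truncated Pareto, pdf exponent 2.5, scale solved so the capped
mean hits the target) association and co-occurrence degrees,
exponential-like feature and phonological degrees. Cross-layer degree
coupling uses a latent-Gaussian copula with Pearson parameters sin(πτ/2) for
Kendall-τ targets (defaults: feature–co-occurrence −0.16,
co-occurrence–phonological +0.27); degree sequences are realized by
Havel–Hakimi with rank-matched relabeling onto the coupled targets and
randomized by double-edge swaps. Triadic closure (default extra-edge
fractions 0.1/0.3/0.3/0.1) raises clustering above configuration-model
levels, and edge-overlap injection (default 0.05 among the semantic layers)
copies random edges between layer pairs. Closure and overlap injection
perturb realized degrees and push pairwise degree correlations positive, so
achieved — not target — statistics are what the topology stage reports.

CDI-like norms are planted: the combined score of a chosen metric under
chosen weights (defaults: 0.5/0.25/0.2/0.05 on closeness-scale structure,
with phonological influence near zero as in the empirical finding) maps
monotonically decreasing onto acquisition-onset months, jittered by Gaussian
noise (default 0.5 months), and production curves are logistics with slope
2/month, with onsets confined so every word crosses 50% (indeed 95%) by
month 30. Zipfian frequencies (exponent 1) and word lengths 2–10 negatively
rank-correlated with frequency complete the dataset.

What passing tests on synthetic data do and do not show: they verify the
statistical machinery end to end — sampling laws, estimator calibration,
recoverability of planted influences — under logistic, monotone production
curves and copula-coupled random topology. Real CDI curves can be
non-monotone, real layers have core–periphery and lexical structure no
configuration-style generator reproduces, and real layer influences are not
planted constants; conclusions about children's learning require the real
datasets, supplied through the documented TSV/CSV readers.

## Problem sizes and numerics

Default desk-scale runs use N = 100–529, 30 normative orderings, 100 null
samples, 10–50 hold-out configurations and DE budgets of 40–200 generations;
the test suite and the reproduction script use the lower ends of those
ranges as their study conditions. Eigenvalues below 1e−14 are dropped from
entropy sums; PageRank iterates to 1e−10; weight simplex tolerance is 1e−9;
all stochastic stages consume seeds derived from a master seed through
`numpy.random.SeedSequence`, making every run bit-reproducible. Degenerate
inputs are defined rather than left to chance: empty layers yield zero mean
degree and clustering with missing assortativity and path length, constant
degree vectors yield missing correlations, zero-edge layers are rejected by
the reducibility analysis, and σ = 0 baselines yield missing Z.

## Known limitations

- The multiplex closeness/betweenness reading (free layer jumps on the
  union graph) is one defensible interpretation of path metrics on an
  edge-coloured multiplex; versatile PageRank is approximated by the
  multiplicity-weighted union.
- Pipeline configuration is validated by a plain dataclass with explicit
  checks rather than a JSON-schema engine.
- The synthetic generator targets marginal scales and pairwise summaries,
  not higher-order lexical structure; heavy-tailed layers have large
  sample-to-sample fluctuations in realized mean degree (infinite-variance
  marginals), and overlap injection trades off against negative degree
  correlation targets.
- The extended adult phonological layer is not built; any externally built
  layer can be supplied through the edge-list format and participates in
  every analysis.
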