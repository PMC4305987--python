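# Methods notes

## Problem and model

`gofuse` scores the functional similarity of gene pairs from their Gene
Ontology annotations by integrating several established measures rather
than trusting any single one. The pipeline has three stages.

**Rank normalization.** Raw measures live on incomparable scales
(Resnik is an unbounded information content, SimUI a Jaccard index), so
within the gene set *GS* under analysis every measure's pair scores are
replaced by ascending fractional ranks and rescaled as
`RankSim = 2·rank/|GS|²`. Two consequences are worth flagging to users:
the divisor is |GS|² rather than the pair count, so the largest
attainable value is (|GS|−1)/|GS|, not 1; and scores are *relative to
the query set* — the same pair scored inside a different set gets a
different value. Ties receive the average of the tied positions, which
preserves the per-measure rank sum and makes the transform invariant to
permutations of equal scores.

**Seed selection.** For one pair, measures that agree form a tight
cluster on the RankSim axis. The reference procedure describes
agglomerative grouping with a shrinking distance threshold that prunes
isolated measures; on a 1-D axis this is equivalent to picking a
maximal contiguous window of the sorted values, which is how it is
implemented (deterministic and order-free). The window must span at
most `d_prime` (default 0.10) and hold at least `seed_min_size`
measures (default 3). Tie-breaks between equal-size windows: smaller
diameter, then the window containing the median value, then the lower
window. When no window qualifies, all measures are kept (`fallback`)
and the pair is treated as type *mix* — the model then degrades
gracefully toward average-style integration. The high/low/mix label
counts the isolated measures below versus above the chosen window; a
"central isolated cluster" cannot occur under contiguous windows, so
ties simply map to *mix*. Because the final lower-window tie-break is
direction-asymmetric, the label-reflection property (labels swap when
all values are replaced by 1−v) holds exactly only when the winning
window is unique before that tie-break; this is checked in the tests.

**Integration and training.** Each group type has its own parameter
vector (one weight per candidate measure, plus coefficients for the
max, min and mean of the seed RankSims), constrained non-negative with
unit sum; weights of measures outside a pair's seed group contribute
nothing to that pair, and no per-pair renormalization over the active
subset is applied. Weights are fitted by maximising OptF — the mean
over groups of LogFC, the log fold change between inter- and
intra-group distances `1 − sim + c_smooth` — on a training set grouped
by EC number or pathway. The printed form of LogFC divides each gene's
contribution by the partner-group size; a config switch
(`divisor="ei"`) provides the own-group variant. Only groups with at
least one fully disjoint partner group enter OptF, and the group-size
filters default to 3 genes for EC groups and 2 for pathways.

## Tabu search

The search optimises one type's simplex at a time (high → low → mix,
cycling until a full cycle brings no improvement), with independent
restarts from symmetric Dirichlet(1) draws. A move transfers
`min(δ, donor)` mass between an ordered pair of parameters, so all
neighbours stay on the simplex; step sizes default to {0.05, 0.01}.
Solutions are fingerprinted by rounding the full parameter vector to 4
decimals; a bounded FIFO tabu list (capacity 50) blocks recently
visited fingerprints except when a neighbour beats the best solution so
far (aspiration). A type stops when the best objective has not improved
for `stability_patience` consecutive moves (default 25; note that
non-improving moves are still taken, so the patience counter also
bounds downhill drift). Defaults of 5 restarts suit training sets of a
few hundred pairs; the test suite and acceptance script use 2–3
restarts with patience 8–15, which on the ~30–40-gene synthetic
conditions reaches the same optima in a few seconds. OptF evaluation in
the inner loop is vectorised (precomputed sparse aggregation over pair
indices); it is verified against the plain reference implementation.

## Candidate measures

Seven measures, implemented from their source definitions: SimUI
(Jaccard of ancestor-closed annotation sets), TO (closed-set overlap
normalised by the smaller set, so it is rank-comparable in [0, 1]),
SimGIC (IC-weighted Jaccard), Resnik (IC of the most informative common
ancestor, left un-normalised since only ranks matter), Schlicker
(relevance similarity, `2·IC(MICA)/(IC₁+IC₂) · (1−p(MICA))`), Wang
(semantic-contribution S-values with edge weights 0.8 for `is_a` and
0.6 for `part_of`), and HRSS (`1/(1+γ) · α/(α+β)` with α the MICA IC, γ
the IC distance of the terms to the MICA, and β the mean IC distance to
each term's most informative leaf descendant). Degenerate 0/0 cases are
pinned: Schlicker and HRSS at the root give 0; SimGIC over a union of
zero-IC terms gives 1 (the sets are informationally indistinguishable).
Term-level measures are lifted to genes by best-match average over the
direct annotation sets — the dominant, symmetric convention in this
literature. IC uses natural log of gene-level annotation frequencies
(closed sets over annotated genes); terms never annotated carry no IC
and are excluded from MICA candidacy. Ancestor closure is reflexive and
traverses only `is_a`/`part_of`, the relations the source definitions
use. Evidence codes are all retained by default, with an allowlist
option. The *fake* measure copies Resnik for a random half of pairs and
scores the rest 0 within a shared EC group and 1 across groups — a
deliberately reversed signal for robustness experiments.

## Synthetic data

The fixture generator emulates the *shape* of real inputs, not GO's
topology statistics: a complete `is_a` tree of configurable depth and
branching with ~10% extra `part_of` cross-edges to shallower terms
(keeping the DAG rooted and acyclic), and membership-disjoint gene
groups each owning a disjoint pool of leaf terms. A gene draws each
in-pool leaf with probability `p_in` and each off-pool leaf with
`p_out`. The default study condition — 5 groups × 6 genes, `p_in` 0.8,
`p_out` 0.1 — gives a clear but noisy planted signal: strong enough
that a sane measure separates groups, weak enough that measures
disagree and integration has room to help. Real corpora differ in ways
the fixtures do not model (shallow-vs-deep annotation imbalance,
correlated evidence, overlapping ECs, scale), so passing tests
demonstrate the machinery and its qualitative behaviour, not
organism-level performance figures. Cross-validation experiments use a
larger 10-group × 4-gene condition so that the held-out fifth of the
groups still contains disjoint group pairs.

## Numerical choices and degenerate inputs

* `c_smooth` (Laplacian smoothing inside LogFC) defaults to 0.01; any
  small positive constant works and the sign structure of diff is
  preserved on well-separated data.
* Groups that are singletons after removing the focal gene, or that
  have no disjoint partner, are excluded from OptF with a log line.
* Sum-to-one parameter validation uses a 1e−9 tolerance; tabu
  fingerprints round to 4 decimals.
* The trainer with `stability_patience=0` returns the (evaluated)
  random initial solution — useful as a baseline.
* Scoring refuses parameter sets trained with the fake measure, since
  the fake column cannot be computed without a grouping.

## Known limitations

Within-set ranking means scores are not comparable across different
query sets. The seed-selection window search is the package's normative
reading of the dendrogram-pruning description; other linkage choices
could pick a different core when clusters are equally tight. Training
assumes the grouping contains at least two mutually disjoint groups
with ≥ 2 genes each. Cross-aspect similarity and measures beyond the
seven candidates (Lin, Jiang–Conrath, …) are out of scope.
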