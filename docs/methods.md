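# Methods

## Network representation

A model is a signed directed multigraph over BEL terms. Node identity is
the canonical term rendering, which is injective on term structure (names
with characters outside `[A-Za-z0-9_-]` are double-quoted with backslash
escaping). The supported BEL 1.0 subset is the vocabulary used by causal
biological network models: functions `p, act, r, g, m, bp, path, complex,
composite` and the four causal relations; other BEL constructs
(translocation, degradation, hasComponent, …) are rejected with an explicit
error rather than silently skipped.

Layer assignment is purely functional: `r()` terms form the transcript
layer, everything else the backbone. An `r()` node with outgoing causal
edges stays a transcript node (it is still usable as a scoring gene) and is
reported by the iNode indexer. Edges are unique per
`(source, target, sign, direct)`; duplicate statements merge their evidence
contexts, deduplicated by (citation, evidence text, annotations) so that
merging a model with itself is the identity. Conflicting curation — both a
+1 and a −1 edge between the same pair — is retained as two edges; the
scoring layer treats such transcript attachments as *ambivalent* and
excludes them, since no resolution rule can be justified from curation
alone. Self-loops are kept and flagged.

Dead-end trimming removes every backbone node with no directed path (edge
signs ignored) to an anchor, where anchors are the `bp()`/`path()` nodes —
signalling in these models flows toward processes and pathologies, so
outgoing reachability is the linkage criterion (the alternative, counting
incoming paths from anchors as linkage too, would keep strictly more nodes;
it is not implemented). Transcript nodes survive only while attached to a
surviving backbone node. Reachability is computed once on the reversed
graph, which is already the fixed point of iterated dead-end removal; the
tests verify this against a per-node forward-search oracle. A model without
anchors is returned unchanged with a warning.

Orthologization maps `MGI`/`RGD` leaf symbols to HGNC through a
user-supplied two-column table (no ortholog database is bundled); renamed
nodes that collide with existing HGNC nodes are fused with edge and
evidence union, and unmapped symbols are left unchanged and reported.

## The Strength statistic

For an iNode *v* with measured signed transcripts `G_v`,

    S(v) = (1/|G_v|) Σ s_g · log2FC_g .

This is the minimal statistic that is threshold-free (every measured
transcript contributes, no fold-change or p-value cutoff) and
direction-aware (edge signs flip the contribution of repressed targets).
No gene-level variance weighting is applied; fold changes are taken as
given. Genes in the model but absent from the contrast are skipped, not
imputed as zero — absence from an expression platform is not evidence of
no change. Duplicate rows for a gene in a contrast table are aggregated by
median before scoring, and symbols are upper-cased.

## Permutation significance

The null is competitive: redraw `|G_v|` fold changes uniformly without
replacement from the full measured universe, keep the assignment signs,
and recompute S. This preserves the contrast's empirical fold-change
distribution and asks whether the node's transcripts are unusually
concordant relative to arbitrary measured genes. The test is two-sided on
|S|.

* **Exact mode.** When the number of distinguishable draws — C(U, n)
  subsets times C(n, k) assignments of drawn values to the k positive sign
  slots when signs are mixed — is at most `exact_threshold` (default
  100 000), the null is enumerated. Averaging over sign-slot splits is
  exactly equivalent to enumerating ordered draws, which is what the
  Monte-Carlo sampler approximates; the unit tests check this equivalence
  against a brute-force ordered-draw oracle.
* **Monte-Carlo mode.** Otherwise `n_perm` (default 10 000) ordered draws
  are sampled and `p = (1 + #{|S*| ≥ |S|}) / (1 + n_perm)`; the add-one
  correction makes the floor 1/(n_perm+1) and keeps the null distribution
  of p uniform on its grid. Sampling uses random-key ordering on small
  universes and rejection of duplicate index rows on large ones; both
  yield uniformly random ordered arrangements, which matters whenever
  signs are mixed.
* **Tie tolerance.** Draws are counted as at least as extreme using
  `|S*| ≥ |S| − 1e−12`, so the observed draw itself (always part of the
  null) is never lost to floating-point summation order.

Multiplicity is handled per contrast by Benjamini–Hochberg across all
scored iNodes (delegated to `statsmodels.stats.multitest`); `significant`
means adjusted p below `alpha` (default 0.05), and the inferred direction
is the sign of S for significant nodes, `null` otherwise. Scoring is
deterministic given the seed: one child generator per node is spawned from
a `SeedSequence` in sorted node-id order, so results do not depend on
iteration order and score tables are byte-identical across runs.

## Two-contrast divergence

Each node receives a category from its two significance flags (`both`,
`first_only`, `second_only`, `none`); nodes scored in only one contrast are
non-significant in the other. Divergent = significant in both with opposite
Strength signs, or significant in exactly one; the stricter
opposite-sign-only predicate is exposed as an option because the inclusive
rule is a modelling choice, not a mathematical necessity. The minimal
divergent network is the induced subgraph on the flagged nodes; optional
path contraction adds an `indirect` edge for a pair joined by a directed
simple path of ≤ `max_path_len` edges through unselected backbone nodes,
with sign the product of edge signs along the path. Pairs whose qualifying
paths disagree on the net sign get no edge and are reported — asserting an
unsupported net direction would be worse than asserting nothing. An
indirect edge duplicating the sign of an existing induced edge is likewise
suppressed.

## Synthetic data

The generator emulates the two-layer structure the scorer consumes, not a
microarray: backbone nodes `act(p(HGNC:SYNnnnn))` with Bernoulli(edge_prob)
signed edges per ordered pair, one `bp()` anchor fed by every backbone node
(so trimming is the identity on generated models), and
`max(min_genes, Poisson(genes_per_node_mean))` private `r()` transcripts
per node with attachment sign +1 with probability `sign_prob`. Exactly
`⌊frac_active · n⌋` nodes carry a planted activity `a ∈ {−1, +1}`; a
transcript of node *v* with sign *s* measures
`log2FC = s · a_v · δ + N(0, σ²)` and `n_null_genes` unattached genes are
pure noise. Transcripts are private to one node by default so the planted
truth is unambiguous; `share_prob` exists for stress tests. Gaussian noise
on log2 fold changes is the standard additive effect model; the generator
does not simulate probe-level intensities, count overdispersion,
inter-gene correlation, or shared targets between regulators — so passing
recovery tests demonstrate the inference machinery, not robustness to
correlated real-data noise.

Reference conditions (the defaults): 100 backbone nodes, half active,
effect δ = 2 log2 units against noise σ = 0.2, ten transcripts per node on
average, 500 null genes, edge_prob = 0.05. These give a cleanly separated
planted signal under which sign recovery and power are expected to be
perfect while type-I error stays within the nominal level.

## Simulation sizes used by the checks

* Null calibration: 2000 backbone nodes, no backbone edges (they do not
  affect scoring), frac_active = 0, ~6 transcripts per node, 1000 null
  genes, n_perm = 2000 — p-value resolution 1/2001 is ample for assessing
  the 0.05 tail, and the run stays a few seconds.
* Exact-vs-Monte-Carlo corpus: 100 cases with universe ≤ 8 and set size
  ≤ 3, n_perm = 10 000. A per-case 3-standard-error band holds each case
  with ~99.7% probability, so the corpus is judged simultaneously (≥ 97
  cases within 3 SE, all within 5 SE).
* Recovery: the reference conditions above, n_perm = 10 000.

## Known limitations

* The permutation null treats genes as exchangeable; correlated transcripts
  (co-regulation, probe redundancy) make it anti-conservative on real data.
* Strength carries no gene-level uncertainty; two contrasts are compared
  only through their significance calls and score signs, never by testing
  S_A − S_B directly.
* `min_genes = 3` is a floor for the null's granularity, not a guarantee of
  power; with three genes the smallest exact two-sided p can still be far
  from 0.05 on tiny universes.
* BEL coverage is deliberately the subset above; scripts using other BEL
  1.0 or 2.x constructs must be reduced before compilation.
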