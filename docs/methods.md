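# Methods

## Input encoding

Recorder data arrive as an allele table: per cell, one edit label per
target site (`NONE` = unedited). A *synthetic marker* is a distinct
(site, edit label) pair; this key makes scGESTALT-style inputs (one
edit can span sites, labels repeat across sites) and ScarTrace-style
inputs uniform. Cells with identical binary marker profiles share a
*barcode*; the paired-event matrix `E` (B barcodes × S markers) plus
the cell→barcode map `z` is the working representation, expanded to
an N × S cell-level matrix where needed. Every marker column has at
least one carrier by construction, and barcode rows are pairwise
distinct.

Expression input is expected normalized, imputed and log-scale. For
fixtures and datasets without an external imputer, a fallback is
provided: per-cell library-size scaling to the median total followed
by log2(x + 1), optionally preceded by a cluster-mean imputer (k-means
on log counts, k chosen by silhouette over 2–10; each zero entry is
replaced by the mean of the nonzero values of that gene among its
cluster's cells). This transform is a deliberately simple stand-in,
not a re-implementation of any specific external tool, and is
isolated behind `preprocess_expression`.

## Mutation likelihood

Markers evolve irreversibly (Camin-Sokal): the 2×2 transition matrix
has zero probability for 1 → 0. Given a tree, Fitch's algorithm
assigns per-marker ancestral states minimizing changes, with the root
forced to the unedited state; the top-down pass takes the parent's
state whenever it lies in the node's state set (ties broken toward
the parent, root = 0). The per-marker log-likelihood is the sum of
log transition probabilities over edges — equivalently the bottom-up
partial-likelihood recursion evaluated at the root, and both routes
are implemented and cross-checked. A marker whose Fitch assignment
contains a reversal contributes a flat −100000 penalty, applied once
per violating marker (the assignment of that marker is the violating
object, not each violating edge). `m_s` is always the fraction of
*cells* carrying marker `s`, also when barcode-level trees are scored.

Edge cases: `m_s = 1` markers contribute 0 on their gain edges
(log 1), and a 0→0 edge cannot co-occur with `m_s = 1` under a Fitch
assignment; `m_s = 0` markers (possible only for hypothetical
markers, not encoded ones) contribute 0.

## Expression likelihood (BHC)

Per gene, the observation model is Normal with unknown mean and
precision under a conjugate Normal-Gamma prior; genes are independent
(diagonal covariance), so the one-cluster marginal `P(Y|H1)` is a sum
of closed-form per-gene terms computed from sufficient statistics
(n, Σx, Σx²). Default hyperparameters are empirical Bayes: prior mean
= per-gene grand mean, strength κ₀ = 0.01·N pseudo-observations,
shape a₀ = 1, rate b₀ = per-gene variance (floored at 1e−8 for
constant genes); the DPM concentration α defaults to 1. All are
configurable through `ExpressionPrior`.

The recursion uses the identity `1 − π_v = d_u d_w / d_v` so both
mixture weights are exact in log space; `Γ(n_v)` enters only through
`gammaln`. The root marginal is the tree's expression likelihood;
single-leaf trees score as the leaf marginal directly.

One behavioral note: with a vague variance prior, two *extremely*
distant cells can still merge (r_v > 0.5), because one inflated-
variance cluster explains them better than two clusters whose means
are each implausible under the prior. Distance forces a split only
when the precision prior is informative. This is an inherent property
of marginal-likelihood clustering with unknown variance, not a bug;
the empirical-Bayes default (rate = data variance) behaves sensibly
on real-scale data because the prior variance is then matched to the
data spread.

Scoring is a full re-evaluation per candidate tree: a post-order pass
accumulates sufficient statistics, one vectorized pass computes all
H1 marginals, and a cheap scalar loop runs the π/d/L recursion. At
the problem sizes this package targets (≤ a few hundred cells) this
is faster and simpler than fine-grained per-node cache invalidation,
which was considered and dropped.

## Combined likelihood and search

`L_T = ω₁ log L_M + ω₂ log L_E`, defaults ω₁ = 50, ω₂ = 1 (keeps the
two terms in the same range at typical S and G; both are exposed).

The four-step search:

1. **Barcode trees.** Hill climbing by `L_M` on B-leaf trees with
   rSPR proposals, strict improvement, stopping after `stall` (2000)
   non-improving proposals. Because single-move rSPR hill climbing
   from random starts can land in genuine one-move local optima, the
   phase is an iterated local search: the first climb starts from a
   deterministic perfect-phylogeny-style guide tree (recursive split
   of the barcode set by the most frequent marker informative within
   the block — exact on Camin-Sokal-compatible data), followed by
   random-start climbs (sequential random leaf attachment) and
   ratchet rounds that kick the incumbent with 2–8 random rSPR moves
   and re-climb. The move set stays rSPR-only. The `t` (default 5)
   best distinct topologies ever evaluated are retained, deduplicated
   by a canonical topology hash.
2. **Cellular subtrees.** For each barcode with ≥ 3 cells, hill
   climbing by `L_E` with stNNI moves from an average-linkage
   (Euclidean) start; 2 cells become a cherry directly.
3. **Assembly.** Each barcode leaf is replaced by its cellular
   subtree (1 cell → leaf, 2 cells → cherry); the `t` assemblies are
   scored by `L_T`, the best kept, and the mutation slack frozen at
   `L_M_thr = L_M_best + thr·L_M_best` (thr default 0.01; log-
   likelihoods are negative, so the bound is looser than `L_M_best`).
4. **Refinement.** rSPR hill climbing on the full cell tree; a
   proposal is accepted iff `L_M ≥ L_M_thr` *and* `L_T` strictly
   improves; same stall rule.

Strict improvement (ties rejected) guarantees each phase terminates.
Every phase consumes randomness only from one seeded generator, so a
given (inputs, config, seed) triple reproduces the search trace and
the final tree bit-exactly. Proposals: stNNI picks a focal internal
branch of the *unrooted* topology and swaps one subtree from each
side (trees with < 4 leaves have no focal branch and return
unchanged); rSPR prunes a random non-root subtree, suppresses the
unary node, and regrafts on a random remaining branch or above the
root.

## Cluster inference

`r_v = π_v P(Y_v|H1) / L_v`, evaluated in log space; leaves have
r = 1. The tree is cut top-down at the topmost node with `r_v > 0.5`
on each root-to-leaf path, so every leaf belongs to exactly one
cluster; a leaf none of whose ancestors merge becomes a singleton.
`r_v = 0.5` exactly counts as "not merged" (deterministic
tie-break). After inference the binary tree can be reported with
unsupported branchings contracted: an internal edge is kept only if
some marker is gained on it or its child is a cluster cut.

## Invariant lineage

Per individual, clusters with fewer than `tc` (default 3) cells are
dropped. Cluster representatives are mean expression vectors over the
intersection of gene sets, standardized per gene across the pooled
clusters of all individuals (so no gene dominates the Euclidean
distances). Candidate cross-individual groups are enumerated (capped
at 10⁷ tuples; beyond that each non-reference individual is
pre-filtered to the 50 nearest neighbors of the reference clusters),
ranked by the summed pairwise distance, and the smallest x% (default
1%) retained. Greedy matching scans that ranking and takes every
group whose constituents are all unused, yielding K matched groups.

Each individual's tree is restricted to its K matched cut nodes
(nested matched clusters are an error), unary nodes suppressed. The
invariant tree on K leaves and the matching minimize
`ω₁ D_S + ω₂ D_E`, where `D_S` sums, per individual, the pairwise
leaf shortest-path disagreement (edge counts to the MRCA) between the
invariant tree and the backbone, and `D_E` sums the within-group
expression distances. Both terms are normalized by their initial
values (falling back to 1 when an initial value is 0) and weighted
ω₁ = ω₂ = 1 by default. Optimization: step 1 alternates
best-improvement matching transpositions (swap one individual's
clusters between two invariant leaves, accepted iff `D_E` falls) with
topology hill climbing at fixed matching (rSPR/stNNI, accepted iff
`D_S` falls) until the matching is locally optimal, then freezes
`D_E_thr = D_E_best + thr·D_E_best` (thr default 0.05); step 2
proposes matching transpositions (accepted iff the objective falls
and `D_E ≤ D_E_thr`) or topology moves (accepted iff the objective
falls), stopping on stall (default 500) or the iteration cap. The
initial invariant topology is the first individual's backbone with
leaves relabelled by the matching.

## Recorder simulator

Each cell carries `m` target sites (default 5). Along each branch,
every still-unedited target mutates with probability `mu` (default
0.15) to one of `n_states` (default 8) equiprobable outcomes; edits
are then immutable. Site-specific rates can be drawn once from a
Beta distribution parameterized by (mean, sd) (shape parameters
solved analytically; pairs with sd² ≥ mean(1−mean) are rejected).
Dropout: each internal branch (child is an internal node) drops with
probability `eps_d / #internal branches`; an event picks one
currently-mutated target uniformly and erases its record — state
reset to unedited, indistinguishable from never-edited — for the
whole descendant subtree. A branch with no mutated target is
unaffected even when the trial fires, so the realized event count
falls slightly below `eps_d` at low edit rates. Internal-node states
and erased-entry flags are always retained so tests can check
heritability without re-simulating. The bundled depth-4 complete
binary lineage (16 cells, 4 divisions) with m = 5 and 8 states is the
reference calibration protocol; the expected edited-entry fraction at
depth d is `1 − (1 − mu)^d`.

Matched expression is synthesized per cell type (clade): each type's
mean vector is drawn N(0, separation²) per gene and cells add
independent N(0, noise_sd²) noise. This emulates cluster structure
aligned with lineage, and none of the things real scRNA-seq has:
counts, zero inflation, library-size variation, batch effects, or
types shared across distant clades. Passing tests on these fixtures
therefore demonstrates correctness of the algorithms under their own
model assumptions — not performance on real data.

The deterministic `clade_fixture` plants exactly one unique marker on
every edge of a random clade tree (all cells of a clade share one
barcode), which makes the barcode data a perfect phylogeny and the
generating tree the unique zero-violation optimum; it is the
benchmark for exact-recovery tests (20 clades × 5 cells by default).

## Metrics

Rooted trees are compared as unrooted (standard RF convention):
splits from internal edges, trivial splits dropped, complementary
sides canonicalized. Bipartition accuracy = |B_true ∩ B_inf| /
|B_true|; normalized RF divides the symmetric difference by the *sum*
of the two split counts (the union is a defensible alternative; the
sum is used and stated); FP/FN are the one-sided fractions and
support multifurcating trees. Zero-denominator cases (star trees)
return 0 with an explicit warning collected in the MetricReport. ARI
is computed from the contingency table with exact integer binomials;
when the chance-correction denominator vanishes (both partitions
trivial) the value is 1 if the partitions agree and 0 otherwise.

## Problem sizes and defaults in the test suite

Oracle tests run at the sizes where exhaustive enumeration is exact
(all rooted topologies up to 6 leaves: 15/105/945). End-to-end
recovery uses 20 clades × 5 cells (100 cells, 38 markers, 20 genes);
determinism re-fits an 8-clade fixture twice; simulator calibration
uses 1000 replicates per edit rate and 2000 for dropout. These sizes
were chosen so the whole suite exercises every pipeline stage at
meaningful scale while staying conveniently fast on one core.

## Known limitations

- The exact normalization and the conjugate-prior hyperparameters of
  the original workflows this package emulates are not standardized;
  the choices here are documented defaults, all configurable.
- The dropout-aware mutation model (treating the observed carrier
  fraction as a function of a Beta-distributed true fraction) is not
  implemented; dropout exists only in the simulator.
- Hill climbing offers no optimality guarantee; the iterated local
  search makes perfect-data recovery reliable at benchmark sizes, but
  real saturated recorders can still yield ties and local optima.
- Branch lengths are not modeled (topology only); sequence-level edit
  structure (indel lengths, multi-site deletions) is out of scope.
- Candidate-group enumeration grows as the product of per-individual
  cluster counts; the cap plus nearest-neighbor pre-filter bounds it,
  at the cost of possibly missing exotic matchings.
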