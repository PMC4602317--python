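# Methods

## Problem and model

A *species tree* S is a rooted binary tree over a species set Σ. A *gene
tree* is a rooted binary tree whose leaves are genes, each assigned to a
species by a map s : Γ → Σ. The map extends to internal nodes by
s(x) = lca_S of the species below x. A node x with children x_l, x_r is a
**speciation** when s(x_l) and s(x_r) are *separated* in S (neither is an
ancestor-or-equal of the other) and a **duplication** otherwise; a
duplication with s(x) = r(S) is a **pre-speciation duplication**. Ancestry
is inclusive throughout: a node is an ancestor of itself.

The *duplication cost* of a gene tree is its number of duplication nodes.
The *mutation cost* adds the minimum number of losses implied by the LCA
mapping, counted per edge: the edge from x down to child c spans
e = depth(s(c)) − depth(s(x)) species-tree edges and implies e − 1 losses
under a speciation and e under a duplication. The loss formula is the
standard linear-time count for LCA reconciliation; the test suite verifies
it against exhaustive enumeration of explicit embeddings (all consistent
assignments of internal nodes to ancestors of their LCA images) for trees
with up to six leaves, for both the loss count and the total
duplication+loss cost.

Given a consistent set of partial gene trees, the *supergenetree* problem
asks for a binary tree on the union of their leaf sets that displays every
input and minimizes the duplication (or mutation) cost against S. Both
variants are NP-hard (by reduction from graph coloring, see below), so the
package pairs an exact exponential solver with a greedy heuristic.

## Compatibility: triplets and BUILD

T displays T' iff T restricted to L(T') equals T'. For binary trees this
reduces to rooted triplets: tr(G) collects, for every input tree and every
3-subset of its leaves, the induced triplet xy|z. The BUILD algorithm
recursively decomposes the *triplet graph* (edge xy whenever some triplet
xy|z has all three genes in the current subset): one connected component on
≥ 3 vertices means inconsistency; otherwise each component becomes a child
subproblem. Components are ordered by their smallest gene label so BUILD
trees and solver outputs are reproducible.

## Exact solver

Any binary supertree's root bipartition must keep each triplet-graph
component whole (splitting an edge xy of a triplet xy|z would collapse
lca(x,y) into lca(x,y,z)). Hence the optimum satisfies

    R(P) = min over bipartitions (C, C̄) of the components of the triplet
           graph on P of  R(V(C)) + R(V(C̄)) + d(V(C), V(C̄))

with R(P) = 0 for |P| ≤ 1, where d is 0 when s(V(C)) and s(V(C̄)) are
separated in S and 1 otherwise. Implementation choices:

* **Subset images.** s(X) is precomputed for all 2ⁿ − 1 nonempty subsets
  as a bitmask-indexed table, each entry from one previously computed
  subset plus one singleton via a single O(1) LCA query (Euler tour +
  sparse table). The table is filled in increasing bitmask order, which
  also guarantees every proper subset precedes its superset.
* **Bipartitions** are enumerated as unordered pairs (2^(m−1) − 1 of them
  for m components, the first component pinned to one side), halving the
  symmetric enumeration.
* **Mutation cost.** The per-node term becomes d plus the node's losses,
  computed from s(P), s(V(C)), s(V(C̄)) by the same depth-difference
  formula; summed over the DP tree this equals the full reconciliation
  cost of the returned tree, which the tests assert.
* **Determinism.** Ties between equal-cost bipartitions go to the smaller
  side bitmask; memo keys are bitmasks over the lexicographic gene order.
* **Caps.** The DP refuses more than 22 genes (≈4M subsets) and the
  enumeration oracle more than 8 (135 135 topologies); both caps are
  arguments, and the greedy solver is the intended fallback.

A constrained variant scores a user-supplied root bipartition (infeasible
when it splits the cherry pair of any input triplet), which is how the
suboptimal-root comparison in the worked example is computed.

The independent ground-truth oracle enumerates all (2n−3)!! rooted binary
topologies by leaf insertion over nested tuples, filters by display
(restriction + canonical-form comparison, implemented separately from the
library's tree container) and minimizes the requested cost, tie-broken by
canonical string. It shares only the species-tree LCA index with the code
it checks.

## Greedy Max-Cut heuristic

A triplet xy|z whose root is a duplication mapped to r(S) is *required*:
every displaying supertree contains that duplication. Over the triplet
graph's components, an edge of weight w records w distinct required
triplets whose cherry pair lies in one component and outgroup in the
other. A root bipartition that cuts weight w merges those w required
duplications into the one duplication created at the root, so the best
greedy root is a maximum cut. The construction recurses into both sides.

Decisions taken where the procedure is underdetermined:

* **Below the root** the "required" notion is taken relative to s(P), the
  species image of the current gene subset P: a triplet counts when its
  root maps exactly to s(P) and is a duplication. This generalizes
  "preceding the first speciation" to every subproblem.
* **Edgeless component graphs** (no required duplication crosses
  components) fall back to the bipartition minimizing the duplication
  flag d, then imbalance, then canonical order — pushing duplications
  down the tree. With more than 16 components the enumeration is replaced
  by grouping components by which child of s(P) their image descends
  into.
* **Max-Cut** is solved exactly (vectorized bipartition enumeration) up
  to 20 component-graph vertices and by seeded multi-restart single-flip
  local search beyond; the local search is deterministic for a fixed
  seed. An SDP rounding scheme was deliberately avoided; the heuristic
  claims no approximation factor (none exists for the overall problem
  unless P = NP) and is validated only as an upper bound on the exact
  optimum, with equality checked on the worked example.

## Synthetic data

`simulate_instance` grows one full gene tree T\* along a random species
tree: at each step a lineage duplicates in place with probability p or
follows the speciation at its current species node, and each descending
branch is lost with probability q; extinct subtrees are contracted.
Input trees are restrictions of T\* to sampled leaf subsets, so instances
are consistent by construction and T\* (restricted to the sampled family)
is a feasible supertree whose cost upper-bounds the optimum — both facts
are asserted in tests. Defaults — 8 species (Yule shape), p = 0.2,
q = 0.1, k = 3 trees of 3–6 genes — describe a modest, mildly paralogous
gene family; the oracle-comparison tests use 6 species and subsets of 2–4
genes so that the union stays within the enumeration cap of 7 genes. The
recorded "true" duplication/loss counts are the LCA reconciliation of the
surviving tree: the generative event count is not recoverable once losses
prune lineages. `speciation_only` assembles subsets greedily so each
restriction contains only speciations; `disjoint` samples without
replacement (the independent-speciation-trees regime, where a feasible
speciation-preserving supertree always exists — asserted via the
constrained oracle).

What the simulator does *not* emulate: sequence evolution and
reconstruction error (inputs are always correct restrictions of one true
tree), branch lengths and rate variation, transfers, and incomplete
lineage sorting. Passing tests therefore certify the combinatorial
optimization, not robustness to gene-tree estimation error.

The coloring encoding turns a graph H into an instance with genes v₁, v₂
per vertex (bijectively mapped to species), species tree (S₁, S₂) with S₁
a left caterpillar over the "1" species and S₂ over the "2" species (any
binary shapes work; caterpillars over sorted labels make outputs
reproducible), and four triplets v₁v₂|w₁, v₁v₂|w₂, w₁w₂|v₁, w₁w₂|v₂ per
edge vw. Every compatible supertree must display ((v₁,v₂),(w₁,w₂)) for
each edge, and the minimum duplication cost equals χ(H) − 1. The test
suite verifies this equivalence exhaustively (against brute-force
chromatic numbers and brute-force tree enumeration) for every graph on at
most 4 vertices with an edge, and for the 5-cycle through the DP at 10
genes.

## Degenerate inputs and edge cases

Input trees must be binary; polytomies are rejected at parse time rather
than resolved (BUILD output is the one place polytomies occur). A
restriction keeps its root at the LCA of the kept leaves. Single-gene
input trees are legal and constrain nothing. Gene trees may share genes;
the disjointness required by the speciation-preservation mode is enforced
only when requested. Rooted-tree isomorphism uses a canonical form with
children sorted by (minimum leaf label, subtree string).

## Known limitations

* The exact solver is exponential by nature (the problem is NP-hard to
  approximate within n^(1−ε)); beyond ~22 genes only the heuristic runs.
* The heuristic optimizes pre-speciation duplications level by level;
  its gap to the optimum is unbounded in theory and only empirically
  small on the tested instances.
* Only duplication and loss events are modeled; transfers are out of
  scope, as are unrooted or non-binary species trees and branch-length
  aware costs.
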