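# supergenetree

Supertree construction for **gene** trees: given a binary species tree *S*
and a collection of binary gene trees G₁..G_k on (possibly overlapping)
subsets of a gene family Γ, decide whether one tree can display them all
and, if so, build a binary supertree *T* minimizing a reconciliation cost
against *S*.

Phylogenomic pipelines routinely produce several partial trees for one gene
family — trees for ortholog clusters, trees from different databases, trees
restricted to well-aligned subfamilies. Classical supertree methods (the
BUILD algorithm and its descendants) only ask for *compatibility*. When a
species tree is known, there is a much better criterion for choosing among
the exponentially many compatible supertrees: pick one whose LCA
reconciliation with *S* implies the fewest gene duplications (the
*duplication cost*), or the fewest duplications plus losses (the *mutation*
cost). This package implements that optimization:

* **`core_trees`** — rooted leaf-labeled trees, Newick I/O, constant-time
  LCA index, restriction `T|L'` and the *displays* relation, gene→species
  mappings, validated problem instances.
* **`reconcile`** — LCA mapping s(x), speciation/duplication labeling,
  duplication / loss / mutation costs, required-duplication triplets, and
  the speciation-preservation check for independent speciation trees.
* **`triplets_build`** — triplet extraction tr(G), the triplet graph,
  and the BUILD compatibility test.
* **`exact_solver`** — exact optimum via a memoized recurrence
  `R(P) = min over component bipartitions (C, C̄) of
  R(V(C)) + R(V(C̄)) + d(V(C), V(C̄))`
  over gene subsets, with an O(2ⁿ) precomputation of the species image
  s(X) of every subset; plus a constrained-root variant and a brute-force
  enumeration oracle over all (2n−3)!! topologies.
* **`greedy_maxcut`** — a recursive Max-Cut heuristic that merges as many
  *required* pre-speciation duplications as possible into each created
  node (the problem is NP-hard to approximate, so no factor is claimed).
* **`simulate`** — synthetic instances with known ground truth, and a
  graph-coloring encoding whose optimum is χ(H) − 1, used as an exact
  correctness fixture.
* **`cli`** — the `sgt` command (`check`, `solve`, `reconcile`,
  `simulate`, `reduce-coloring`).

## Worked example

Six species, three input triplets whose roots are all duplications forced
onto the species root:

```sh
cat species.nwk      # ((a,(b,c)),(d,(e,f)));
cat genetrees.nwk    # ((a1,d1),c1);  ((d1,b1),e1);  ((c1,e1),f1);  (one per line)
sgt solve -s species.nwk -g genetrees.nwk -m map.tsv --method dp
```

prints

```
dup=1
(((a1,b1),(d1,f1)),(c1,e1));
```

The triplet graph has components {a1,b1,d1}, {c1,e1}, {f1}; the required
duplications induce component-graph edges of weight 2 ({a1,b1,d1}–{c1,e1})
and weight 1 ({c1,e1}–{f1}). The maximum cut has weight 3 and yields the
root bipartition ({a1,b1,d1,f1},{c1,e1}), which merges all three required
duplications into the single root duplication — hence the optimal cost 1.
Forcing the suboptimal root instead:

```sh
sgt solve -s species.nwk -g genetrees.nwk -m map.tsv --root-split "a1,b1,d1|c1,e1,f1"
```

```
dup=2
(((a1,b1),d1),((c1,e1),f1));
```

defers the c1e1|f1 duplication one level down and pays for it.

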