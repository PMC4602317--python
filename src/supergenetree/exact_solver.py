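"""Exact minimum-duplication / minimum-mutation supergenetrees.

The solver evaluates the recurrence

    R(P) = min over proper component subsets C of the triplet graph on P of
           R(V(C)) + R(complement) + d(V(C), complement)

where d is 0 when the species images of the two sides are separated in S
(the node is a speciation) and 1 otherwise (a duplication).  R(Gamma) is
the optimal duplication cost over all binary supertrees displaying every
input tree; memoization over canonical gene-subset bitmasks plus an O(2^n)
precomputation of the species image s(X) of every gene subset X make each
subproblem cheap.  For the mutation cost the per-node term additionally
charges the losses implied by the node's mapping (see
:mod:`supergenetree.reconcile` for the loss formula).

A brute-force enumerator over all (2n-3)!! rooted binary topologies serves
as the independent ground-truth oracle at small n, optionally constrained
to speciation-preserving supertrees.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

from .core_trees import (
    GeneTree,
    Node,
    ProblemInstance,
    SpeciesTree,
    Tree,
    TreeError,
)
from .reconcile import label_nodes
from .triplets_build import extract_triplets

__all__ = [
    "InconsistentError",
    "InfeasibleError",
    "SizeLimitError",
    "SubsetLcaTable",
    "precompute_subset_lca",
    "dup_flag",
    "solve_exact",
    "solve_constrained_root",
    "oracle_enumerate",
    "enumerate_topologies",
]

INFINITY = math.inf

DP_GENE_CAP = 22
ORACLE_GENE_CAP = 8


class InconsistentError(TreeError):
    """The input gene trees admit no common supertree."""


class InfeasibleError(TreeError):
    """No supertree satisfies the requested constraint."""


class SizeLimitError(TreeError):
    """The instance exceeds a configured size cap."""


# ---------------------------------------------------------------------- #
# subset LCA precomputation


class SubsetLcaTable:
    """s(X) for every nonempty gene subset X, indexed by bitmask.

    Gene order is lexicographic by gene id; bit i of a mask stands for
    ``genes[i]``.  Entry ``mask`` is filled from a previously computed
    proper subset and one singleton via a single pairwise LCA, so the whole
    table costs O(2^n) LCA queries.
    """

    def __init__(self, instance: ProblemInstance,
                 max_genes: int = DP_GENE_CAP) -> None:
        genes = instance.genes
        n = len(genes)
        if n > max_genes:
            raise SizeLimitError(
                f"{n} genes exceeds the subset-DP cap of {max_genes}; "
                "use the greedy solver for larger instances")
        self.genes: tuple[str, ...] = genes
        self.index: dict[str, int] = {g: i for i, g in enumerate(genes)}
        self.species_tree: SpeciesTree = instance.species_tree
        S = instance.species_tree
        table: list[Node | None] = [None] * (1 << n)
        for i, gene in enumerate(genes):
            table[1 << i] = instance.species_node(gene)
        for mask in range(1, 1 << n):
            if table[mask] is not None:
                continue
            low = mask & -mask
            table[mask] = S.lca_pair(table[mask ^ low], table[low])
        self._table = table

    def species_of_mask(self, mask: int) -> Node:
        node = self._table[mask]
        if node is None:
            raise TreeError("empty subset has no species image")
        return node

    def mask_of(self, genes: Iterable[str]) -> int:
        mask = 0
        for gene in genes:
            mask |= 1 << self.index[gene]
        return mask

    def genes_of_mask(self, mask: int) -> tuple[str, ...]:
        return tuple(g for i, g in enumerate(self.genes) if mask >> i & 1)

    def species_of(self, genes: Iterable[str]) -> Node:
        return self.species_of_mask(self.mask_of(genes))


def precompute_subset_lca(instance: ProblemInstance,
                          max_genes: int = DP_GENE_CAP) -> SubsetLcaTable:
    return SubsetLcaTable(instance, max_genes=max_genes)


def dup_flag(left: Iterable[str] | int, right: Iterable[str] | int,
             table: SubsetLcaTable) -> int:
    """The d term of the recurrence: 0 when s(left) and s(right) are
    separated in S (speciation node), 1 otherwise (duplication node).

    Separation is decided by checking that lca(s(left), s(right)) differs
    from both images.
    """
    lmask = left if isinstance(left, int) else table.mask_of(left)
    rmask = right if isinstance(right, int) else table.mask_of(right)
    if not lmask or not rmask:
        raise TreeError("dup_flag requires two nonempty sides")
    if lmask & rmask:
        raise TreeError("dup_flag requires disjoint sides")
    s_left = table.species_of_mask(lmask)
    s_right = table.species_of_mask(rmask)
    anc = table.species_tree.lca_pair(s_left, s_right)
    return 0 if (anc is not s_left and anc is not s_right) else 1


# ---------------------------------------------------------------------- #
# the subset dynamic program


class _DP:
    def __init__(self, instance: ProblemInstance, cost: str,
                 max_genes: int) -> None:
        if cost not in ("dup", "mutation"):
            raise ValueError(f"cost must be 'dup' or 'mutation', got {cost!r}")
        self.cost = cost
        self.table = SubsetLcaTable(instance, max_genes=max_genes)
        self.S = instance.species_tree
        idx = self.table.index
        tr = extract_triplets(instance.gene_trees)
        # per triplet: the full 3-gene mask and the pair edge it induces
        self.triplets = [
            (1 << idx[t.a] | 1 << idx[t.b] | 1 << idx[t.z],
             idx[t.a], idx[t.b])
            for t in tr
        ]
        self.memo: dict[int, tuple[float, tuple[int, int] | None]] = {}

    def components(self, mask: int) -> list[int]:
        """Connected components (as submasks) of the triplet graph on mask."""
        bits = [i for i in range(mask.bit_length()) if mask >> i & 1]
        parent = {i: i for i in bits}

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for tmask, a, b in self.triplets:
            if tmask & mask == tmask:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
        comps: dict[int, int] = {}
        for i in bits:
            r = find(i)
            comps[r] = comps.get(r, 0) | (1 << i)
        return sorted(comps.values(), key=lambda m: m & -m)

    def node_cost(self, lmask: int, rmask: int) -> int:
        d = dup_flag(lmask, rmask, self.table)
        if self.cost == "dup":
            return d
        S = self.S
        s_node = self.table.species_of_mask(lmask | rmask)
        s_left = self.table.species_of_mask(lmask)
        s_right = self.table.species_of_mask(rmask)
        e_left = S.depth(s_left) - S.depth(s_node)
        e_right = S.depth(s_right) - S.depth(s_node)
        losses = e_left + e_right if d else (e_left - 1) + (e_right - 1)
        return d + losses

    def solve(self, mask: int) -> float:
        cached = self.memo.get(mask)
        if cached is not None:
            return cached[0]
        if mask & (mask - 1) == 0:  # one gene
            self.memo[mask] = (0, None)
            return 0
        comps = self.components(mask)
        m = len(comps)
        if m == 1:
            # a connected triplet graph on >= 3 genes admits no tree;
            # (a 2-gene subset always yields two singleton components)
            self.memo[mask] = (INFINITY, None)
            return INFINITY
        best: float = INFINITY
        best_split: tuple[int, int] | None = None
        first = comps[0]
        rest = comps[1:]
        for sel in range((1 << (m - 1)) - 1):
            lmask = first
            rmask = 0
            for i, comp in enumerate(rest):
                if sel >> i & 1:
                    lmask |= comp
                else:
                    rmask |= comp
            total = self.solve(lmask)
            if total == INFINITY:
                continue
            r_cost = self.solve(rmask)
            if r_cost == INFINITY:
                continue
            total += r_cost + self.node_cost(lmask, rmask)
            if total < best or (total == best and best_split is not None
                                and min(lmask, rmask) < min(best_split)):
                best = total
                best_split = (lmask, rmask)
        self.memo[mask] = (best, best_split)
        return best

    def reconstruct(self, mask: int) -> Node:
        if mask & (mask - 1) == 0:
            return Node(self.table.genes[mask.bit_length() - 1])
        split = self.memo[mask][1]
        assert split is not None
        lmask, rmask = split
        if (lmask & -lmask) > (rmask & -rmask):
            lmask, rmask = rmask, lmask
        return Node(None, [self.reconstruct(lmask), self.reconstruct(rmask)])


def solve_exact(instance: ProblemInstance, cost: str = "dup", *,
                max_genes: int = DP_GENE_CAP) -> tuple[GeneTree, int]:
    """Optimal binary supertree displaying every input tree, by the subset
    dynamic program.  Returns ``(tree, optimal_cost)``; raises
    :class:`InconsistentError` when no supertree exists."""
    dp = _DP(instance, cost, max_genes)
    full = (1 << len(dp.table.genes)) - 1
    value = dp.solve(full)
    if value == INFINITY:
        raise InconsistentError("the input gene trees are inconsistent")
    return Tree(dp.reconstruct(full)), int(value)


def solve_constrained_root(instance: ProblemInstance,
                           root_bipartition: tuple[Iterable[str], Iterable[str]],
                           cost: str = "dup", *,
                           max_genes: int = DP_GENE_CAP
                           ) -> tuple[GeneTree | None, float]:
    """Optimum over supertrees whose root splits the gene family exactly as
    given; ``(None, inf)`` when no compatible supertree has that root."""
    dp = _DP(instance, cost, max_genes)
    lmask = dp.table.mask_of(root_bipartition[0])
    rmask = dp.table.mask_of(root_bipartition[1])
    full = (1 << len(dp.table.genes)) - 1
    if lmask & rmask or lmask | rmask != full or not lmask or not rmask:
        raise TreeError("root bipartition must split the gene family "
                        "into two nonempty parts")
    # a triplet xy|z with x and y on opposite sides of the root is violated
    for tmask, a, b in dp.triplets:
        pair = (1 << a) | (1 << b)
        if pair & lmask and pair & rmask:
            return None, INFINITY
    value = dp.solve(lmask)
    if value != INFINITY:
        r_val = dp.solve(rmask)
        value = (INFINITY if r_val == INFINITY
                 else value + r_val + dp.node_cost(lmask, rmask))
    if value == INFINITY:
        return None, INFINITY
    left_root, right_root = dp.reconstruct(lmask), dp.reconstruct(rmask)
    if (lmask & -lmask) > (rmask & -rmask):
        left_root, right_root = right_root, left_root
    return Tree(Node(None, [left_root, right_root])), float(value)


# ---------------------------------------------------------------------- #
# brute-force oracle


def enumerate_topologies(leaves: Sequence[str]):
    """Yield every rooted binary topology on ``leaves`` as nested tuples;
    there are (2n-3)!! of them."""
    leaves = list(leaves)
    if not leaves:
        raise TreeError("no leaves to enumerate")

    def rec(k: int):
        if k == 1:
            yield leaves[0]
            return
        for sub in rec(k - 1):
            yield from _insertions(sub, leaves[k - 1])

    yield from rec(len(leaves))


def _insertions(t, leaf: str):
    yield (t, leaf)
    if isinstance(t, tuple):
        left, right = t
        for nl in _insertions(left, leaf):
            yield (nl, right)
        for nr in _insertions(right, leaf):
            yield (left, nr)


def _restrict_tuple(t, keep: frozenset):
    if isinstance(t, str):
        return t if t in keep else None
    left = _restrict_tuple(t[0], keep)
    right = _restrict_tuple(t[1], keep)
    if left is None:
        return right
    if right is None:
        return left
    return (left, right)


def _canon_tuple(t) -> tuple[str, str]:
    # same (min leaf, subtree string) ordering as Tree.canonical
    if isinstance(t, str):
        return (t, t)
    parts = sorted((_canon_tuple(t[0]), _canon_tuple(t[1])))
    return (parts[0][0], "(" + ",".join(p[1] for p in parts) + ")")


def _tuple_to_node(t) -> Node:
    if isinstance(t, str):
        return Node(t)
    return Node(None, [_tuple_to_node(t[0]), _tuple_to_node(t[1])])


def oracle_enumerate(instance: ProblemInstance, cost: str = "dup",
                     constraint: str | None = None, *,
                     max_genes: int = ORACLE_GENE_CAP
                     ) -> tuple[GeneTree, int]:
    """Ground truth by exhaustive enumeration of all rooted binary trees.

    ``constraint='preserve_speciations'`` additionally requires every input
    tree's copy in the supertree to contain only speciation nodes (the
    feasibility notion for independent speciation trees; input leaf sets
    must then be pairwise disjoint).
    """
    if cost not in ("dup", "mutation"):
        raise ValueError(f"cost must be 'dup' or 'mutation', got {cost!r}")
    if constraint not in (None, "preserve_speciations"):
        raise ValueError(f"unknown constraint {constraint!r}")
    genes = list(instance.genes)
    if len(genes) > max_genes:
        raise SizeLimitError(
            f"{len(genes)} genes exceeds the enumeration cap of {max_genes}")
    S = instance.species_tree
    species_node = {g: instance.species_node(g) for g in genes}
    targets = [(t.leaf_labels, t.canonical()) for t in instance.gene_trees]
    constrained = constraint == "preserve_speciations"
    if constrained and not instance.leafsets_disjoint():
        raise TreeError("the speciation-preserving constraint requires "
                        "pairwise disjoint gene-tree leaf sets")
    # A displayed copy is isomorphic to its input tree with the same leaf
    # mapping, hence has the same node labels: the copy is speciation-only
    # exactly when the input tree is.
    if constrained:
        for gtree in instance.gene_trees:
            if (len(gtree.leaf_labels) >= 2 and
                    label_nodes(gtree, S, instance.mapping).duplication_count):
                raise InfeasibleError(
                    "an input tree contains a duplication; no supertree "
                    "can preserve its speciations")

    depth = S.depth
    lca = S.lca_pair

    def tuple_cost(t):
        # returns (species image, duplications, losses)
        if isinstance(t, str):
            return species_node[t], 0, 0
        s_l, d_l, l_l = tuple_cost(t[0])
        s_r, d_r, l_r = tuple_cost(t[1])
        s_x = lca(s_l, s_r)
        dup = 1 if (s_x is s_l or s_x is s_r) else 0
        e = depth(s_l) + depth(s_r) - 2 * depth(s_x)
        losses = e if dup else e - 2
        return s_x, d_l + d_r + dup, l_l + l_r + losses

    best_val: float = INFINITY
    best_key: str | None = None
    best_tree = None
    for cand in enumerate_topologies(genes):
        ok = True
        for leafset, canon in targets:
            sub = _restrict_tuple(cand, leafset)
            if _canon_tuple(sub)[1] != canon:
                ok = False
                break
        if not ok:
            continue
        _, dups, losses = tuple_cost(cand)
        value = dups if cost == "dup" else dups + losses
        key = _canon_tuple(cand)[1]
        if value < best_val or (value == best_val and key < best_key):
            best_val, best_key, best_tree = value, key, cand
    if best_tree is None:
        if constrained:
            raise InfeasibleError("no supertree satisfies the constraint")
        raise InconsistentError("the input gene trees are inconsistent")
    return Tree(_tuple_to_node(best_tree)), int(best_val)
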