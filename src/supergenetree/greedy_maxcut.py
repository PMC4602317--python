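"""Greedy minimum-pre-speciation-duplication heuristic via recursive Max-Cut.

A triplet xy|z whose root, under LCA reconciliation, is a duplication
mapped to the species root is *required*: every supertree displaying it
contains that duplication.  The heuristic builds, over the connected
components of the triplet graph, a weighted *component graph* whose edge
weights count the distinct required-duplication triplets crossing between
two components.  A root bipartition that cuts weight w merges those w
required duplications into the single duplication created at the root, so
the best root is a maximum-weight cut.  The construction recurses into the
two sides; below the root the "required" notion is taken relative to the
species image s(P) of the current gene subset P (the generalization of
"preceding the first speciation" to each subproblem).

Max-Cut is NP-hard; an exact bipartition enumeration is used up to a
configurable vertex count and a seeded multi-restart single-flip local
search beyond it.  No approximation factor is claimed for the overall
heuristic — it is validated against the exact solver as an upper bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np

from .core_trees import (
    GeneSpeciesMap,
    GeneTree,
    Node,
    ProblemInstance,
    SpeciesTree,
    Tree,
    TreeError,
)
from .reconcile import reconciliation_cost
from .triplets_build import (
    Triplet,
    extract_triplets,
    graph_components,
    triplet_graph,
)
from .exact_solver import InconsistentError, SizeLimitError

__all__ = [
    "ComponentGraph",
    "CutResult",
    "component_graph",
    "max_cut",
    "solve_greedy",
    "MAXCUT_EXACT_LIMIT",
]

MAXCUT_EXACT_LIMIT = 20
_FALLBACK_ENUM_LIMIT = 16
_LOCAL_SEARCH_RESTARTS = 32

#: the component graph is a networkx Graph whose vertices are frozensets of
#: genes (the triplet-graph components) and whose edges carry a ``weight``
ComponentGraph = nx.Graph


@dataclass(frozen=True)
class CutResult:
    """A bipartition of component-graph vertices and its crossing weight."""

    side1: tuple[frozenset[str], ...]
    side2: tuple[frozenset[str], ...]
    weight: int

    @property
    def genes1(self) -> frozenset[str]:
        return frozenset().union(*self.side1)

    @property
    def genes2(self) -> frozenset[str]:
        return frozenset().union(*self.side2)


def _species_lca(S: SpeciesTree, smap: GeneSpeciesMap,
                 genes: Iterable[str]) -> Node:
    return S.lca(S.leaf(smap[g]) for g in genes)


def _triplet_required_at(t: Triplet, S: SpeciesTree, smap: GeneSpeciesMap,
                         level_species: Node) -> bool:
    """Root of t maps to ``level_species`` and is a duplication."""
    s_a = S.leaf(smap[t.a])
    s_b = S.leaf(smap[t.b])
    s_z = S.leaf(smap[t.z])
    root_image = S.lca_pair(S.lca_pair(s_a, s_b), s_z)
    if root_image is not level_species:
        return False
    return not S.separated(S.lca_pair(s_a, s_b), s_z)


def component_graph(triplets: Iterable[Triplet], genes: Iterable[str],
                    S: SpeciesTree, smap: GeneSpeciesMap,
                    level_species: Node | None = None) -> ComponentGraph:
    """The weighted graph over triplet-graph components whose edge weights
    count distinct required-duplication triplets with the cherry pair in
    one component and the outgroup gene in the other.

    ``level_species`` defaults to the species image of ``genes`` (at the
    top level this is the species root whenever a required duplication
    exists at all).
    """
    genes = frozenset(genes)
    triplets = set(triplets)
    comps = graph_components(triplet_graph(triplets, genes))
    if level_species is None:
        level_species = _species_lca(S, smap, genes)
    comp_of: dict[str, frozenset[str]] = {}
    for comp in comps:
        for g in comp:
            comp_of[g] = comp
    graph: ComponentGraph = nx.Graph()
    graph.add_nodes_from(comps)
    for t in triplets:
        if not t.genes <= genes:
            continue
        pair_comp = comp_of[t.a]  # a and b share a triplet-graph edge
        out_comp = comp_of[t.z]
        if pair_comp is out_comp:
            continue
        if not _triplet_required_at(t, S, smap, level_species):
            continue
        if graph.has_edge(pair_comp, out_comp):
            graph[pair_comp][out_comp]["weight"] += 1
        else:
            graph.add_edge(pair_comp, out_comp, weight=1)
    return graph


# ---------------------------------------------------------------------- #
# Max-Cut


def _cut_weight(edges, assign: dict) -> int:
    return sum(w for u, v, w in edges if assign[u] != assign[v])


def max_cut(graph: ComponentGraph, mode: str = "exact",
            seed: int | None = None, *,
            exact_limit: int = MAXCUT_EXACT_LIMIT) -> CutResult:
    """Maximum-weight bipartition of the component graph.

    ``mode='exact'`` enumerates all 2^(m-1) - 1 bipartitions (vertex count
    must not exceed ``exact_limit``); ties are broken toward the smallest
    canonical side-assignment mask.  ``mode='local_search'`` runs seeded
    multi-restart single-flip hill climbing and is deterministic for a
    fixed seed.
    """
    vertices = sorted(graph.nodes, key=lambda c: min(c))
    m = len(vertices)
    if m < 2:
        raise TreeError("max_cut needs at least two vertices")
    vidx = {v: i for i, v in enumerate(vertices)}
    edges = [(vidx[u], vidx[v], int(d["weight"]))
             for u, v, d in graph.edges(data=True)]

    if mode == "exact":
        if m > exact_limit:
            raise SizeLimitError(
                f"{m} component-graph vertices exceed the exact Max-Cut "
                f"limit of {exact_limit}; use mode='local_search'")
        # vertex 0 pinned to side 1; mask bits select side-2 members
        n_masks = (1 << (m - 1)) - 1
        masks = np.arange(1, n_masks + 1, dtype=np.int64)
        weights = np.zeros(n_masks, dtype=np.int64)
        for i, j, w in edges:
            bi = (masks >> (i - 1)) & 1 if i else np.zeros_like(masks)
            bj = (masks >> (j - 1)) & 1 if j else np.zeros_like(masks)
            weights += w * (bi != bj)
        best_pos = int(np.argmax(weights))  # first occurrence: smallest mask
        best_mask = int(masks[best_pos])
        weight = int(weights[best_pos])
        side2 = tuple(vertices[i] for i in range(1, m)
                      if best_mask >> (i - 1) & 1)
        side1 = tuple(v for v in vertices if v not in side2)
        return CutResult(side1, side2, weight)

    if mode == "local_search":
        rng = np.random.default_rng(seed)
        wmat = np.zeros((m, m), dtype=np.int64)
        for i, j, w in edges:
            wmat[i, j] = wmat[j, i] = w
        best_assign: np.ndarray | None = None
        best_weight = -1
        best_key: tuple | None = None
        for _ in range(_LOCAL_SEARCH_RESTARTS):
            assign = rng.integers(0, 2, size=m)
            assign[0] = 0
            if assign.sum() == 0:
                assign[-1] = 1
            improved = True
            while improved:
                improved = False
                for v in range(m):
                    flipped = assign.copy()
                    flipped[v] ^= 1
                    if 0 < flipped.sum() < m:
                        gain = (_assign_weight(wmat, flipped)
                                - _assign_weight(wmat, assign))
                        if gain > 0:
                            assign = flipped
                            improved = True
            if assign[0] == 1:
                assign = 1 - assign
            weight = _assign_weight(wmat, assign)
            key = tuple(assign.tolist())
            if weight > best_weight or (weight == best_weight and key < best_key):
                best_weight, best_assign, best_key = weight, assign, key
        assert best_assign is not None
        side1 = tuple(v for i, v in enumerate(vertices) if best_assign[i] == 0)
        side2 = tuple(v for i, v in enumerate(vertices) if best_assign[i] == 1)
        return CutResult(side1, side2, int(best_weight))

    raise ValueError(f"mode must be 'exact' or 'local_search', got {mode!r}")


def _assign_weight(wmat: np.ndarray, assign: np.ndarray) -> int:
    diff = assign[:, None] != assign[None, :]
    return int((wmat * diff).sum()) // 2


# ---------------------------------------------------------------------- #
# the recursive heuristic


def _fallback_bipartition(comps: list[frozenset[str]], S: SpeciesTree,
                          smap: GeneSpeciesMap
                          ) -> tuple[frozenset[str], frozenset[str]]:
    """Bipartition of components when no required duplication crosses them:
    minimize the duplication flag, then imbalance, then canonical order —
    pushing duplications down the tree."""
    m = len(comps)
    comp_lca = [_species_lca(S, smap, c) for c in comps]

    def score(sel: int) -> tuple:
        left_nodes = [comp_lca[i] for i in range(m) if sel >> i & 1]
        right_nodes = [comp_lca[i] for i in range(m) if not sel >> i & 1]
        s_left = S.lca(left_nodes)
        s_right = S.lca(right_nodes)
        d = 0 if S.separated(s_left, s_right) else 1
        n_left = sum(len(comps[i]) for i in range(m) if sel >> i & 1)
        n_right = sum(len(c) for c in comps) - n_left
        return (d, abs(n_left - n_right), sel)

    if m <= _FALLBACK_ENUM_LIMIT:
        # component 0 pinned to the left side
        best_sel = min((1 | (rest << 1) for rest in range(1 << (m - 1))
                        if 1 | (rest << 1) != (1 << m) - 1), key=score)
    else:
        # large graphs: split by which child of s(P) each component's
        # species image descends into
        level = S.lca(comp_lca)
        left_child = level.children[0] if level.children else None
        sel = 0
        for i, node in enumerate(comp_lca):
            if left_child is not None and S.is_ancestor(left_child, node):
                sel |= 1 << i
        if sel == 0 or sel == (1 << m) - 1:
            sel = 1  # degenerate: isolate the first component
        best_sel = sel
    left = frozenset().union(*(comps[i] for i in range(m) if best_sel >> i & 1))
    right = frozenset().union(*(comps[i] for i in range(m)
                                if not best_sel >> i & 1))
    return left, right


def solve_greedy(instance: ProblemInstance, seed: int | None = 0,
                 maxcut_mode: str = "exact") -> tuple[GeneTree, int]:
    """Build a supertree by recursive Max-Cut over required duplications.

    Returns the tree and its duplication cost (by LCA reconciliation).
    Deterministic for a fixed seed; raises :class:`InconsistentError` for
    incompatible inputs.
    """
    S = instance.species_tree
    smap = instance.mapping
    triplets = extract_triplets(instance.gene_trees)

    def grow(genes: frozenset[str]) -> Node:
        ordered = sorted(genes)
        if len(ordered) == 1:
            return Node(ordered[0])
        if len(ordered) == 2:
            return Node(None, [Node(ordered[0]), Node(ordered[1])])
        comps = graph_components(triplet_graph(triplets, genes))
        if len(comps) == 1:
            raise InconsistentError("the input gene trees are inconsistent")
        level = _species_lca(S, smap, genes)
        cgraph = component_graph(triplets, genes, S, smap, level)
        if cgraph.number_of_edges():
            mode = maxcut_mode
            if mode == "exact" and cgraph.number_of_nodes() > MAXCUT_EXACT_LIMIT:
                mode = "local_search"
            cut = max_cut(cgraph, mode=mode, seed=seed)
            left, right = cut.genes1, cut.genes2
        else:
            left, right = _fallback_bipartition(comps, S, smap)
        if min(left) > min(right):
            left, right = right, left
        return Node(None, [grow(left), grow(right)])

    tree = Tree(grow(frozenset(instance.genes)))
    return tree, reconciliation_cost(tree, S, smap, "dup")
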