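"""Rooted triplets, the triplet graph, and the BUILD compatibility test.

A binary tree on three leaves {x, y, z} is written ``xy|z`` when x and y
are closer to each other than to z.  The triplet set tr(G) of a collection
of binary gene trees collects, for every tree and every 3-subset of its
leaves, the induced triplet.  The triplet graph on a gene set V has an edge
xy whenever some triplet xy|z has all three genes inside V; the BUILD
algorithm of Aho et al. recursively decomposes this graph's connected
components, reporting inconsistency when a graph on >= 3 vertices stays
connected.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, NamedTuple

import networkx as nx

from .core_trees import GeneTree, Node, ProblemInstance, Tree, TreeError

__all__ = [
    "Triplet",
    "extract_triplets",
    "tree_triplets",
    "triplet_graph",
    "graph_components",
    "build",
    "is_consistent",
]


class Triplet(NamedTuple):
    """The rooted triplet ab|z, stored with a < b so xy|z == yx|z."""

    a: str
    b: str
    z: str

    @classmethod
    def of(cls, x: str, y: str, z: str) -> "Triplet":
        if x == y or x == z or y == z:
            raise TreeError("triplet with a repeated gene")
        return cls(min(x, y), max(x, y), z)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset((self.a, self.b, self.z))

    def as_tree(self) -> GeneTree:
        return Tree(Node(None, [Node(None, [Node(self.a), Node(self.b)]),
                                Node(self.z)]))


def tree_triplets(tree: GeneTree) -> set[Triplet]:
    """All C(n,3) triplets induced by one binary tree."""
    leaves = tree.leaves
    lca_depth: dict[tuple[int, int], int] = {}
    for u, v in combinations(leaves, 2):
        key = (id(u), id(v)) if id(u) <= id(v) else (id(v), id(u))
        lca_depth[key] = tree.depth(tree.lca_pair(u, v))

    def d(u: Node, v: Node) -> int:
        key = (id(u), id(v)) if id(u) <= id(v) else (id(v), id(u))
        return lca_depth[key]

    out: set[Triplet] = set()
    for x, y, z in combinations(leaves, 3):
        dxy, dxz, dyz = d(x, y), d(x, z), d(y, z)
        # in a binary tree exactly one pairwise lca is strictly deepest
        if dxy > dxz and dxy > dyz:
            out.add(Triplet.of(x.label, y.label, z.label))
        elif dxz > dxy and dxz > dyz:
            out.add(Triplet.of(x.label, z.label, y.label))
        elif dyz > dxy and dyz > dxz:
            out.add(Triplet.of(y.label, z.label, x.label))
        else:  # pragma: no cover - impossible for binary trees
            raise TreeError("unresolved triple in a binary tree")
    return out


def extract_triplets(gene_trees: Iterable[GeneTree]) -> set[Triplet]:
    """tr(G): the union of the triplets of every input tree, deduplicated."""
    out: set[Triplet] = set()
    for tree in gene_trees:
        out |= tree_triplets(tree)
    return out


def triplet_graph(triplets: Iterable[Triplet],
                  genes: Iterable[str]) -> nx.Graph:
    """The graph on ``genes`` with an edge ab for every triplet ab|z whose
    three genes all lie inside ``genes``."""
    vertices = set(genes)
    g = nx.Graph()
    g.add_nodes_from(vertices)
    for t in triplets:
        if t.a in vertices and t.b in vertices and t.z in vertices:
            g.add_edge(t.a, t.b)
    return g


def graph_components(g: nx.Graph) -> list[frozenset[str]]:
    """Connected components ordered by their smallest gene label, for
    reproducible child order in BUILD trees and solver backtracking."""
    comps = [frozenset(c) for c in nx.connected_components(g)]
    comps.sort(key=min)
    return comps


def build(triplets: Iterable[Triplet],
          genes: Iterable[str]) -> Tree | None:
    """The BUILD algorithm: a (possibly polytomous) tree displaying every
    triplet restricted to ``genes``, or ``None`` when the set is
    inconsistent."""
    triplets = set(triplets)

    def rec(vertices: frozenset[str]) -> Node | None:
        ordered = sorted(vertices)
        if len(ordered) == 1:
            return Node(ordered[0])
        if len(ordered) == 2:
            return Node(None, [Node(ordered[0]), Node(ordered[1])])
        comps = graph_components(triplet_graph(triplets, vertices))
        if len(comps) == 1:
            return None
        children = []
        for comp in comps:
            child = rec(comp)
            if child is None:
                return None
            children.append(child)
        return Node(None, children)

    root = rec(frozenset(genes))
    return Tree(root) if root is not None else None


def is_consistent(instance: ProblemInstance) -> bool:
    """Does some supertree display every input tree?  Polynomial-time BUILD
    verdict on tr(G)."""
    tr = extract_triplets(instance.gene_trees)
    return build(tr, instance.genes) is not None
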