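"""Rooted leaf-labeled trees: the substrate for supergenetree construction.

Everything downstream (reconciliation, triplet extraction, the exact DP and
the greedy heuristic) manipulates the same rooted-tree container defined
here.  Trees are rooted, leaf-labeled, and — for all *input* trees — binary;
the BUILD algorithm may produce polytomies, so the container itself allows
arbitrary arity.

Conventions
-----------
* A species tree ``S`` is a binary tree whose leaf labels are the species
  set Sigma.  A gene tree is a binary tree whose leaves are gene
  identifiers; a :class:`GeneSpeciesMap` sends each gene to a species.
* ``restrict(T, L')`` prunes the tree to the leaf subset ``L'`` and
  contracts every suppressed degree-2 node, rooting the result at the
  lowest common ancestor of ``L'``.
* ``T`` *displays* ``T'`` iff ``restrict(T, L(T'))`` is isomorphic to
  ``T'`` as a rooted leaf-labeled tree.

LCA queries are answered in constant time after an Euler-tour / sparse-table
preprocessing, which the subset dynamic program relies on.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "TreeError",
    "NewickError",
    "ArityError",
    "Node",
    "Tree",
    "SpeciesTree",
    "GeneTree",
    "GeneSpeciesMap",
    "ProblemInstance",
    "read_newick",
    "write_newick",
    "restrict",
    "displays",
    "load_instance",
    "load_instance_files",
]


class TreeError(ValueError):
    """Base class for malformed trees or invalid tree operations."""


class NewickError(TreeError):
    """Raised when a Newick string cannot be parsed."""


class ArityError(TreeError):
    """Raised when a tree required to be binary has a polytomy."""


class Node:
    """A node of a rooted tree. Leaves carry a label; internal nodes may not."""

    __slots__ = ("label", "parent", "children")

    def __init__(self, label: str | None = None,
                 children: Iterable["Node"] = ()) -> None:
        self.label = label
        self.parent: Node | None = None
        self.children: list[Node] = []
        for child in children:
            self.add_child(child)

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        stack: list[tuple[Node, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.label!r}>" if self.is_leaf else f"<Node {len(self.children)} children>"


class Tree:
    """A rooted leaf-labeled tree with an O(1) LCA index.

    The tree is treated as immutable once constructed: the Euler-tour index
    is built in ``__init__`` and is not invalidated by later mutation of the
    node structure.  Build a new ``Tree`` instead of mutating one.
    """

    def __init__(self, root: Node) -> None:
        self.root = root
        self._depth: dict[int, int] = {}
        self._first: dict[int, int] = {}
        self._leaves: list[Node] = []
        self._leaf_by_label: dict[str, Node] = {}
        self._nodes: set[int] = set()
        tour_nodes: list[Node] = []
        tour_depth: list[int] = []

        order: list[tuple[Node, int]] = [(root, 0)]
        self._depth[id(root)] = 0
        while order:
            node, depth = order.pop()
            self._nodes.add(id(node))
            self._depth[id(node)] = depth
            if node.is_leaf:
                if node.label is None:
                    raise TreeError("leaf without a label")
                if node.label in self._leaf_by_label:
                    raise TreeError(f"duplicate leaf label {node.label!r}")
                self._leaf_by_label[node.label] = node
                self._leaves.append(node)
            for child in node.children:
                order.append((child, depth + 1))
        # second pass for the Euler tour proper (recursive shape, iterative code)
        stack2: list[tuple[Node, int]] = [(root, 0)]
        while stack2:
            node, child_idx = stack2.pop()
            if child_idx == 0:
                self._first.setdefault(id(node), len(tour_nodes))
            tour_nodes.append(node)
            tour_depth.append(self._depth[id(node)])
            if child_idx < len(node.children):
                stack2.append((node, child_idx + 1))
                stack2.append((node.children[child_idx], 0))
        # leaves collected above are in reversed DFS order; fix to left-to-right
        self._leaves = [n for n in tour_nodes if n.is_leaf]
        seen: set[int] = set()
        self._leaves = [n for n in self._leaves
                        if not (id(n) in seen or seen.add(id(n)))]

        self._tour_nodes = tour_nodes
        depth_arr = np.asarray(tour_depth, dtype=np.int64)
        m = len(depth_arr)
        levels = max(1, m.bit_length())
        sparse = np.empty((levels, m), dtype=np.int64)
        sparse[0] = np.arange(m)
        for k in range(1, levels):
            half = 1 << (k - 1)
            span = m - (1 << k) + 1
            if span <= 0:
                sparse[k] = sparse[k - 1]
                continue
            left = sparse[k - 1, :span]
            right = sparse[k - 1, half:half + span]
            take_right = depth_arr[right] < depth_arr[left]
            sparse[k, :span] = np.where(take_right, right, left)
        self._sparse = sparse
        self._tour_depth = depth_arr

    # ------------------------------------------------------------------ #
    # basic queries

    @property
    def leaves(self) -> list[Node]:
        return list(self._leaves)

    @property
    def leaf_labels(self) -> frozenset[str]:
        return frozenset(self._leaf_by_label)

    def leaf(self, label: str) -> Node:
        try:
            return self._leaf_by_label[label]
        except KeyError:
            raise TreeError(f"unknown leaf label {label!r}") from None

    def depth(self, node: Node) -> int:
        """Edge count from the root."""
        try:
            return self._depth[id(node)]
        except KeyError:
            raise TreeError("node not in this tree") from None

    def __contains__(self, node: Node) -> bool:
        return id(node) in self._nodes

    @property
    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.root.preorder()
                   if not n.is_leaf)

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.root.postorder() if not n.is_leaf]

    # ------------------------------------------------------------------ #
    # LCA

    def lca_pair(self, u: Node, v: Node) -> Node:
        if id(u) not in self._nodes or id(v) not in self._nodes:
            raise TreeError("node not in this tree")
        i, j = self._first[id(u)], self._first[id(v)]
        if i > j:
            i, j = j, i
        k = (j - i + 1).bit_length() - 1
        a = self._sparse[k, i]
        b = self._sparse[k, j - (1 << k) + 1]
        best = a if self._tour_depth[a] <= self._tour_depth[b] else b
        return self._tour_nodes[best]

    def lca(self, nodes: Iterable[Node]) -> Node:
        it = iter(nodes)
        try:
            acc = next(it)
        except StopIteration:
            raise TreeError("lca of an empty node set") from None
        for node in it:
            acc = self.lca_pair(acc, node)
        return acc

    def lca_labels(self, labels: Iterable[str]) -> Node:
        return self.lca(self.leaf(l) for l in labels)

    def is_ancestor(self, u: Node, v: Node) -> bool:
        """True iff ``u`` is an ancestor-or-equal of ``v``."""
        return self.lca_pair(u, v) is u

    def separated(self, u: Node, v: Node) -> bool:
        """Neither node is an ancestor-or-equal of the other."""
        a = self.lca_pair(u, v)
        return a is not u and a is not v

    # ------------------------------------------------------------------ #
    # structure operations

    def copy(self) -> "Tree":
        return Tree(_copy_node(self.root))

    def canonical(self) -> str:
        """Canonical form: children sorted by (min leaf label, subtree string).

        Two rooted leaf-labeled trees are isomorphic iff their canonical
        strings are equal.
        """
        return _canonical(self.root)[1]

    def isomorphic(self, other: "Tree") -> bool:
        return self.canonical() == other.canonical()

    def newick(self, internal_labels: Mapping[int, str] | None = None) -> str:
        return write_newick(self, internal_labels=internal_labels)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree({self.newick()!r})"


# alias types: species and gene trees share the container
SpeciesTree = Tree
GeneTree = Tree


def _copy_node(node: Node) -> Node:
    return Node(node.label, (_copy_node(c) for c in node.children))


def _canonical(node: Node) -> tuple[str, str]:
    if node.is_leaf:
        return (node.label, node.label)  # type: ignore[return-value]
    parts = sorted(_canonical(c) for c in node.children)
    return (parts[0][0], "(" + ",".join(p[1] for p in parts) + ")")


# ---------------------------------------------------------------------- #
# Newick I/O


def read_newick(text: str, kind: str = "gene", *,
                require_binary: bool = True) -> Tree:
    """Parse a rooted Newick string into a :class:`Tree`.

    ``kind`` is ``"species"`` or ``"gene"``; both produce the same container
    and both reject polytomies when ``require_binary`` (the default — input
    trees are required to be binary; branch lengths are parsed and ignored).
    """
    if kind not in ("gene", "species"):
        raise ValueError(f"kind must be 'gene' or 'species', got {kind!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickError(f"malformed newick: {exc}") from exc

    def convert(dnode) -> Node:
        children = dnode.child_nodes()
        if not children:
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            if label is None:
                raise NewickError("leaf without a label")
            return Node(str(label))
        return Node(None, (convert(c) for c in children))

    root = convert(dtree.seed_node)
    if root.is_leaf and root.label is None:
        raise NewickError("empty newick string")
    tree = Tree(root)
    if require_binary:
        for node in root.preorder():
            if node.children and len(node.children) != 2:
                raise ArityError(
                    f"non-binary internal node with {len(node.children)} "
                    f"children (polytomies are rejected for input trees)")
    return tree


_NEWICK_UNSAFE = set("(),;:[]' \t\n")


def _newick_label(label: str) -> str:
    if any(ch in _NEWICK_UNSAFE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree,
                 internal_labels: Mapping[int, str] | None = None) -> str:
    """Serialize in child order as stored; optional internal node labels
    (keyed by ``id(node)``) are written after the closing parenthesis."""

    def rec(node: Node) -> str:
        if node.is_leaf:
            return _newick_label(node.label)  # type: ignore[arg-type]
        inner = ",".join(rec(c) for c in node.children)
        tag = ""
        if internal_labels is not None:
            tag = internal_labels.get(id(node), "")
        return f"({inner}){tag}"

    return rec(tree.root) + ";"


# ---------------------------------------------------------------------- #
# restriction and display


def restrict(tree: Tree, labels: Iterable[str]) -> Tree:
    """The restriction of ``tree`` to the leaf subset ``labels``.

    Leaves outside the subset are removed and every suppressed degree-2
    node is contracted; the result is rooted at the LCA of the kept leaves.
    """
    keep = frozenset(labels)
    if not keep:
        raise TreeError("cannot restrict to an empty leaf set")
    missing = keep - tree.leaf_labels
    if missing:
        raise TreeError(f"labels not in tree: {sorted(missing)}")

    def rec(node: Node) -> Node | None:
        if node.is_leaf:
            return Node(node.label) if node.label in keep else None
        kept = [r for r in (rec(c) for c in node.children) if r is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        return Node(None, kept)

    root = rec(tree.root)
    assert root is not None
    return Tree(root)


def displays(tree: Tree, sub: Tree) -> bool:
    """True iff ``tree`` restricted to ``sub``'s leaves is isomorphic to ``sub``."""
    if not sub.leaf_labels <= tree.leaf_labels:
        raise TreeError("leaf set of the candidate subtree is not contained "
                        "in the displaying tree")
    return restrict(tree, sub.leaf_labels).canonical() == sub.canonical()


# ---------------------------------------------------------------------- #
# gene -> species mapping


class GeneSpeciesMap(Mapping):
    """A total mapping from gene identifiers to species identifiers."""

    def __init__(self, mapping: Mapping[str, str]) -> None:
        self._map = dict(mapping)

    def __getitem__(self, gene: str) -> str:
        return self._map[gene]

    def __iter__(self):
        return iter(self._map)

    def __len__(self) -> int:
        return len(self._map)

    @classmethod
    def from_tsv(cls, source: str | os.PathLike) -> "GeneSpeciesMap":
        """Read a two-column TSV ``gene<TAB>species``; a header line
        ``gene\\tspecies`` is recognized and skipped."""
        with open(source) as fh:
            text = fh.read()
        return cls.from_tsv_text(text)

    @classmethod
    def from_tsv_text(cls, text: str) -> "GeneSpeciesMap":
        pairs: dict[str, str] = {}
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise TreeError(f"mapping line {lineno}: expected two "
                                f"tab-separated columns, got {raw!r}")
            gene, species = fields
            if lineno == 1 and (gene, species) == ("gene", "species"):
                continue
            if gene in pairs and pairs[gene] != species:
                raise TreeError(f"gene {gene!r} mapped to two species")
            pairs[gene] = species
        return cls(pairs)

    @classmethod
    def from_labels(cls, genes: Iterable[str], sep: str = "_") -> "GeneSpeciesMap":
        """Fallback convention: the species id is the gene label's prefix
        before the first ``sep`` (e.g. ``human_BRCA2 -> human``)."""
        pairs = {}
        for gene in genes:
            if sep not in gene:
                raise TreeError(f"gene {gene!r} has no {sep!r}-separated "
                                "species prefix")
            pairs[gene] = gene.split(sep, 1)[0]
        return cls(pairs)

    def to_tsv_text(self) -> str:
        lines = ["gene\tspecies"]
        lines += [f"{g}\t{s}" for g, s in sorted(self._map.items())]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------- #
# problem instances


@dataclass
class ProblemInstance:
    """A full supergenetree input: species tree S, gene trees G_1..G_k on
    subsets of the gene family, and the gene-to-species map.

    Overlapping gene-tree leaf sets are the normal case; pass
    ``require_disjoint=True`` for inputs that must satisfy the
    independent-speciation-trees precondition (each gene in at most one tree).
    """

    species_tree: SpeciesTree
    gene_trees: list[GeneTree]
    mapping: GeneSpeciesMap
    require_disjoint: bool = False
    genes: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if not self.gene_trees:
            raise TreeError("instance needs at least one gene tree")
        all_genes: set[str] = set()
        species_leaves = self.species_tree.leaf_labels
        for gtree in self.gene_trees:
            labels = gtree.leaf_labels
            if not labels:
                raise TreeError("empty gene tree")
            if self.require_disjoint and all_genes & labels:
                raise TreeError("gene tree leaf sets overlap but the "
                                "instance requires disjoint leaf sets")
            all_genes |= labels
        for gene in sorted(all_genes):
            if gene not in self.mapping:
                raise TreeError(f"gene {gene!r} has no species mapping")
            sp = self.mapping[gene]
            if sp not in species_leaves:
                raise TreeError(f"gene {gene!r} maps to species {sp!r} "
                                "absent from the species tree")
        self.genes = tuple(sorted(all_genes))

    @property
    def k(self) -> int:
        return len(self.gene_trees)

    def species_node(self, gene: str) -> Node:
        return self.species_tree.leaf(self.mapping[gene])

    def leafsets_disjoint(self) -> bool:
        seen: set[str] = set()
        for gtree in self.gene_trees:
            labels = gtree.leaf_labels
            if seen & labels:
                return False
            seen |= labels
        return True


def load_instance(species_newick: str,
                  gene_newicks: Iterable[str],
                  mapping: Mapping[str, str] | None = None,
                  *,
                  species_prefix_sep: str | None = None,
                  require_disjoint: bool = False) -> ProblemInstance:
    """Build a validated :class:`ProblemInstance` from Newick strings.

    ``mapping`` may be any gene->species mapping; if omitted,
    ``species_prefix_sep`` enables the label-prefix convention instead.
    """
    species = read_newick(species_newick, kind="species")
    gene_trees = [read_newick(nwk, kind="gene") for nwk in gene_newicks]
    if not gene_trees:
        raise TreeError("instance needs at least one gene tree")
    genes = sorted(set().union(*(t.leaf_labels for t in gene_trees)))
    if mapping is None:
        if species_prefix_sep is None:
            raise TreeError("either a mapping or species_prefix_sep is required")
        smap = GeneSpeciesMap.from_labels(genes, sep=species_prefix_sep)
    elif isinstance(mapping, GeneSpeciesMap):
        smap = mapping
    else:
        smap = GeneSpeciesMap(mapping)
    return ProblemInstance(species, gene_trees, smap,
                           require_disjoint=require_disjoint)


def load_instance_files(species_path: str | os.PathLike,
                        genes_path: str | os.PathLike,
                        map_path: str | os.PathLike | None = None,
                        *,
                        species_prefix_sep: str | None = None,
                        require_disjoint: bool = False) -> ProblemInstance:
    """File-based loader: one species Newick, one gene-tree Newick per line,
    and an optional two-column mapping TSV."""
    with open(species_path) as fh:
        species_newick = fh.read().strip()
    with open(genes_path) as fh:
        gene_newicks = [line.strip() for line in fh if line.strip()]
    mapping = GeneSpeciesMap.from_tsv(map_path) if map_path is not None else None
    return load_instance(species_newick, gene_newicks, mapping,
                         species_prefix_sep=species_prefix_sep,
                         require_disjoint=require_disjoint)
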