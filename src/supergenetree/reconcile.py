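"""LCA-mapping reconciliation of a gene tree against a species tree.

Each internal gene-tree node x is mapped to s(x), the species-tree LCA of
the species of the genes below it.  A node is a *speciation* when the
images of its two children are separated in S (neither ancestral to the
other) and a *duplication* otherwise; a duplication mapped to the species
root is a *pre-speciation* duplication.  The duplication cost is the number
of duplication nodes; the mutation (reconciliation) cost adds the minimum
number of losses implied by the mapping, counted edge-by-edge with the
standard depth-difference formula: an edge from x down to child c crosses
``e = depth(s(c)) - depth(s(x))`` species-tree edges and implies ``e - 1``
losses when x is a speciation and ``e`` when x is a duplication.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_trees import (
    GeneSpeciesMap,
    GeneTree,
    Node,
    ProblemInstance,
    SpeciesTree,
    TreeError,
    restrict,
)

__all__ = [
    "Reconciliation",
    "SPECIATION",
    "DUPLICATION",
    "map_nodes",
    "label_nodes",
    "count_losses",
    "reconcile",
    "reconciliation_cost",
    "required_duplication",
    "preserves_speciations",
]

SPECIATION = "speciation"
DUPLICATION = "duplication"


@dataclass
class Reconciliation:
    """The LCA reconciliation of one gene tree with the species tree."""

    gene_tree: GeneTree
    species_tree: SpeciesTree
    #: gene-tree node -> species-tree node, keyed by id(node)
    mapping: dict[int, Node]
    #: internal gene-tree node -> SPECIATION | DUPLICATION, keyed by id(node)
    labels: dict[int, str]
    #: ids of duplication nodes mapped to the species root
    pre_speciation: frozenset[int]
    duplication_count: int
    loss_count: int

    @property
    def mutation_cost(self) -> int:
        return self.duplication_count + self.loss_count

    @property
    def speciation_count(self) -> int:
        return sum(1 for lab in self.labels.values() if lab == SPECIATION)

    def label_of(self, node: Node) -> str:
        return self.labels[id(node)]

    def annotated_newick(self) -> str:
        """Newick with internal nodes tagged D (duplication) / S (speciation)."""
        tags = {nid: ("D" if lab == DUPLICATION else "S")
                for nid, lab in self.labels.items()}
        return self.gene_tree.newick(internal_labels=tags)


def map_nodes(T: GeneTree, S: SpeciesTree,
              smap: GeneSpeciesMap) -> dict[int, Node]:
    """Bottom-up LCA mapping s(x) for every node of ``T`` (keyed by id)."""
    mapping: dict[int, Node] = {}
    for node in T.root.postorder():
        if node.is_leaf:
            gene = node.label
            if gene not in smap:
                raise TreeError(f"gene {gene!r} has no species mapping")
            mapping[id(node)] = S.leaf(smap[gene])
        else:
            images = [mapping[id(c)] for c in node.children]
            mapping[id(node)] = S.lca(images)
    return mapping


def label_nodes(T: GeneTree, S: SpeciesTree,
                smap: GeneSpeciesMap) -> Reconciliation:
    """Full reconciliation: mapping, speciation/duplication labels, losses."""
    mapping = map_nodes(T, S, smap)
    labels: dict[int, str] = {}
    pre_spec: set[int] = set()
    dup_count = 0
    loss_count = 0
    for node in T.root.postorder():
        if node.is_leaf:
            continue
        if len(node.children) != 2:
            raise TreeError("reconciliation requires a binary gene tree")
        left, right = node.children
        s_left = mapping[id(left)]
        s_right = mapping[id(right)]
        s_node = mapping[id(node)]
        if S.separated(s_left, s_right):
            labels[id(node)] = SPECIATION
        else:
            labels[id(node)] = DUPLICATION
            dup_count += 1
            if s_node is S.root:
                pre_spec.add(id(node))
        e_left = S.depth(s_left) - S.depth(s_node)
        e_right = S.depth(s_right) - S.depth(s_node)
        if labels[id(node)] == SPECIATION:
            loss_count += (e_left - 1) + (e_right - 1)
        else:
            loss_count += e_left + e_right
    return Reconciliation(
        gene_tree=T,
        species_tree=S,
        mapping=mapping,
        labels=labels,
        pre_speciation=frozenset(pre_spec),
        duplication_count=dup_count,
        loss_count=loss_count,
    )


# `reconcile` is the natural name for the one-shot computation
reconcile = label_nodes


def count_losses(T: GeneTree, S: SpeciesTree, smap: GeneSpeciesMap) -> int:
    return label_nodes(T, S, smap).loss_count


def reconciliation_cost(T: GeneTree, S: SpeciesTree, smap: GeneSpeciesMap,
                        cost: str = "dup") -> int:
    """``cost='dup'``: number of duplications; ``cost='mutation'``:
    duplications plus implied losses."""
    rec = label_nodes(T, S, smap)
    if cost == "dup":
        return rec.duplication_count
    if cost == "mutation":
        return rec.mutation_cost
    raise ValueError(f"cost must be 'dup' or 'mutation', got {cost!r}")


def required_duplication(triplet: GeneTree, S: SpeciesTree,
                         smap: GeneSpeciesMap) -> bool:
    """Is the root of this 3-leaf tree a duplication mapped to r(S)?

    Such a triplet forces a pre-speciation duplication in *every* supertree
    displaying it, which is why the greedy heuristic counts them.
    """
    if len(triplet.leaf_labels) != 3:
        raise TreeError("required_duplication expects a 3-leaf tree")
    rec = label_nodes(triplet, S, smap)
    root = triplet.root
    return (rec.label_of(root) == DUPLICATION
            and rec.mapping[id(root)] is S.root)


def preserves_speciations(T: GeneTree, instance: ProblemInstance) -> bool:
    """Does ``T`` display every input tree with all its copies' internal
    nodes labeled speciation?

    This is the feasibility notion for instances of independent speciation
    trees; it requires the input leaf sets to be pairwise disjoint.
    """
    if not instance.leafsets_disjoint():
        raise TreeError("preserves_speciations requires pairwise disjoint "
                        "gene-tree leaf sets")
    S = instance.species_tree
    for gtree in instance.gene_trees:
        labels = gtree.leaf_labels
        if not labels <= T.leaf_labels:
            raise TreeError("supertree does not contain all input genes")
        copy = restrict(T, labels)
        if not copy.isomorphic(gtree):
            return False
        if len(labels) >= 2:
            rec = label_nodes(copy, S, instance.mapping)
            if rec.duplication_count:
                return False
    return True
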