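"""Synthetic supergenetree instances with known ground truth.

Two generators live here:

* ``simulate_instance`` grows a full gene tree T* inside a random species
  tree under a simple birth (duplication) / death (loss) model, then cuts
  leaf subsets out of T* and hands their restrictions to the solvers.
  Because every input tree is a restriction of one common tree, the
  instance is consistent by construction and T* restricted to the sampled
  gene family is a feasible supertree — an upper bound on the optimum.

* ``coloring_reduction`` encodes an undirected graph H as a supergenetree
  instance with two genes per vertex and four triplet trees per edge, such
  that H is k-colorable iff some compatible supertree has at most k - 1
  duplications (all of them pre-speciation).  The chromatic number of small
  graphs is analytically known, which makes these instances exact
  correctness fixtures for the solvers.
"""

from __future__ import annotations

import json
import os
import string
from dataclasses import dataclass
from pathlib import Path

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
    restrict,
)
from .reconcile import label_nodes

__all__ = [
    "SimulationConfig",
    "SimulatedInstance",
    "random_species_tree",
    "simulate_instance",
    "coloring_reduction",
    "write_instance",
]


@dataclass
class SimulationConfig:
    """Knobs of the generative model.

    Defaults describe a modest gene family: 8 species, one starting gene
    lineage, a 0.2 chance that a lineage duplicates in place before its
    next speciation, a 0.1 chance that a lineage is lost along each species
    branch, and three partial trees of 3-6 genes each cut from the result.
    """

    n_species: int = 8
    dup_prob: float = 0.2
    loss_prob: float = 0.1
    k: int = 3
    min_size: int = 3
    max_size: int = 6
    speciation_only: bool = False
    disjoint: bool = False
    species_shape: str = "yule"  # or "uniform"
    seed: int = 0
    max_genes: int = 64
    max_retries: int = 200

    def __post_init__(self) -> None:
        if not 0.0 <= self.dup_prob <= 1.0 or not 0.0 <= self.loss_prob <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_species < 2 or self.k < 1 or self.min_size < 1:
            raise ValueError("sizes must be positive (and >= 2 species)")
        if self.max_size < self.min_size:
            raise ValueError("max_size < min_size")
        if self.species_shape not in ("yule", "uniform"):
            raise ValueError("species_shape must be 'yule' or 'uniform'")


@dataclass
class SimulatedInstance:
    """A problem instance plus its generating tree and true costs.

    ``true_tree`` is the full gene tree restricted to the genes that made
    it into the instance; its LCA-reconciliation duplication and loss
    counts are the recorded truth (the raw event count is not recoverable
    once losses prune lineages).
    """

    instance: ProblemInstance
    true_tree: GeneTree
    true_duplications: int
    true_losses: int
    config: SimulationConfig


def _species_names(n: int) -> list[str]:
    if n <= 26:
        return list(string.ascii_lowercase[:n])
    return [f"s{i:03d}" for i in range(n)]


def random_species_tree(n_species: int, rng: np.random.Generator,
                        shape: str = "yule") -> SpeciesTree:
    """A random binary species tree.

    ``yule``: split a random pending leaf repeatedly (pure-birth shapes);
    ``uniform``: join two uniformly chosen roots repeatedly.
    """
    names = _species_names(n_species)
    if shape == "yule":
        leaves = [Node(names[0])]
        for name in names[1:]:
            idx = int(rng.integers(len(leaves)))
            old = leaves[idx]
            # replace the chosen leaf by a cherry (old, new)
            replacement = Node(None, [Node(old.label), Node(name)])
            if old.parent is None:
                leaves[idx] = replacement.children[0]
                leaves.append(replacement.children[1])
                root = replacement
                continue
            parent = old.parent
            parent.children[parent.children.index(old)] = replacement
            replacement.parent = parent
            leaves[idx] = replacement.children[0]
            leaves.append(replacement.children[1])
        root = leaves[0]
        while root.parent is not None:
            root = root.parent
        return Tree(root)
    # uniform sequential joins
    roots = [Node(name) for name in names]
    while len(roots) > 1:
        i, j = sorted(rng.choice(len(roots), size=2, replace=False))
        b = roots.pop(int(j))
        a = roots.pop(int(i))
        roots.append(Node(None, [a, b]))
    return Tree(roots[0])


def _grow_gene_tree(S: SpeciesTree, rng: np.random.Generator,
                    dup_prob: float, loss_prob: float,
                    max_genes: int) -> tuple[Node | None, dict[str, str]]:
    """Top-down growth of one gene tree along S.

    At each step a lineage sitting on a species-tree node either duplicates
    in place (probability ``dup_prob``) or follows the speciation at that
    node; each descending branch survives with probability
    ``1 - loss_prob``.  Lost lineages are contracted away.  Returns the
    root (or None if the family went extinct) and the gene->species map.
    """
    counter: dict[str, int] = {}
    mapping: dict[str, str] = {}
    budget = [max_genes]

    def new_gene(species: str) -> Node:
        counter[species] = counter.get(species, 0) + 1
        gene = f"{species}{counter[species]}"
        mapping[gene] = species
        return Node(gene)

    def evolve(snode: Node) -> Node | None:
        if budget[0] <= 0:
            return None
        if rng.random() < dup_prob and budget[0] > 1:
            left = evolve(snode)
            right = evolve(snode)
            if left is None:
                return right
            if right is None:
                return left
            return Node(None, [left, right])
        if snode.is_leaf:
            budget[0] -= 1
            return new_gene(snode.label)
        kept: list[Node] = []
        for child in snode.children:
            if rng.random() < loss_prob:
                continue
            sub = evolve(child)
            if sub is not None:
                kept.append(sub)
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        return Node(None, kept)

    return evolve(S.root), mapping


def _speciation_only_subset(true_tree: GeneTree, S: SpeciesTree,
                            smap: GeneSpeciesMap, pool: list[str],
                            target: int, rng: np.random.Generator
                            ) -> list[str]:
    """Greedily assemble a gene subset whose restriction of the true tree
    contains only speciation nodes."""
    order = list(pool)
    rng.shuffle(order)
    chosen: list[str] = []
    for gene in order:
        candidate = chosen + [gene]
        if len(candidate) >= 2:
            sub = restrict(true_tree, candidate)
            if label_nodes(sub, S, smap).duplication_count:
                continue
        chosen = candidate
        if len(chosen) == target:
            break
    return chosen


def simulate_instance(config: SimulationConfig) -> SimulatedInstance:
    """Draw one instance under ``config`` (reproducible given the seed)."""
    rng = np.random.default_rng(config.seed)
    for _ in range(config.max_retries):
        S = random_species_tree(config.n_species, rng, config.species_shape)
        root, mapping = _grow_gene_tree(S, rng, config.dup_prob,
                                        config.loss_prob, config.max_genes)
        if root is None or root.is_leaf:
            continue
        full_tree = Tree(root)
        genes = sorted(full_tree.leaf_labels)
        if len(genes) < max(2, config.min_size):
            continue
        smap = GeneSpeciesMap(mapping)
        subsets: list[list[str]] = []
        pool = list(genes)
        ok = True
        for _ in range(config.k):
            if len(pool) < 1:
                ok = False
                break
            target = int(rng.integers(config.min_size, config.max_size + 1))
            target = min(target, len(pool))
            if config.speciation_only:
                chosen = _speciation_only_subset(full_tree, S, smap, pool,
                                                 target, rng)
            else:
                chosen = [pool[i] for i in
                          rng.choice(len(pool), size=target, replace=False)]
            if len(chosen) < 1:
                ok = False
                break
            subsets.append(sorted(chosen))
            if config.disjoint:
                pool = [g for g in pool if g not in set(chosen)]
        if not ok or not subsets:
            continue
        gamma = sorted(set().union(*map(set, subsets)))
        if len(gamma) < 2:
            continue
        gene_trees = [restrict(full_tree, sub) for sub in subsets]
        instance = ProblemInstance(
            S, gene_trees, smap, require_disjoint=config.disjoint)
        true_tree = restrict(full_tree, gamma)
        rec = label_nodes(true_tree, S, smap)
        return SimulatedInstance(
            instance=instance,
            true_tree=true_tree,
            true_duplications=rec.duplication_count,
            true_losses=rec.loss_count,
            config=config,
        )
    raise TreeError("simulation failed to produce a usable instance; "
                    "loosen the configuration")


# ---------------------------------------------------------------------- #
# the graph-coloring reduction


def _caterpillar(labels: list[str]) -> Node:
    node = Node(labels[0])
    for label in labels[1:]:
        node = Node(None, [node, Node(label)])
    return node


def coloring_reduction(H: nx.Graph) -> ProblemInstance:
    """Encode graph coloring as a supergenetree instance.

    Each vertex v contributes genes v1, v2 in species of the same name; an
    edge vw contributes the triplet trees v1v2|w1, v1v2|w2, w1w2|v1 and
    w1w2|v2, forcing every compatible supertree to display
    ((v1,v2),(w1,w2)).  The species tree joins a caterpillar over the
    "1" species with one over the "2" species, so v1 and v2 are separated
    only by the species root, making lca(v1, v2) a pre-speciation
    duplication whenever v has a neighbor.  The minimum duplication cost of
    the instance is chi(H) - 1.
    """
    if H.number_of_edges() == 0:
        raise TreeError("the coloring reduction needs at least one edge")
    vertices = sorted(H.nodes, key=str)
    side1 = [f"{v}1" for v in vertices]
    side2 = [f"{v}2" for v in vertices]
    species_tree = Tree(Node(None, [_caterpillar(side1), _caterpillar(side2)]))
    mapping = GeneSpeciesMap({name: name for name in side1 + side2})
    gene_trees: list[GeneTree] = []

    def triplet_tree(x: str, y: str, z: str) -> GeneTree:
        return Tree(Node(None, [Node(None, [Node(x), Node(y)]), Node(z)]))

    for v, w in sorted(H.edges, key=lambda e: tuple(sorted(map(str, e)))):
        v, w = sorted((v, w), key=str)
        gene_trees.append(triplet_tree(f"{v}1", f"{v}2", f"{w}1"))
        gene_trees.append(triplet_tree(f"{v}1", f"{v}2", f"{w}2"))
        gene_trees.append(triplet_tree(f"{w}1", f"{w}2", f"{v}1"))
        gene_trees.append(triplet_tree(f"{w}1", f"{w}2", f"{v}2"))
    return ProblemInstance(species_tree, gene_trees, mapping)


# ---------------------------------------------------------------------- #
# file output


def write_instance(instance: ProblemInstance, out_dir: str | os.PathLike,
                   truth: SimulatedInstance | None = None) -> dict[str, str]:
    """Emit species.nwk, genetrees.nwk (one Newick per line), map.tsv and,
    for simulated instances, truth.json.  Returns the file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "species": str(out / "species.nwk"),
        "genetrees": str(out / "genetrees.nwk"),
        "map": str(out / "map.tsv"),
    }
    (out / "species.nwk").write_text(instance.species_tree.newick() + "\n")
    (out / "genetrees.nwk").write_text(
        "".join(t.newick() + "\n" for t in instance.gene_trees))
    (out / "map.tsv").write_text(instance.mapping.to_tsv_text())
    if truth is not None:
        payload = {
            "true_tree": truth.true_tree.newick(),
            "true_duplications": truth.true_duplications,
            "true_losses": truth.true_losses,
            "seed": truth.config.seed,
        }
        (out / "truth.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n")
        paths["truth"] = str(out / "truth.json")
    return paths
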