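"""Shared fixtures: the six-species worked example, random tree builders,
and a deterministic stream of small consistent instances."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from supergenetree.core_trees import (
    Node,
    ProblemInstance,
    Tree,
    load_instance,
)
from supergenetree.simulate import SimulationConfig, simulate_instance

settings.register_profile("suite", derandomize=True, max_examples=40)
settings.load_profile("suite")

# The six-species worked example: three triplet gene trees whose roots are
# all required duplications mapped to the species root.
FIG_SPECIES = "((a,(b,c)),(d,(e,f)));"
FIG_GENE_TREES = ["((a1,d1),c1);", "((d1,b1),e1);", "((c1,e1),f1);"]
FIG_MAP = {f"{s}1": s for s in "abcdef"}


@pytest.fixture
def fig_instance() -> ProblemInstance:
    return load_instance(FIG_SPECIES, FIG_GENE_TREES, FIG_MAP)


def random_binary_tree(labels, rng: np.random.Generator) -> Tree:
    """Uniform-ish random rooted binary topology by random sequential joins."""
    roots = [Node(label) for label in labels]
    while len(roots) > 1:
        i, j = sorted(rng.choice(len(roots), size=2, replace=False))
        b = roots.pop(int(j))
        a = roots.pop(int(i))
        roots.append(Node(None, [a, b]))
    return Tree(roots[0])


def naive_lca(tree: Tree, u, v):
    """Path-walking LCA, the oracle for the Euler-tour index."""
    ancestors = set()
    node = u
    while node is not None:
        ancestors.add(id(node))
        node = node.parent
    node = v
    while id(node) not in ancestors:
        node = node.parent
    return node


def small_consistent_instances(count: int, *, max_genes: int = 7,
                               start_seed: int = 0,
                               speciation_only: bool = False,
                               disjoint: bool = False):
    """Yield ``count`` simulated (hence consistent) instances with at most
    ``max_genes`` genes, scanning seeds deterministically."""
    produced = 0
    seed = start_seed
    while produced < count:
        config = SimulationConfig(
            n_species=6, dup_prob=0.25, loss_prob=0.15, k=3,
            min_size=2, max_size=4, seed=seed,
            speciation_only=speciation_only, disjoint=disjoint)
        seed += 1
        try:
            sim = simulate_instance(config)
        except Exception:
            continue
        if len(sim.instance.genes) > max_genes:
            continue
        produced += 1
        yield sim
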