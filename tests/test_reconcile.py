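"""LCA reconciliation: mapping, labels, duplication and loss counts."""

from itertools import product

import numpy as np
import pytest

from supergenetree.core_trees import (
    GeneSpeciesMap,
    TreeError,
    load_instance,
    read_newick,
)
from supergenetree.reconcile import (
    DUPLICATION,
    SPECIATION,
    label_nodes,
    map_nodes,
    preserves_speciations,
    reconciliation_cost,
    required_duplication,
)

from conftest import FIG_MAP, FIG_SPECIES, random_binary_tree

S6 = read_newick(FIG_SPECIES, "species")
SMAP = GeneSpeciesMap(FIG_MAP)


def embedding_loss_oracle(T, S, smap):
    """Minimum losses (and minimum duplications+losses) over all explicit
    embeddings of the gene tree into the species tree.

    An embedding assigns each internal node an ancestor-or-equal of the LCA
    of its children's images, consistently with the tree order; each
    embedding implies a duplication/speciation labeling and a loss count.
    """
    internals = [n for n in T.root.postorder() if not n.is_leaf]
    image = {id(l): S.leaf(smap[l.label]) for l in T.leaves}

    def ancestors(node):
        out = [node]
        while node.parent is not None:
            node = node.parent
            out.append(node)
        return out

    candidate_sets = []
    for x in internals:
        # children may themselves be internal; candidates depend on the
        # choice below, so enumerate over all species nodes that are
        # ancestors of the LCA mapping of the subtree's leaves
        base = S.lca([image[id(l)] for l in x.postorder() if l.is_leaf])
        candidate_sets.append(ancestors(base))

    best_total = None
    best_losses = None
    for choice in product(*candidate_sets):
        mu = dict(image)
        for x, s_node in zip(internals, choice):
            mu[id(x)] = s_node
        ok = True
        dups = 0
        losses = 0
        for x in internals:
            cl, cr = x.children
            a, b, m = mu[id(cl)], mu[id(cr)], mu[id(x)]
            if not (S.is_ancestor(m, a) and S.is_ancestor(m, b)):
                ok = False
                break
            lca_ab = S.lca_pair(a, b)
            speciation = m is lca_ab and S.separated(a, b)
            if not speciation:
                dups += 1
            for c_img in (a, b):
                dist = S.depth(c_img) - S.depth(m)
                losses += dist - (1 if speciation else 0)
        if not ok:
            continue
        total = dups + losses
        if best_total is None or total < best_total:
            best_total = total
        if best_losses is None or losses < best_losses:
            best_losses = losses
    return best_losses, best_total


class TestMappingAndLabels:
    def test_cherry_maps_to_root(self):
        inst = load_instance("(a,b);", ["(ga,gb);"], {"ga": "a", "gb": "b"})
        m = map_nodes(inst.gene_trees[0], inst.species_tree, inst.mapping)
        assert m[id(inst.gene_trees[0].root)] is inst.species_tree.root

    def test_triplet_root_maps_to_species_root(self):
        t = read_newick("((a1,d1),c1);")
        m = map_nodes(t, S6, SMAP)
        assert m[id(t.root)] is S6.root

    def test_identity_reconciliation(self):
        # gene tree congruent to the species tree, one gene per species
        t = read_newick("((a1,(b1,c1)),(d1,(e1,f1)));")
        rec = label_nodes(t, S6, SMAP)
        assert rec.duplication_count == 0
        assert rec.loss_count == 0
        assert rec.mutation_cost == 0
        assert all(lab == SPECIATION for lab in rec.labels.values())
        m = rec.mapping
        for node in t.root.postorder():
            leaves = {l.label[:-1] for l in node.postorder() if l.is_leaf}
            assert m[id(node)] is S6.lca_labels(leaves)

    def test_same_species_cherry_is_duplication(self):
        inst = load_instance("(a,b);", ["(g1,g2);"], {"g1": "a", "g2": "a"})
        rec = label_nodes(inst.gene_trees[0], inst.species_tree, inst.mapping)
        assert rec.label_of(inst.gene_trees[0].root) == DUPLICATION
        assert rec.loss_count == 0  # duplication inside an extant species

    def test_speciation_across_cherries_counts_losses(self):
        # root speciation with images two edges below on each side
        S = read_newick("((a,b),(c,d));", "species")
        smap = GeneSpeciesMap({"ga": "a", "gc": "c"})
        t = read_newick("(ga,gc);")
        rec = label_nodes(t, S, smap)
        assert rec.label_of(t.root) == SPECIATION
        assert rec.loss_count == 2

    def test_label_partition_invariant(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            genes = [f"{s}1" for s in "abcdef"]
            t = random_binary_tree(genes, rng)
            rec = label_nodes(t, S6, SMAP)
            assert (rec.duplication_count + rec.speciation_count
                    == len(t.internal_nodes()))
            assert rec.mutation_cost >= rec.duplication_count
            for nid in rec.pre_speciation:
                assert rec.mapping[nid] is S6.root

    def test_worked_example_supertree_costs(self):
        # the suboptimal supertree of the worked example: 2 duplications
        t2 = read_newick("(((a1,b1),d1),((c1,e1),f1));")
        assert reconciliation_cost(t2, S6, SMAP, "dup") == 2
        # the optimal supertree: only the root is a duplication
        t1 = read_newick("(((a1,b1),(d1,f1)),(c1,e1));")
        assert reconciliation_cost(t1, S6, SMAP, "dup") == 1


class TestLossOracle:
    @pytest.mark.parametrize("seed", range(10))
    def test_losses_match_embedding_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        species = list("abcdef")[:max(2, int(rng.integers(2, 7)))]
        S = random_binary_tree(species, rng)
        genes = [f"g{i}" for i in range(n)]
        smap = GeneSpeciesMap(
            {g: species[int(rng.integers(len(species)))] for g in genes})
        T = random_binary_tree(genes, rng)
        rec = label_nodes(T, S, smap)
        min_losses, min_total = embedding_loss_oracle(T, S, smap)
        assert rec.loss_count == min_losses
        assert rec.mutation_cost == min_total


class TestRequiredDuplication:
    def test_worked_example_triplet_is_required(self):
        assert required_duplication(read_newick("((a1,d1),c1);"), S6, SMAP)

    def test_same_species_triplet_below_root_not_required(self):
        S = read_newick("(a,b);", "species")
        smap = GeneSpeciesMap({"g1": "a", "g2": "a", "g3": "a"})
        t = read_newick("((g1,g2),g3);")
        assert not required_duplication(t, S, smap)

    def test_speciation_triplet_not_required(self):
        # bc|a maps below the species root and is a speciation
        assert not required_duplication(read_newick("((b1,c1),a1);"), S6, SMAP)

    def test_non_triplet_rejected(self):
        with pytest.raises(TreeError):
            required_duplication(read_newick("(a1,b1);"), S6, SMAP)


class TestPreservesSpeciations:
    def test_join_of_disjoint_speciation_trees(self):
        # two speciation trees glued under a duplication root keep their
        # internal speciations
        S = read_newick("((a,b),(c,d));", "species")
        smap = {"x1": "a", "x2": "b", "y1": "a", "y2": "c"}
        inst = load_instance("((a,b),(c,d));", ["(x1,x2);", "(y1,y2);"],
                             smap, require_disjoint=True)
        T = read_newick("((x1,x2),(y1,y2));")
        assert preserves_speciations(T, inst)

    def test_single_speciation_input(self):
        inst = load_instance("((a,b),(c,d));", ["(x1,x2);"],
                             {"x1": "a", "x2": "b"})
        assert preserves_speciations(read_newick("(x1,x2);"), inst)

    def test_duplicated_copy_root_fails(self):
        inst = load_instance("((a,b),(c,d));", ["(x1,x2);"],
                             {"x1": "a", "x2": "a"})
        assert not preserves_speciations(read_newick("(x1,x2);"), inst)

    def test_undisplayed_copy_fails(self):
        smap = {"x1": "a", "x2": "b", "x3": "c"}
        inst = load_instance("((a,b),(c,d));", ["((x1,x2),x3);"], smap)
        T = read_newick("((x1,x3),x2);")
        assert not preserves_speciations(T, inst)

    def test_overlapping_inputs_rejected(self):
        inst = load_instance("((a,b),(c,d));", ["(x1,x2);", "(x2,x3);"],
                             {"x1": "a", "x2": "b", "x3": "c"})
        with pytest.raises(TreeError):
            preserves_speciations(read_newick("((x1,x2),x3);"), inst)
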