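"""The subset dynamic program against the brute-force oracle."""

import math

import numpy as np
import pytest

from supergenetree.core_trees import displays, load_instance, read_newick
from supergenetree.exact_solver import (
    InconsistentError,
    SizeLimitError,
    SubsetLcaTable,
    dup_flag,
    enumerate_topologies,
    oracle_enumerate,
    precompute_subset_lca,
    solve_constrained_root,
    solve_exact,
)
from supergenetree.reconcile import reconciliation_cost
from supergenetree.simulate import coloring_reduction

import networkx as nx

from conftest import small_consistent_instances


class TestSubsetLca:
    def test_singletons_and_pairs(self, fig_instance):
        table = precompute_subset_lca(fig_instance)
        S = fig_instance.species_tree
        assert table.species_of(["a1"]) is S.leaf("a")
        assert table.species_of(["a1", "d1"]) is S.root
        assert table.species_of(["a1", "b1"]) is S.root.children[0]

    def test_recursive_identity_on_random_subsets(self, fig_instance):
        table = precompute_subset_lca(fig_instance)
        S = fig_instance.species_tree
        rng = np.random.default_rng(0)
        genes = fig_instance.genes
        for _ in range(30):
            k = int(rng.integers(2, 7))
            sub = [genes[i] for i in rng.choice(6, size=k, replace=False)]
            direct = S.lca([fig_instance.species_node(g) for g in sub])
            assert table.species_of(sub) is direct

    def test_cap_enforced(self, fig_instance):
        with pytest.raises(SizeLimitError):
            SubsetLcaTable(fig_instance, max_genes=3)


class TestDupFlag:
    def test_separated_pair_is_speciation(self, fig_instance):
        table = precompute_subset_lca(fig_instance)
        assert dup_flag(["a1"], ["b1"], table) == 0

    def test_both_sides_at_root_is_duplication(self, fig_instance):
        table = precompute_subset_lca(fig_instance)
        assert dup_flag(["a1", "b1", "d1"], ["c1", "e1", "f1"], table) == 1

    def test_equal_images_never_separated(self, fig_instance):
        table = precompute_subset_lca(fig_instance)
        # both subsets map to the species root
        assert dup_flag(["a1", "d1"], ["c1", "e1"], table) == 1


class TestSolveExact:
    def test_worked_example_optimum(self, fig_instance):
        tree, cost = solve_exact(fig_instance, "dup")
        assert cost == 1
        left, right = tree.root.children
        sides = {frozenset(l.label for l in c.postorder() if l.is_leaf)
                 for c in (left, right)}
        assert sides == {frozenset({"a1", "b1", "d1", "f1"}),
                         frozenset({"c1", "e1"})}

    def test_solution_displays_every_input(self, fig_instance):
        tree, _ = solve_exact(fig_instance, "dup")
        for g in fig_instance.gene_trees:
            assert displays(tree, g)

    def test_single_input_tree_is_an_upper_bound(self):
        inst = load_instance("((a,(b,c)),(d,(e,f)));",
                             ["(((a1,b1),d1),((c1,e1),f1));"],
                             {f"{s}1": s for s in "abcdef"})
        tree, cost = solve_exact(inst, "dup")
        own = reconciliation_cost(inst.gene_trees[0], inst.species_tree,
                                  inst.mapping, "dup")
        assert cost <= own
        assert displays(tree, inst.gene_trees[0])

    def test_inconsistent_verdict(self):
        inst = load_instance("((a,b),c);", ["((a1,b1),c1);", "((b1,c1),a1);"],
                             {"a1": "a", "b1": "b", "c1": "c"})
        with pytest.raises(InconsistentError):
            solve_exact(inst)

    def test_mutation_cost_equals_reconciliation_of_output(self):
        for sim in small_consistent_instances(10, start_seed=100):
            tree, cost = solve_exact(sim.instance, "mutation")
            again = reconciliation_cost(tree, sim.instance.species_tree,
                                        sim.instance.mapping, "mutation")
            assert cost == again

    def test_optimum_bounded_by_simulated_truth(self):
        for sim in small_consistent_instances(10, start_seed=300):
            _, cost = solve_exact(sim.instance, "dup")
            assert cost <= sim.true_duplications

    def test_monotone_under_added_input_trees(self):
        for sim in small_consistent_instances(6, start_seed=500):
            inst = sim.instance
            prev = 0
            for j in range(1, inst.k + 1):
                partial = load_instance(
                    inst.species_tree.newick(),
                    [t.newick() for t in inst.gene_trees[:j]],
                    dict(inst.mapping))
                _, cost = solve_exact(partial, "dup")
                assert cost >= prev
                prev = cost


class TestConstrainedRoot:
    def test_worked_example_bipartitions(self, fig_instance):
        _, c_subopt = solve_constrained_root(
            fig_instance, (["a1", "b1", "d1"], ["c1", "e1", "f1"]), "dup")
        assert c_subopt == 2
        _, c_opt = solve_constrained_root(
            fig_instance, (["a1", "b1", "d1", "f1"], ["c1", "e1"]), "dup")
        assert c_opt == 1

    def test_splitting_a_triplet_pair_is_infeasible(self, fig_instance):
        tree, cost = solve_constrained_root(
            fig_instance, (["a1", "b1", "c1"], ["d1", "e1", "f1"]), "dup")
        assert tree is None and math.isinf(cost)


class TestOracle:
    def test_topology_count_double_factorial(self):
        assert sum(1 for _ in enumerate_topologies(list("abc"))) == 3
        assert sum(1 for _ in enumerate_topologies(list("abcde"))) == 105

    def test_single_triplet_feasible_fraction(self):
        inst = load_instance("((a,b),c);", ["((a1,b1),c1);"],
                             {"a1": "a", "b1": "b", "c1": "c"})
        tree, cost = oracle_enumerate(inst, "dup")
        assert cost == 0
        assert tree.isomorphic(read_newick("((a1,b1),c1);"))

    def test_oracle_matches_dp_on_worked_example(self, fig_instance):
        _, dp = solve_exact(fig_instance, "dup")
        _, orc = oracle_enumerate(fig_instance, "dup")
        assert dp == orc == 1

    def test_cap_enforced(self, fig_instance):
        with pytest.raises(SizeLimitError):
            oracle_enumerate(fig_instance, max_genes=4)

    @pytest.mark.parametrize("cost", ["dup", "mutation"])
    def test_dp_equals_oracle_on_random_instances(self, cost):
        for sim in small_consistent_instances(25, start_seed=1000):
            _, dp = solve_exact(sim.instance, cost)
            _, orc = oracle_enumerate(sim.instance, cost)
            assert dp == orc


class TestColoringFixtures:
    @pytest.mark.parametrize("graph,chi", [
        (nx.complete_graph(3), 3),
        (nx.path_graph(3), 2),
        (nx.cycle_graph(5), 3),
        (nx.complete_graph(4), 4),
    ])
    def test_optimum_is_chromatic_number_minus_one(self, graph, chi):
        inst = coloring_reduction(graph)
        _, cost = solve_exact(inst, "dup")
        assert cost == chi - 1
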