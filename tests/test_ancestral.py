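import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import oracles
from pancestor.ancestral import (
    copy_number_interval,
    fitch_states,
    fitch_union_count,
    root_content_interval,
    sankoff_linear,
    squared_change,
)
from pancestor.datamodel import GenomeRecord, OrthologMatrix, ValidationError
from pancestor.simulate import SimulationConfig, simulate_gene_content, \
    simulate_tree
from pancestor.trees import Phylogeny


def _random_binary_tree(rng, n_tips):
    return simulate_tree(n_tips, 1.0, rng=rng)


class TestFitch:
    def test_textbook_symmetric_case(self, quartet_tree):
        rec = fitch_states(quartet_tree, {"A": 1, "B": 1, "C": 0, "D": 0})
        idx = quartet_tree.index()
        root = idx.labels[idx.root]
        assert rec.node_states[root] == frozenset({0, 1})
        assert rec.total_cost == 1

    def test_constant_character(self, quartet_tree):
        rec = fitch_states(quartet_tree, {t: 1 for t in "ABCD"})
        assert rec.total_cost == 0
        assert all(s == frozenset({1}) for s in rec.node_states.values())

    def test_missing_tip_state_rejected(self, quartet_tree):
        with pytest.raises(ValidationError):
            fitch_states(quartet_tree, {"A": 1, "B": 1, "C": 0})

    def test_matches_exhaustive_enumeration(self, rng):
        """Cost and MPR node sets equal brute-force minimisation over all
        internal assignments on random 7-tip binary trees."""
        for rep in range(30):
            tree = _random_binary_tree(rng, 7)
            states = {t: int(rng.integers(2)) for t in tree.tip_labels}
            rec = fitch_states(tree, states)
            best, node_sets = oracles.enumerate_parsimony(
                tree, states, [0, 1], oracles.unit_cost)
            assert rec.total_cost == best
            for label, expected in node_sets.items():
                assert rec.node_states[label] == frozenset(expected)

    def test_union_count_equals_cost_on_binary_trees(self, rng):
        for rep in range(20):
            tree = _random_binary_tree(rng, 8)
            states = {t: int(rng.integers(3)) for t in tree.tip_labels}
            assert fitch_union_count(tree, states) == \
                fitch_states(tree, states).total_cost

    def test_cost_invariant_under_rerooting(self, rng):
        """Unit-cost parsimony score does not depend on root placement."""
        import dendropy
        for rep in range(10):
            tree = _random_binary_tree(rng, 7)
            states = {t: int(rng.integers(2)) for t in tree.tip_labels}
            base = fitch_states(tree, states).total_cost
            newick = tree.to_newick()
            for target in list(states)[:3]:
                dt = dendropy.Tree.get(data=newick, schema="newick",
                                       preserve_underscores=True)
                edge = [l for l in dt.leaf_node_iter()
                        if l.taxon.label == target][0].edge
                dt.reroot_at_edge(edge, update_bipartitions=False)
                # suppress the degree-2 node left at the old root
                dt.suppress_unifurcations()
                rerooted = Phylogeny(dt)
                assert fitch_states(rerooted, states).total_cost == base

    def test_equivocal_branch_flags(self, quartet_tree):
        rec = fitch_states(quartet_tree, {"A": 1, "B": 1, "C": 0, "D": 0})
        idx = quartet_tree.index()
        # branches below the ambiguous root are equivocal, pendant ones not
        for v in range(idx.n_nodes):
            if idx.parent[v] == idx.root:
                assert rec.equivocal_branches[idx.labels[v]]
            elif idx.parent[v] >= 0:
                assert not rec.equivocal_branches[idx.labels[v]]


class TestSankoffLinear:
    def test_constant_copy_number(self, quartet_tree):
        rec = sankoff_linear(quartet_tree, {t: 2 for t in "ABCD"})
        idx = quartet_tree.index()
        assert rec.total_cost == 0
        assert rec.node_states[idx.labels[idx.root]] == frozenset({2})

    def test_two_tip_linear_degeneracy(self):
        tree = Phylogeny.from_newick("(A:1,B:1);")
        rec = sankoff_linear(tree, {"A": 0, "B": 4})
        idx = tree.index()
        assert rec.total_cost == 4
        assert rec.node_states[idx.labels[idx.root]] == \
            frozenset({0, 1, 2, 3, 4})

    def test_negative_copies_rejected(self, quartet_tree):
        with pytest.raises(ValidationError):
            sankoff_linear(quartet_tree, {"A": -1, "B": 0, "C": 0, "D": 0})

    def test_matches_exhaustive_enumeration(self, rng):
        for rep in range(20):
            tree = _random_binary_tree(rng, 6)
            copies = {t: int(rng.integers(4)) for t in tree.tip_labels}
            rec = sankoff_linear(tree, copies)
            alphabet = list(range(max(copies.values()) + 1))
            best, node_sets = oracles.enumerate_parsimony(
                tree, copies, alphabet, oracles.linear_cost)
            assert rec.total_cost == best
            for label, expected in node_sets.items():
                assert rec.node_states[label] == frozenset(expected)


class TestRootContentInterval:
    def _matrix(self, tree, presence_rows):
        tips = sorted(tree.tip_labels)
        genomes = {t: GenomeRecord(id=t) for t in tips}
        functional = pd.DataFrame(presence_rows, columns=tips,
                                  index=[f"G{i}" for i in
                                         range(len(presence_rows))])
        pseudo = functional * 0
        return OrthologMatrix(functional, pseudo, genomes)

    def test_ubiquitous_family_counts_toward_min(self, quartet_tree):
        m = self._matrix(quartet_tree, [[1, 1, 1, 1]])
        iv = root_content_interval(m, quartet_tree)
        assert (iv.min_genes, iv.max_genes) == (1, 1)

    def test_single_tip_family_counts_toward_neither(self, quartet_tree):
        m = self._matrix(quartet_tree, [[1, 0, 0, 0]])
        iv = root_content_interval(m, quartet_tree)
        assert (iv.min_genes, iv.max_genes) == (0, 0)

    def test_symmetric_split_is_ambiguous(self, quartet_tree):
        # A,B present; C,D absent -> root MPR set {0,1}: max only
        m = self._matrix(quartet_tree, [[1, 1, 0, 0]])
        iv = root_content_interval(m, quartet_tree)
        assert (iv.min_genes, iv.max_genes) == (0, 1)
        assert len(iv.ambiguous_groups) == 1

    def test_agrees_with_per_group_fitch(self, rng):
        tree = _random_binary_tree(rng, 6)
        cfg = SimulationConfig(n_tips=6, n_families=60, seed=31)
        m, _ = simulate_gene_content(tree, cfg)
        m = m.subset_groups(m.functional.index[
            (m.functional.sum(axis=1) > 0)])
        iv = root_content_interval(m, tree, "functional_only")
        idx = tree.index()
        root = idx.labels[idx.root]
        lo = hi = 0
        for gid in m.group_ids:
            states = {t: int(m.functional.at[gid, t] > 0)
                      for t in tree.tip_labels}
            rs = fitch_states(tree, states).node_states[root]
            if rs == frozenset({1}):
                lo += 1
                hi += 1
            elif rs == frozenset({0, 1}):
                hi += 1
        assert (iv.min_genes, iv.max_genes) == (lo, hi)

    def test_tip_mismatch_rejected(self, quartet_tree, tiny_matrix):
        with pytest.raises(ValidationError):
            root_content_interval(tiny_matrix, quartet_tree)

    def test_copy_number_interval_brackets_presence_interval(self, rng):
        tree = _random_binary_tree(rng, 6)
        cfg = SimulationConfig(n_tips=6, n_families=40, dup_rate=0.3, seed=37)
        m, _ = simulate_gene_content(tree, cfg)
        m = m.subset_groups(m.functional.index[m.functional.sum(axis=1) > 0])
        pres = root_content_interval(m, tree)
        copies = copy_number_interval(m, tree)
        # counting copies can only widen the upper bound
        assert copies.max_genes >= pres.max_genes
        assert copies.min_genes >= pres.min_genes


class TestSquaredChange:
    def test_star_tree_mean(self):
        tree = Phylogeny.from_newick("(A:1,B:1,C:1);")
        rec = squared_change(tree, {"A": 2.0, "B": 4.0, "C": 6.0})
        idx = tree.index()
        assert rec.node_states[idx.labels[idx.root]] == pytest.approx(4.0)

    def test_two_tip_midpoint(self):
        tree = Phylogeny.from_newick("(A:1,B:1);")
        rec = squared_change(tree, {"A": 2.0, "B": 4.0})
        idx = tree.index()
        assert rec.node_states[idx.labels[idx.root]] == pytest.approx(3.0)

    def test_weighted_two_tip_inverse_length_mean(self):
        # weighted optimum is the inverse-branch-length weighted mean
        tree = Phylogeny.from_newick("(A:1,B:3);")
        rec = squared_change(tree, {"A": 0.0, "B": 4.0}, weighted=True)
        idx = tree.index()
        expected = (0.0 / 1 + 4.0 / 3) / (1 / 1 + 1 / 3)
        assert rec.node_states[idx.labels[idx.root]] == pytest.approx(expected)

    def test_weighted_zero_branch_rejected(self):
        tree = Phylogeny.from_newick("(A:0,B:1);")
        with pytest.raises(ValidationError):
            squared_change(tree, {"A": 0.0, "B": 1.0}, weighted=True)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_numeric_minimizer(self, rng, weighted):
        for rep in range(5):
            tree = _random_binary_tree(rng, 8)
            values = {t: float(rng.normal()) for t in tree.tip_labels}
            rec = squared_change(tree, values, weighted=weighted)
            idx = tree.index()
            internal = [v for v in range(idx.n_nodes) if not idx.is_tip[v]]

            def objective(x):
                vals = dict(values)
                for v, xv in zip(internal, x):
                    vals[idx.labels[v]] = xv
                cost = 0.0
                for v in range(idx.n_nodes):
                    p = idx.parent[v]
                    if p < 0:
                        continue
                    w = 1.0 / idx.length[v] if weighted else 1.0
                    cost += w * (vals[idx.labels[v]]
                                 - vals[idx.labels[p]]) ** 2
                return cost

            x0 = np.zeros(len(internal))
            res = minimize(objective, x0, method="BFGS",
                           options={"gtol": 1e-12})
            assert rec.total_cost == pytest.approx(res.fun, abs=1e-8)
            for v, xv in zip(internal, res.x):
                assert rec.node_states[idx.labels[v]] == \
                    pytest.approx(xv, abs=1e-5)

    def test_local_optimality_probe(self, rng):
        tree = _random_binary_tree(rng, 10)
        values = {t: float(rng.normal()) for t in tree.tip_labels}
        rec = squared_change(tree, values)
        idx = tree.index()
        internal = [idx.labels[v] for v in range(idx.n_nodes)
                    if not idx.is_tip[v]]

        def cost_of(assign):
            total = 0.0
            for v in range(idx.n_nodes):
                p = idx.parent[v]
                if p < 0:
                    continue
                total += (assign[idx.labels[v]] - assign[idx.labels[p]]) ** 2
            return total

        base = dict(rec.node_states)
        assert cost_of(base) == pytest.approx(rec.total_cost)
        for _ in range(100):
            perturbed = dict(base)
            for lab in internal:
                perturbed[lab] += rng.normal(0, 0.1)
            assert cost_of(perturbed) >= rec.total_cost - 1e-12
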