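import math

import numpy as np
import pytest
from scipy.linalg import expm

from pancestor.datamodel import build_matrix, parse_coghits, parse_genomes, \
    parse_groups, parse_pseudogenes
from pancestor.simulate import (
    SimulationConfig,
    clade_assignment,
    simulate_continuous,
    simulate_dataset,
    simulate_gene_content,
    simulate_genome_metadata,
    simulate_tree,
)
from pancestor.trees import Phylogeny


class TestSimulateTree:
    def test_two_tips_forced_shape(self):
        t = simulate_tree(2, 1.0, seed=0)
        idx = t.index()
        assert sorted(idx.tip_index) == ["t01", "t02"]
        lengths = [idx.length[idx.tip_index[x]] for x in ("t01", "t02")]
        assert lengths[0] == lengths[1] > 0

    def test_determinism(self):
        a = simulate_tree(12, 0.7, seed=42).to_newick()
        b = simulate_tree(12, 0.7, seed=42).to_newick()
        assert a == b

    def test_58_tips_binary_internal_count(self):
        t = simulate_tree(58, 1.0, seed=5)
        idx = t.index()
        assert idx.n_tips == 58
        assert idx.n_nodes - idx.n_tips == 57
        assert t.is_binary()

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            simulate_tree(1, 1.0, seed=0)


class TestGeneContent:
    def test_no_events_all_present(self):
        tree = simulate_tree(6, 1.0, seed=1)
        cfg = SimulationConfig(n_tips=6, n_families=20, gain_rate=0.0,
                               loss_rate=0.0, root_presence_prob=1.0,
                               dup_rate=0.0, seed=2)
        m, truth = simulate_gene_content(tree, cfg)
        assert (m.functional.to_numpy() == 1).all()
        assert truth.root_presence.all()

    def test_no_events_empty(self):
        tree = simulate_tree(6, 1.0, seed=1)
        cfg = SimulationConfig(n_tips=6, n_families=20, gain_rate=0.0,
                               loss_rate=0.0, root_presence_prob=0.0, seed=2)
        m, _ = simulate_gene_content(tree, cfg)
        assert (m.functional.to_numpy() == 0).all()

    def test_tip_presence_matches_matrix_exponential(self):
        """Tip presence frequencies agree with the analytic 2-state chain.

        For each tip, the presence probability is the root distribution
        propagated through expm(Q * t) along the root-to-tip path; observed
        frequencies over 500 iid families must fall within 3 binomial
        standard errors.
        """
        gain, loss, p0, F = 0.1, 0.1, 0.5, 500
        tree = simulate_tree(8, 1.0, seed=7)
        cfg = SimulationConfig(n_tips=8, n_families=F, gain_rate=gain,
                               loss_rate=loss, root_presence_prob=p0,
                               dup_rate=0.0, seed=11)
        m, _ = simulate_gene_content(tree, cfg)
        Q = np.array([[-gain, gain], [loss, -loss]])
        idx = tree.index()
        for label, v in idx.tip_index.items():
            # accumulate path from root to tip
            path = []
            u = v
            while idx.parent[u] >= 0:
                path.append(idx.length[u])
                u = idx.parent[u]
            P = np.eye(2)
            for t in path:
                P = P @ expm(Q * t)
            p_present = p0 * P[1, 1] + (1 - p0) * P[0, 1]
            observed = m.presence("functional_only")[label].mean()
            se = math.sqrt(p_present * (1 - p_present) / F)
            assert abs(observed - p_present) <= 3 * se + 1e-12

    def test_gamma_rate_heterogeneity_spreads_family_dynamics(self):
        """With a low-shape Gamma multiplier some families evolve far faster
        than others, so the across-family variance of the per-family flip
        count exceeds the i.i.d. case."""
        tree = simulate_tree(16, 1.0, seed=13)
        base = SimulationConfig(n_tips=16, n_families=400, gain_rate=0.05,
                                loss_rate=0.05, root_presence_prob=0.5,
                                seed=14)
        hot = SimulationConfig(n_tips=16, n_families=400, gain_rate=0.05,
                               loss_rate=0.05, root_presence_prob=0.5,
                               gamma_rate_shape=0.2, seed=14)

        def tip_freq_var(cfg):
            m, _ = simulate_gene_content(tree, cfg)
            freq = m.presence("functional_only").mean(axis=1)
            return float(freq.var())

        assert tip_freq_var(hot) > tip_freq_var(base)

    def test_truth_matches_tips_exactly(self):
        tree = simulate_tree(10, 1.0, seed=3)
        cfg = SimulationConfig(n_tips=10, n_families=100, seed=4)
        m, truth = simulate_gene_content(tree, cfg)
        for label in tree.tip_labels:
            assert (m.functional[label].to_numpy()
                    == truth.node_copies[label]).all()


class TestContinuous:
    def test_zero_rate_constant(self):
        tree = simulate_tree(5, 1.0, seed=9)
        vals = simulate_continuous(tree, 0.0, 3.5, seed=1)
        assert all(v == 3.5 for v in vals.values())

    def test_two_tip_difference_variance(self):
        """On a two-tip tree with unit branches the tip difference is
        Normal(0, v1+v2); the empirical variance over 2000 replicates must
        be within 3 se of the closed form."""
        tree = Phylogeny.from_newick("(A:1,B:1);")
        vals = simulate_continuous(tree, 1.0, 0.0, seed=21, size=2000)
        diff = vals["A"] - vals["B"]
        var = diff.var(ddof=1)
        se = 2.0 * math.sqrt(2.0 / (2000 - 1))  # sd of sample variance of N(0,2)
        assert abs(var - 2.0) <= 3 * se

    def test_determinism(self):
        tree = simulate_tree(6, 1.0, seed=2)
        a = simulate_continuous(tree, 1.0, 0.0, seed=5)
        b = simulate_continuous(tree, 1.0, 0.0, seed=5)
        assert a == b

    def test_negative_rate_rejected(self):
        tree = simulate_tree(4, 1.0, seed=2)
        with pytest.raises(ValueError):
            simulate_continuous(tree, -1.0, 0.0, seed=0)


class TestMetadata:
    def _content(self, f, seed=6, n_tips=10):
        tree = simulate_tree(n_tips, 1.0, seed=seed)
        cfg = SimulationConfig(n_tips=n_tips, n_families=200, dup_rate=0.3,
                               pseudo_fraction=f, seed=seed)
        m, truth = simulate_gene_content(tree, cfg)
        return tree, cfg, m

    def test_no_pseudogenization(self):
        tree, cfg, m = self._content(0.0)
        records = simulate_genome_metadata(tree, m, cfg)
        assert (m.pseudo.to_numpy() == 0).all()
        assert all(r.pseudogene_bp == 0 for r in records)

    def test_full_pseudogenization_target(self):
        tree, cfg, m = self._content(1.0)
        target = cfg.pseudo_target or sorted(
            t for t, c in clade_assignment(tree).items() if c == "clade1")[0]
        simulate_genome_metadata(tree, m, cfg)
        assert (m.functional[target].to_numpy() == 0).all()

    def test_partial_pseudogenization_binomial_mean(self):
        """With fraction f the pseudogenized copy count is Binomial(n, f)."""
        f = 0.64
        tree, cfg, m = self._content(f)
        target = sorted(
            t for t, c in clade_assignment(tree).items() if c == "clade1")[0]
        n_before = int(m.functional[target].sum())
        simulate_genome_metadata(tree, m, cfg)
        moved = int(m.pseudo[target].sum())
        sd = math.sqrt(n_before * f * (1 - f))
        assert abs(moved - f * n_before) <= 3 * sd

    def test_partition_invariant_holds_exactly(self):
        tree, cfg, m = self._content(0.64)
        for r in simulate_genome_metadata(tree, m, cfg):
            assert r.coding_bp + r.noncoding_bp + r.pseudogene_bp \
                == r.genome_size_bp

    def test_unknown_target_rejected(self):
        tree, cfg, m = self._content(0.5)
        cfg2 = SimulationConfig(n_tips=10, n_families=200,
                                pseudo_target="nope", seed=1)
        with pytest.raises(Exception, match="nope"):
            simulate_genome_metadata(tree, m, cfg2)


class TestDataset:
    def test_roundtrip_through_files(self, tmp_path):
        """Emitted files re-parsed by the readers reproduce the dataset."""
        cfg = SimulationConfig(n_tips=10, n_families=80, seed=17,
                               planted_signatures={"heterocystous": 3})
        ds = simulate_dataset(cfg)
        ds.write(tmp_path)
        groups = parse_groups(tmp_path / "groups.txt")
        genomes = parse_genomes(tmp_path / "genomes.tsv")
        pseudo = parse_pseudogenes(tmp_path / "pseudogenes.tsv")
        matrix = build_matrix(groups, genomes, pseudo)
        assert genomes == ds.genomes
        assert matrix.functional.sort_index().equals(
            ds.matrix.functional.sort_index())
        assert matrix.pseudo.sort_index().equals(
            ds.matrix.pseudo.sort_index())
        tree = Phylogeny.from_path(tmp_path / "tree.nwk")
        assert sorted(tree.tip_labels) == sorted(ds.tree.tip_labels)
        hits = parse_coghits(tmp_path / "coghits.tsv")
        assert hits.hits == ds.cog_hits.hits

    def test_dataset_determinism(self):
        a = simulate_dataset(SimulationConfig(n_tips=8, n_families=40, seed=9))
        b = simulate_dataset(SimulationConfig(n_tips=8, n_families=40, seed=9))
        assert a.tree.to_newick() == b.tree.to_newick()
        assert a.matrix.functional.equals(b.matrix.functional)
        assert a.truth_summary() == b.truth_summary()

    def test_planted_families_track_phenotype(self):
        # seed chosen so the flag is polymorphic (5 of 12 tips positive)
        cfg = SimulationConfig(n_tips=12, n_families=50, seed=29,
                               planted_signatures={"filamentous": 4})
        ds = simulate_dataset(cfg)
        flags = ds.truth.node_phenotypes["filamentous"]
        planted = [g for g in ds.matrix.group_ids if g.startswith("SIG_")]
        assert len(planted) == 4
        presence = ds.matrix.presence("any_copy")
        for gid in planted:
            for t in ds.tree.tip_labels:
                assert presence.at[gid, t] == flags[t]
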