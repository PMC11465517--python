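import numpy as np
import pytest
from scipy.linalg import expm

import mitorates as mr
from mitorates.likelihood import discretize_gamma
from mitorates.models import write_paml_matrix
from mitorates.trees import PhyloTree
from oracles import enumeration_loglik, gamma_category_means_quadrature


def random_small_tree(rng, n_tips):
    t, _ = mr.simulate_time_tree(n_tips, 0, 100.0, seed=int(rng.integers(1e6)))
    lengths = rng.uniform(0.01, 0.5, t.n_nodes)
    lengths[t.root] = 0.0
    return t.with_lengths(lengths, cls=PhyloTree)


class TestDiscretizeGamma:
    def test_single_category_is_unit_rate(self):
        assert discretize_gamma(2.3, 1).tolist() == [1.0]

    def test_matches_quadrature_oracle(self):
        for alpha, k in [(0.5, 4), (1.7, 6), (0.1, 4), (5.0, 8)]:
            got = discretize_gamma(alpha, k)
            exp = gamma_category_means_quadrature(alpha, k)
            assert np.allclose(got, exp, atol=1e-8)

    def test_mean_is_one_for_random_shapes(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            alpha = float(10 ** rng.uniform(-1.5, 1.5))
            k = int(rng.integers(1, 12))
            r = discretize_gamma(alpha, k)
            assert abs(r.mean() - 1.0) < 1e-12
            assert np.all(np.diff(r) > 0) or k == 1

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            discretize_gamma(0.0, 4)


class TestLogLikelihood:
    def test_zero_lengths_identical_sequences_give_log_pi(self, poisson1):
        pi = np.linspace(1, 2, 20)
        model = mr.poisson_model(frequencies=pi / pi.sum(), n_categories=1)
        tree = PhyloTree([-1, 0, 0], [0.0, 0.0, 0.0], [None, "a", "b"])
        msa = mr.ProteinAlignment.from_dict({"a": "A", "b": "A"})
        assert mr.log_likelihood(msa, tree, model) == pytest.approx(
            np.log(model.frequencies[0]), abs=1e-12
        )

    def test_two_taxon_matches_expm_oracle(self, poisson1):
        pi = np.arange(1, 21, dtype=float)
        model = mr.poisson_model(frequencies=pi / pi.sum(), n_categories=1)
        t = 0.37
        tree = PhyloTree([-1, 0, 0], [0.0, t, 0.0], [None, "a", "b"])
        msa = mr.ProteinAlignment.from_dict({"a": "AR", "b": "NC"})
        P = expm(model.Q * t)
        f = model.frequencies
        exp_ll = np.log(f[0] * P[0, 2]) + np.log(f[1] * P[1, 4])
        assert mr.log_likelihood(msa, tree, model) == pytest.approx(
            exp_ll, abs=1e-10
        )

    def test_four_taxon_matches_enumeration(self, poisson4):
        rng = np.random.default_rng(1)
        tree = random_small_tree(rng, 4)
        chrono, _ = mr.simulate_time_tree(4, 0, 100.0, seed=9)
        aln = mr.simulate_alignment(chrono, poisson4, 0.002, None, 20, seed=2)
        got = mr.log_likelihood(aln, tree, poisson4)
        exp = enumeration_loglik(tree, aln, poisson4)
        assert got == pytest.approx(exp, abs=1e-8)

    def test_pruning_equals_enumeration_on_random_trees(self):
        rng = np.random.default_rng(7)
        for i in range(15):
            n_tips = int(rng.integers(2, 5))
            k = int(rng.choice([1, 3]))
            alpha = float(rng.uniform(0.3, 3.0))
            model = mr.poisson_model(alpha=alpha, n_categories=k)
            tree = random_small_tree(rng, n_tips)
            chrono, _ = mr.simulate_time_tree(n_tips, 0, 50.0,
                                              seed=int(rng.integers(1e6)))
            aln = mr.simulate_alignment(chrono, model, 0.004, None, 10,
                                        seed=int(rng.integers(1e6)))
            got = mr.log_likelihood(aln, tree, model)
            exp = enumeration_loglik(tree, aln, model)
            assert got == pytest.approx(exp, abs=1e-8)

    def test_gap_and_missing_are_undetermined(self, poisson4):
        chrono, _ = mr.simulate_time_tree(4, 0, 100.0, seed=3)
        aln = mr.simulate_alignment(chrono, poisson4, 0.002, None, 50, seed=4)
        tree = chrono.with_lengths(chrono.lengths * 0.002, cls=PhyloTree)
        base = mr.log_likelihood(aln, tree, poisson4)
        sp = aln.labels[0]
        seqs = aln.to_dict()
        half = 25
        seqs[sp] = seqs[sp][:half] + "-" * 12 + "X" * 13
        withgaps = mr.log_likelihood(
            mr.ProteinAlignment.from_dict(seqs), tree, poisson4
        )
        assert withgaps > base  # undetermined sites can only raise site L
        # a fully undetermined tip equals pruning that tip out
        seqs[sp] = "X" * 50
        ll_blank = mr.log_likelihood(
            mr.ProteinAlignment.from_dict(seqs), tree, poisson4
        )
        pruned = chrono.prune_to([s for s in aln.labels if s != sp])
        tr2 = pruned.with_lengths(pruned.lengths * 0.002, cls=PhyloTree)
        ll_pruned = mr.log_likelihood(
            mr.ProteinAlignment.from_dict(
                {s: q for s, q in aln.to_dict().items() if s != sp}
            ),
            tr2, poisson4,
        )
        assert ll_blank == pytest.approx(ll_pruned, abs=1e-8)

    def test_rerooting_invariance(self, poisson4):
        chrono, _ = mr.simulate_time_tree(5, 0, 100.0, seed=5)
        aln = mr.simulate_alignment(chrono, poisson4, 0.003, None, 40, seed=6)
        tree = chrono.with_lengths(chrono.lengths * 0.003, cls=PhyloTree)
        base = mr.log_likelihood(aln, tree, poisson4)
        dt = tree.to_dendropy()
        for edge in list(dt.preorder_edge_iter())[3:5]:
            dt.reroot_at_edge(edge, length1=edge.length / 2,
                              length2=edge.length / 2,
                              update_bipartitions=False)
            rerooted = PhyloTree.from_dendropy(dt)
            assert mr.log_likelihood(aln, rerooted, poisson4) == \
                pytest.approx(base, abs=1e-8)
            break

    def test_species_mismatch_and_bad_lengths_error(self, poisson1):
        tree = PhyloTree([-1, 0, 0], [0.0, 0.1, 0.1], [None, "a", "zz"])
        msa = mr.ProteinAlignment.from_dict({"a": "A", "b": "A"})
        with pytest.raises(ValueError, match="zz"):
            mr.log_likelihood(msa, tree, poisson1)
        tree2 = PhyloTree([-1, 0, 0], [0.0, 0.1, 0.1], [None, "a", "b"])
        tree2.lengths[1] = np.nan
        with pytest.raises(ValueError, match="finite"):
            mr.log_likelihood(msa, tree2, poisson1)


class TestOptimizeBranchLengths:
    def test_identical_sequences_collapse_to_lower_bound(self, poisson1):
        chrono, _ = mr.simulate_time_tree(5, 0, 100.0, seed=8)
        msa = mr.ProteinAlignment.from_dict(
            {sp: "ARNDCQEGHILK" for sp in chrono.tip_labels}
        )
        fit = mr.optimize_branch_lengths(msa, chrono, poisson1)
        est = np.delete(fit.lengths, fit.root)
        assert np.all(est <= 1e-6)

    def test_two_taxon_closed_form(self, poisson1):
        chrono, _ = mr.simulate_time_tree(2, 0, 60.0, seed=1)
        aln = mr.simulate_alignment(chrono, poisson1, 0.003, None, 4000,
                                    seed=2)
        p = float(np.mean(aln.data[0] != aln.data[1]))
        expected = -(19 / 20) * np.log(1 - (20 / 19) * p)
        fit = mr.optimize_branch_lengths(aln, chrono, poisson1)
        assert float(np.delete(fit.lengths, fit.root).sum()) == \
            pytest.approx(expected, abs=1e-4)

    def test_loglik_not_below_start(self, poisson4):
        chrono, _ = mr.simulate_time_tree(6, 0, 150.0, seed=3)
        aln = mr.simulate_alignment(chrono, poisson4, 0.002, None, 300,
                                    seed=4)
        start = chrono.lengths * 0.001
        start[chrono.root] = 0.0
        ll_start = mr.log_likelihood(
            aln, chrono.with_lengths(start, cls=PhyloTree), poisson4
        )
        fit = mr.optimize_branch_lengths(aln, chrono, poisson4,
                                         initial_lengths=start)
        assert fit.log_likelihood >= ll_start - 1e-9


class TestSelectModel:
    def test_single_candidate_returned(self, poisson1):
        chrono, _ = mr.simulate_time_tree(4, 0, 80.0, seed=5)
        aln = mr.simulate_alignment(chrono, poisson1, 0.002, None, 100,
                                    seed=6)
        best, table, fitted = mr.select_model(
            aln, chrono, [poisson1], use_empirical_frequencies=False,
            tol=1e-3, max_rounds=5,
        )
        assert best.name == "Poisson"
        assert len(table) == 1
        assert fitted.log_likelihood == pytest.approx(
            table["log_likelihood"].iloc[0]
        )

    def test_true_model_selected_against_distinct_matrix(self, tmp_path):
        # synthetic "empirical-like" matrix: seeded random exchangeabilities,
        # strongly non-uniform, written/read via the PAML format
        rng = np.random.default_rng(42)
        S = rng.uniform(0.05, 1.0, (20, 20)) ** 3 * 10
        S = (S + S.T) / 2
        np.fill_diagonal(S, 0.0)
        pi = rng.dirichlet(np.full(20, 5.0))
        alt = mr.SubstitutionModel("synthEmpirical", S, pi, alpha=1.0,
                                   n_categories=2)
        write_paml_matrix(alt, tmp_path / "synth.dat")
        alt = mr.read_paml_matrix(tmp_path / "synth.dat",
                                  name="synthEmpirical", n_categories=2)
        poisson = mr.poisson_model(alpha=1.0, n_categories=2)
        wins = 0
        for seed in range(3):
            chrono, _ = mr.simulate_time_tree(6, 0, 150.0, seed=seed)
            aln = mr.simulate_alignment(chrono, alt, 0.004, None, 2000,
                                        seed=seed + 50)
            best, table, _ = mr.select_model(
                aln, chrono, [poisson, alt], tol=1e-2, max_rounds=4
            )
            wins += best.name == "synthEmpirical"
        assert wins == 3

    def test_table_consistent_with_direct_loglik(self, poisson1):
        chrono, _ = mr.simulate_time_tree(4, 0, 80.0, seed=7)
        aln = mr.simulate_alignment(chrono, poisson1, 0.002, None, 150,
                                    seed=8)
        best, table, fitted = mr.select_model(
            aln, chrono, [poisson1], use_empirical_frequencies=False,
            tol=1e-3, max_rounds=5,
        )
        direct = mr.log_likelihood(aln, fitted, best)
        assert direct == pytest.approx(table["log_likelihood"].iloc[0],
                                       abs=1e-6)
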