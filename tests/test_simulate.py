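import numpy as np
import pytest
from scipy.stats import chisquare

import mitorates as mr
from mitorates.trees import TimeTree


class TestTimeTreeSimulation:
    def test_requested_clades_marked_and_non_nested(self):
        tree, meta = mr.simulate_time_tree(30, 5, 500.0, seed=5)
        clades = meta.clades
        assert len(clades) == 5
        assert "hymenoptera" in clades
        # mutual non-nesting: clade tip sets are pairwise disjoint and each
        # clade's MRCA subtends exactly its own members
        names = list(clades)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert not (set(clades[a]) & set(clades[b]))
        tipidx = tree.tip_index()
        for name, members in clades.items():
            ids = {tipidx[m] for m in members}
            # find the MRCA by walking up from one member
            v = tipidx[members[0]]
            while not ids <= set(tree.clade_tips(v)):
                v = int(tree.parent[v])
            assert {tree.labels[t] for t in tree.clade_tips(v)} == set(members)

    def test_metadata_invariants_and_subgroups(self):
        _, meta = mr.simulate_time_tree(40, 5, 500.0, seed=9)
        df = meta.to_frame()
        hyms = df[df.group == "hymenoptera"]
        assert set(hyms.subgroup) == {"bees_ants", "sawflies_wasps"}
        assert (df[df.group != "hymenoptera"].subgroup == "none").all()
        assert (df[df.group == "diploid"].haplodiploidy_type == "none").all()
        others = df[df.group == "other_haplodiploid"]
        assert set(others.haplodiploidy_type) <= {"arrhenotoky", "PGE"}
        assert "PGE" in set(others.haplodiploidy_type)

    def test_impossible_clade_placement_is_explicit(self):
        with pytest.raises(ValueError, match="backbone"):
            mr.simulate_time_tree(7, 4, 100.0, seed=0)

    def test_meta_tsv_round_trip(self, tmp_path):
        _, meta = mr.simulate_time_tree(20, 3, 500.0, seed=2)
        meta.write_tsv(tmp_path / "meta.tsv")
        back = mr.SpeciesMeta.read_tsv(tmp_path / "meta.tsv")
        assert back.group == meta.group
        assert back.clades == meta.clades


class TestSequenceSimulation:
    def test_zero_rate_keeps_root_sequence(self, poisson4):
        tree, _ = mr.simulate_time_tree(8, 0, 200.0, seed=1)
        aln = mr.simulate_alignment(tree, poisson4, 0.0, None, 100, seed=3)
        rows = {aln.sequence(sp) for sp in aln.labels}
        assert len(rows) == 1

    def test_single_branch_matches_equal_rates_transition(self, poisson1):
        # cherry with all divergence on one side: expected subs t=0.1 between
        # the two tips; P(differ) = (19/20) (1 - exp(-20 t / 19))
        t = 0.1
        rate = 0.001
        tree = TimeTree([-1, 0, 0], [0.0, t / rate, 0.0], [None, "a", "b"],
                        check_ultrametric=False)
        n = 10_000
        aln = mr.simulate_alignment(tree, poisson1, rate, None, n, seed=11)
        p_obs = np.mean(aln.data[0] != aln.data[1])
        p_exp = (19 / 20) * (1 - np.exp(-20 * t / 19))
        se = np.sqrt(p_exp * (1 - p_exp) / n)
        assert abs(p_obs - p_exp) < 4 * se

    def test_mismatch_increases_with_rate(self, poisson4):
        tree, _ = mr.simulate_time_tree(6, 0, 150.0, seed=4)

        def mean_mismatch(rate, seed):
            aln = mr.simulate_alignment(tree, poisson4, rate, None, 400,
                                        seed=seed)
            d = aln.data
            vals = [
                np.mean(d[i] != d[j])
                for i in range(len(d))
                for j in range(i + 1, len(d))
            ]
            return np.mean(vals)

        lo = [mean_mismatch(0.0005, s) for s in range(20)]
        hi = [mean_mismatch(0.001, s) for s in range(20)]
        assert np.mean(hi) > np.mean(lo)
        assert np.mean([h > l for h, l in zip(hi, lo)]) >= 0.9

    def test_equilibrium_frequencies_on_long_star_branches(self):
        pi = np.linspace(1, 3, 20)
        pi /= pi.sum()
        model = mr.poisson_model(frequencies=pi, alpha=1.0, n_categories=1)
        tree = TimeTree(
            [-1, 0, 0, 0], [0.0, 400.0, 400.0, 400.0],
            [None, "a", "b", "c"],
        )
        aln = mr.simulate_alignment(tree, model, 0.02, None, 50_000, seed=5)
        counts = np.bincount(aln.data.ravel(), minlength=20)[:20]
        stat = chisquare(counts, pi * counts.sum())
        assert stat.pvalue > 0.01

    def test_clade_multiplier_accelerates_only_clade(self, poisson4):
        tree, meta = mr.simulate_time_tree(16, 2, 500.0, seed=6)
        aln = mr.simulate_alignment(
            tree, poisson4, 0.0015, {"hymenoptera": 3.0}, 3000, seed=7,
            clades=meta.clades,
        )
        root_like = aln.data  # compare hymenopteran vs diploid divergence
        hyms = meta.in_group("hymenoptera")
        dips = meta.in_group("diploid")
        d_h = np.mean(
            aln.data[aln.labels.index(hyms[0])]
            != aln.data[aln.labels.index(dips[0])]
        )
        d_d = np.mean(
            aln.data[aln.labels.index(dips[0])]
            != aln.data[aln.labels.index(dips[-1])]
        )
        assert d_h > d_d


class TestCopyNumbers:
    def test_no_turnover_keeps_root_count(self):
        tree, meta = mr.simulate_time_tree(10, 2, 300.0, seed=1)
        df = mr.simulate_copy_numbers(tree, 0.0, 0.0, 3, 5, seed=2, meta=meta)
        assert (df.to_numpy() == 3).all()

    def test_zero_root_count_is_absorbing(self):
        tree, _ = mr.simulate_time_tree(10, 0, 300.0, seed=1)
        df = mr.simulate_copy_numbers(tree, 0.5, 0.5, 0, 5, seed=2)
        assert (df.to_numpy() == 0).all()

    def test_biased_families_realize_group_contrast(self):
        tree, meta = mr.simulate_time_tree(30, 3, 500.0, seed=3)
        spec = mr.BiasSpec({"sawflies_wasps": 2, "bees_ants": 1},
                           n_families=30, name="bias")
        df = mr.simulate_copy_numbers(
            tree, 1e-4, 1e-4, 1, 0, [spec], seed=4, meta=meta
        )
        sw = meta.in_subgroup("sawflies_wasps")
        ba = meta.in_subgroup("bees_ants")
        ok = 0
        for fid in df.attrs["biased_families"]:
            row = df.loc[fid]
            if row[sw].median() == 2 and row[ba].median() == 1:
                ok += 1
        assert ok >= 0.9 * 30


class TestStudyBundle:
    def test_bundle_files_parse_by_downstream_modules(self, small_bundle,
                                                      tmp_path):
        small_bundle.write(tmp_path)
        tree = TimeTree.read_newick(tmp_path / "chronogram.nwk")
        assert set(tree.tip_labels) == set(small_bundle.tree.tip_labels)
        meta = mr.SpeciesMeta.read_tsv(tmp_path / "species_meta.tsv")
        assert meta.group == small_bundle.meta.group
        fastas = list((tmp_path / "orthogroups").glob("*.fasta"))
        assert len(fastas) == sum(
            len(v) for v in small_bundle.orthogroups.values()
        )
        g = mr.OrthologGroup.from_fasta(fastas[0])
        assert g.length > 0

    def test_truth_table_lists_configured_multipliers(self, small_bundle):
        truth = small_bundle.truth["multipliers"]
        mito = truth[truth.category == "mtOXPHOS"].set_index("clade")
        assert mito.loc["hymenoptera", "multiplier"] == 2.5
        ctrl = truth[truth.category == "nucControl"]
        assert (ctrl.multiplier == 1.0).all()

    def test_seed_changes_data_not_shapes(self):
        from conftest import small_study_config

        a = mr.simulate_study(small_study_config(seed=1))
        b = mr.simulate_study(small_study_config(seed=2))
        assert a.tree.n_tips == b.tree.n_tips
        for cat in a.category_alignments:
            assert (
                a.category_alignments[cat].n_sites
                == b.category_alignments[cat].n_sites
            )
            assert (
                a.category_alignments[cat].n_sequences
                == b.category_alignments[cat].n_sequences
            )
        assert a.category_alignments["mtOXPHOS"].to_dict() != \
            b.category_alignments["mtOXPHOS"].to_dict()

    def test_fixed_seed_is_byte_reproducible(self, tmp_path):
        from conftest import small_study_config

        a = mr.simulate_study(small_study_config(seed=5))
        b = mr.simulate_study(small_study_config(seed=5))
        assert a.tree.to_newick() == b.tree.to_newick()
        assert a.category_alignments["mtOXPHOS"].to_dict() == \
            b.category_alignments["mtOXPHOS"].to_dict()
        assert a.copy_numbers.equals(b.copy_numbers)
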