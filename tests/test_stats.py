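import numpy as np
import pandas as pd
import pytest

import mitorates as mr
from oracles import kruskal_H_by_hand, spearman_d2


class TestKruskalWallis:
    def test_hand_rank_example(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        res = mr.kruskal_wallis(groups)
        assert res.H == pytest.approx(7.2)
        assert res.H == pytest.approx(kruskal_H_by_hand(groups))
        assert res.df == 2

    def test_identical_values_degenerate_case(self):
        res = mr.kruskal_wallis([[5, 5, 5], [5, 5, 5], [5, 5, 5]])
        assert res.H == 0.0
        assert res.p_value == 1.0

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(size=7), rng.normal(1, 1, 6), rng.normal(2, 1, 8)]
        a = mr.kruskal_wallis(groups)
        b = mr.kruskal_wallis([np.exp(g) for g in groups])
        assert a.H == pytest.approx(b.H)
        assert a.p_value == pytest.approx(b.p_value)

    def test_matches_hand_formula_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            groups = [rng.integers(0, 5, rng.integers(3, 9)) for _ in range(3)]
            if len(np.unique(np.concatenate(groups))) < 2:
                continue
            res = mr.kruskal_wallis(groups)
            assert res.H == pytest.approx(kruskal_H_by_hand(groups))

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            mr.kruskal_wallis([[1, 2, 3]])


class TestKruskalPosthoc:
    def test_identical_groups_not_significant(self):
        res = mr.kruskal_posthoc([[1, 2, 3, 4], [1, 2, 3, 4]])
        assert not res["significant"].any()

    def test_widely_separated_groups_all_significant(self):
        res = mr.kruskal_posthoc(
            [list(range(1, 11)), list(range(101, 111)),
             list(range(201, 211))],
            alpha=0.05,
        )
        assert res["significant"].all()
        assert len(res) == 3

    def test_agrees_with_permutation_oracle(self):
        # permutation reference: two-sided p of |mean-rank difference| vs the
        # Siegel-Castellan threshold 2*alpha/(k(k-1))
        rng = np.random.default_rng(11)
        agree = total = 0
        for _ in range(50):
            sizes = rng.integers(4, 9, size=3)
            shift = rng.choice([0.0, 1.5, 3.0])
            groups = [
                rng.normal(i * shift / 2, 1, n) for i, n in enumerate(sizes)
            ]
            res = mr.kruskal_posthoc(groups, alpha=0.05)
            pooled = np.concatenate(groups)
            n = pooled.size
            idx = np.split(np.arange(n), np.cumsum(sizes)[:-1])
            from scipy.stats import rankdata

            obs_ranks = rankdata(pooled)
            obs = {
                (a, b): abs(obs_ranks[idx[a]].mean() - obs_ranks[idx[b]].mean())
                for a in range(3)
                for b in range(a + 1, 3)
            }
            nperm = 10_000
            perms = rng.permuted(
                np.tile(obs_ranks, (nperm, 1)), axis=1
            )
            perm_stats = {
                (a, b): np.abs(
                    perms[:, idx[a]].mean(axis=1)
                    - perms[:, idx[b]].mean(axis=1)
                )
                for (a, b) in obs
            }
            thr = 2 * 0.05 / (3 * 2)
            for row, key in zip(res.itertuples(), obs):
                pval = np.mean(perm_stats[key] >= obs[key] - 1e-12)
                total += 1
                agree += (pval < thr) == row.significant
        assert agree / total >= 0.95


class TestSpearman:
    def test_perfect_monotone(self):
        assert mr.spearman([1, 2, 3, 4], [10, 20, 30, 40]).rho == 1.0
        assert mr.spearman([1, 2, 3, 4], [9, 7, 5, 3]).rho == -1.0

    def test_d2_example(self):
        res = mr.spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.rho == pytest.approx(0.8)
        assert res.n == 5

    def test_equals_d2_formula_without_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(4, 20))
            x = rng.permutation(n).astype(float)
            y = rng.permutation(n).astype(float)
            assert mr.spearman(x, y).rho == pytest.approx(spearman_d2(x, y))

    def test_zero_variance_is_explicit_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            mr.spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestCategoryCorrelations:
    @staticmethod
    def rate_table(seed=0, n=16):
        chrono, meta, = mr.simulate_time_tree(n, 3, 500.0, seed=seed)
        rng = np.random.default_rng(seed)
        rows = []
        base = rng.uniform(0.001, 0.01, n)
        for cat, noise in [("mtOXPHOS", 0.0), ("nucOXPHOS", 5e-4),
                           ("nucControl", None)]:
            for i, sp in enumerate(chrono.tip_labels):
                r = (
                    rng.uniform(0.001, 0.01)
                    if noise is None
                    else base[i] + rng.normal(0, noise or 1e-9)
                )
                rows.append(
                    {"species": sp, "category": cat, "terminal_rate": r,
                     "root_to_tip_rate": r, "terminal_duration": 10.0,
                     "root_age": 500.0, "group": meta.group[sp],
                     "subgroup": meta.subgroup.get(sp, "none")}
                )
        return pd.DataFrame(rows)

    def test_reference_vs_itself_is_one_everywhere(self):
        tbl = self.rate_table()
        res = mr.category_correlations(tbl, "mtOXPHOS", ["mtOXPHOS"])
        ok = res.dropna(subset=["rho"])
        assert len(ok) >= 3
        assert np.allclose(ok["rho"], 1.0)

    def test_correlated_category_found_uncorrelated_not(self):
        tbl = self.rate_table(seed=3)
        res = mr.category_correlations(tbl, "mtOXPHOS")
        allrows = res[res.stratum == "all"].set_index("category")
        assert allrows.loc["nucOXPHOS", "rho"] > 0.8
        assert allrows.loc["nucOXPHOS", "p_value"] < 0.01
        assert abs(allrows.loc["nucControl", "rho"]) < 0.5

    def test_insufficient_overlap_is_note_not_error(self):
        tbl = self.rate_table()
        tbl = tbl[
            ~((tbl.category == "nucOXPHOS")
              & (tbl.group != "other_haplodiploid"))
        ]
        res = mr.category_correlations(tbl, "mtOXPHOS", ["nucOXPHOS"])
        row = res[(res.stratum == "diploid")].iloc[0]
        assert np.isnan(row["rho"])
        assert "insufficient" in row["note"]


class TestHymenopteranSubsample:
    def test_each_hymenopteran_used_exactly_once(self):
        _, meta = mr.simulate_time_tree(80, 5, 500.0, seed=13,
                                        hymenoptera_frac=0.3)
        hyms = meta.in_group("hymenoptera")
        assert len(hyms) == 24
        calls = []

        def stub(species):
            calls.append(list(species))
            return {sp: 1.0 for sp in species}

        res = mr.hymenopteran_subsample(meta, stub)
        assert len(res) == 24
        assert sorted(res["species"]) == sorted(hyms)
        non_h = set(meta.species) - set(hyms)
        for c in calls:
            assert len(set(c) & set(hyms)) == 1
            assert set(c) - set(hyms) == non_h

    def test_single_member_group(self):
        _, meta = mr.simulate_time_tree(12, 2, 300.0, seed=1)
        sp = meta.in_group("other_haplodiploid")
        assert len(sp) == 1
        res = mr.hymenopteran_subsample(
            meta, lambda s: {x: 2.0 for x in s}, group="other_haplodiploid"
        )
        assert len(res) == 1
        assert res["terminal_rate"].iloc[0] == 2.0

    def test_failures_recorded_not_fatal(self):
        _, meta = mr.simulate_time_tree(14, 2, 300.0, seed=2)
        bad = meta.in_group("hymenoptera")[0]

        def stub(species):
            if bad in species:
                raise RuntimeError("boom")
            return {sp: 1.0 for sp in species}

        with pytest.warns(UserWarning, match="failed"):
            res = mr.hymenopteran_subsample(meta, stub)
        assert np.isnan(
            res.set_index("species").loc[bad, "terminal_rate"]
        )
        assert res["terminal_rate"].notna().sum() == len(res) - 1


class TestMatchedControlSubsample:
    def test_target_equal_to_pool_returns_pool(self):
        presence = {f"g{i}": c for i, c in enumerate([3, 5, 5, 7, 9])}
        seen = []

        def stub(ids):
            seen.append(sorted(ids))
            return {"sp1": float(len(ids))}

        res = mr.matched_control_subsample(
            presence, list(presence.values()), stub, n_reps=5, seed=1
        )
        for ids in seen[1:]:  # first call is the full pool itself
            assert ids == sorted(presence)

    def test_replicate_spread_shrinks_with_matched_size(self):
        rng = np.random.default_rng(9)
        pool = {f"g{i}": int(c) for i, c in
                enumerate(rng.integers(5, 60, size=600))}
        values = {g: rng.normal(0, 1) for g in pool}

        def stub(ids):
            return {"sp": float(np.mean([values[g] for g in ids]))}

        def spread(k, seed):
            target = [pool[g] for g in list(pool)[:k]]
            res = mr.matched_control_subsample(
                pool, target, stub, n_reps=40, seed=seed
            )
            return res.groupby("replicate")["rate"].mean().std()

        assert spread(200, 3) < spread(20, 3)

    def test_pool_smaller_than_target_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            mr.matched_control_subsample(
                {"a": 1}, [1, 2], lambda ids: {}, n_reps=1
            )
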