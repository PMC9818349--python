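import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

import ssmpca as sp
from ssmpca.stats import _lilliefors_statistic, _mwu_exact_p


class TestLilliefors:
    def test_statistic_matches_statsmodels(self, rng):
        for _ in range(10):
            x = rng.standard_normal(25) * 3 + 1
            stat_sm, _ = sm_lilliefors(x, dist="norm")
            assert _lilliefors_statistic(x) == pytest.approx(stat_sm, abs=1e-12)

    def test_constant_sample_rejected(self):
        with pytest.raises(sp.DegeneracyError):
            sp.lilliefors_test([2.0, 2.0, 2.0, 2.0])

    def test_seeded_p_is_reproducible(self, rng):
        x = rng.standard_normal(20)
        a = sp.lilliefors_test(x, n_mc=2000, seed=5)
        b = sp.lilliefors_test(x, n_mc=2000, seed=5)
        assert a.p_value == b.p_value

    def test_null_calibration_at_n20(self):
        rng = np.random.default_rng(11)
        rejections = sum(
            sp.lilliefors_test(rng.standard_normal(20), n_mc=2000, seed=0).p_value < 0.05
            for _ in range(1000))
        assert rejections / 1000 == pytest.approx(0.05, abs=0.02)

    def test_bimodal_power(self):
        rejections = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = np.concatenate([rng.normal(-5, 1, 25), rng.normal(5, 1, 25)])
            rejections += sp.lilliefors_test(x, n_mc=2000, seed=0).p_value < 0.05
        assert rejections >= 190


class TestLeveneAnovaKruskal:
    def test_levene_zero_within_group_spread(self):
        r = sp.levene_test([[3.0, 3.0, 3.0], [7.0, 7.0]])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_levene_agrees_with_permutation_oracle(self):
        a, b = [1.0, 2, 3], [10.0, 20, 30]
        r = sp.levene_test([a, b])
        rng = np.random.default_rng(0)
        pooled = np.array(a + b)
        null = []
        for _ in range(5000):
            perm = rng.permutation(pooled)
            null.append(sp.levene_test([perm[:3], perm[3:]]).statistic)
        p_perm = np.mean(np.asarray(null) >= r.statistic - 1e-12)
        assert (r.p_value < 0.05) == (p_perm < 0.05)
        assert r.p_value == pytest.approx(p_perm, abs=0.06)

    def test_levene_invariant_to_within_group_permutation(self):
        r1 = sp.levene_test([[1.0, 5, 2], [4.0, 4, 9]])
        r2 = sp.levene_test([[2.0, 1, 5], [9.0, 4, 4]])
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_anova_equals_squared_pooled_t_for_two_groups(self):
        a, b = [1.0, 2, 3], [4.0, 5, 6]
        f = sp.oneway_anova([a, b])
        t, _ = sps.ttest_ind(a, b, equal_var=True)
        assert f.statistic == pytest.approx(t**2, rel=1e-8)
        assert f.statistic == pytest.approx(13.5, abs=1e-2)

    def test_anova_location_invariance(self, rng):
        groups = [rng.standard_normal(8), rng.standard_normal(6), rng.standard_normal(7)]
        f1 = sp.oneway_anova(groups).statistic
        f2 = sp.oneway_anova([g + 100 for g in groups]).statistic
        assert f1 == pytest.approx(f2, rel=1e-10)

    def test_anova_null_calibration(self):
        rng = np.random.default_rng(3)
        rej = sum(
            sp.oneway_anova([rng.standard_normal(10) for _ in range(3)]).p_value < 0.05
            for _ in range(1000))
        assert rej / 1000 == pytest.approx(0.05, abs=0.02)

    def test_kruskal_hand_example(self):
        r = sp.kruskal_wallis([[1.0, 2], [3.0, 4], [5.0, 6]])
        assert r.statistic == pytest.approx(4.571, abs=1e-3)

    def test_kruskal_rank_invariance_under_monotone_transform(self):
        groups = [[1.0, 4, 2], [8.0, 3], [9.0, 5, 7]]
        r1 = sp.kruskal_wallis(groups).statistic
        r2 = sp.kruskal_wallis([np.exp(g) for g in map(np.asarray, groups)]).statistic
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_kruskal_null_p_uniform(self):
        rng = np.random.default_rng(9)
        ps = [sp.kruskal_wallis([rng.standard_normal(8) for _ in range(3)]).p_value
              for _ in range(500)]
        # KS check against uniformity at Monte-Carlo resolution
        d, p = sps.kstest(ps, "uniform")
        assert p > 0.01

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(sp.DegeneracyError):
            sp.oneway_anova([[1.0, 1], [2.0, 2]])
        with pytest.raises(sp.DegeneracyError):
            sp.kruskal_wallis([[1.0, 1], [1.0, 1]])


class TestMannWhitney:
    def test_exact_enumeration_hand_example(self):
        r = sp.mann_whitney([1.0, 2], [3.0, 4])
        assert r.statistic == 0
        assert r.p_value == pytest.approx(1 / 3, abs=1e-3)

    def test_identical_multisets_give_half_max_u(self):
        r = sp.mann_whitney([1.0, 2, 3], [1.0, 2, 3])
        assert r.statistic == pytest.approx(4.5)

    def test_swap_symmetry(self, rng):
        a, b = rng.standard_normal(5), rng.standard_normal(4)
        r1, r2 = sp.mann_whitney(a, b), sp.mann_whitney(b, a)
        assert r1.statistic + r2.statistic == pytest.approx(20)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_exact_branch_matches_scipy_without_ties(self, rng):
        for _ in range(20):
            a, b = rng.standard_normal(5), rng.standard_normal(6)
            ours = sp.mann_whitney(a, b)
            u_sp, p_sp = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert ours.statistic == pytest.approx(u_sp)
            assert ours.p_value == pytest.approx(p_sp, abs=1e-12)

    def test_large_samples_use_tie_corrected_normal_approximation(self, rng):
        a = np.round(rng.standard_normal(15), 1)
        b = np.round(rng.standard_normal(15), 1)
        ours = sp.mann_whitney(a, b)
        u_sp, p_sp = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert ours.p_value == pytest.approx(p_sp, abs=1e-12)


class TestHolmSpearman:
    def test_holm_hand_example(self):
        np.testing.assert_allclose(sp.holm_adjust([0.01, 0.02, 0.04]), [0.03, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(sp.holm_adjust([0.2]), [0.2])

    def test_adjusted_at_least_raw_and_monotone(self, rng):
        p = rng.random(12)
        adj = sp.holm_adjust(p)
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(sp.StatValidationError):
            sp.holm_adjust([0.1, 1.2])

    def test_holm_fwer_on_all_null_family(self):
        rng = np.random.default_rng(21)
        fails = 0
        for _ in range(1000):
            groups = [rng.standard_normal(10) for _ in range(4)]
            pvals = [sps.ttest_ind(groups[i], groups[j], equal_var=True)[1]
                     for i in range(4) for j in range(i + 1, 4)]
            fails += np.any(sp.holm_adjust(pvals) < 0.05)
        assert fails / 1000 <= 0.07

    def test_spearman_perfect_monotone(self):
        assert sp.spearman_corr([1, 2, 3], [3, 2, 1]).statistic == pytest.approx(-1.0)
        assert sp.spearman_corr([1, 2, 3], [10, 100, 1000]).statistic == pytest.approx(1.0)

    def test_spearman_null_calibration(self):
        rng = np.random.default_rng(31)
        rej = sum(sp.spearman_corr(rng.standard_normal(30),
                                   rng.standard_normal(30)).p_value < 0.05
                  for _ in range(1000))
        assert rej / 1000 == pytest.approx(0.05, abs=0.02)


class TestCompareGroups:
    @staticmethod
    def table(groups_dict):
        rows = [{"subject_id": f"{g}{i}", "group": g, "z_score": v}
                for g, vals in groups_dict.items() for i, v in enumerate(vals)]
        return pd.DataFrame(rows)

    def test_monotone_groups_significant_and_uptrending(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            tbl = self.table({g: rng.normal(m, 1, 14)
                              for g, m in [("C", 0), ("nonDIP", 1), ("DIP", 2), ("PD", 3)]})
            rep = sp.compare_groups(tbl, n_mc=2000)
            means = [rep["group_means"][g] for g in ["C", "nonDIP", "DIP", "PD"]]
            hits += rep["omnibus"]["significant"] and np.all(np.diff(means) > 0)
        assert hits >= 9

    def test_null_omnibus_rate(self):
        rej = 0
        n_sim = 300
        for seed in range(n_sim):
            rng = np.random.default_rng(10_000 + seed)
            tbl = self.table({g: rng.normal(0, 1, 15) for g in "ABCD"})
            rej += sp.compare_groups(tbl, n_mc=2000)["omnibus"]["significant"]
        assert rej / n_sim == pytest.approx(0.05, abs=0.03)

    def test_two_groups_single_posthoc_pair(self, rng):
        tbl = self.table({"A": rng.normal(0, 1, 12), "B": rng.normal(2, 1, 12)})
        rep = sp.compare_groups(tbl, n_mc=2000)
        assert len(rep["posthoc"]) == 1

    def test_nonparametric_branch_taken_for_skewed_data(self, rng):
        tbl = self.table({"A": rng.lognormal(0, 2, 30), "B": rng.lognormal(0.1, 2, 30)})
        rep = sp.compare_groups(tbl, n_mc=2000)
        assert rep["branch"] == "nonparametric"
        assert rep["omnibus"]["test"] == "kruskal-wallis"

    def test_single_group_rejected(self, rng):
        with pytest.raises(sp.StatValidationError):
            sp.compare_groups(self.table({"A": rng.normal(0, 1, 10)}))


class TestCPZEquivalent:
    TABLE = {"haloperidol": 2.0, "risperidone": 1.0, "quetiapine": 0.5}

    def test_single_drug(self):
        assert sp.cpz_equivalent([sp.DoseRecord("haloperidol", 300)], self.TABLE) == 600

    def test_empty_list_is_zero(self):
        assert sp.cpz_equivalent([], self.TABLE) == 0

    def test_linear_sum(self):
        doses = [sp.DoseRecord("risperidone", 100), sp.DoseRecord("quetiapine", 400)]
        assert sp.cpz_equivalent(doses, self.TABLE) == 300

    def test_unknown_drug_named_in_error(self):
        with pytest.raises(KeyError, match="clozapine"):
            sp.cpz_equivalent([sp.DoseRecord("clozapine", 100)], self.TABLE)

    def test_ratio_table_round_trip(self, tmp_path):
        pd.DataFrame({"drug": ["haloperidol", "olanzapine"],
                      "multiplier": [2.0, 1.5],
                      "source": ["min-effective-dose", "consensus"]}
                     ).to_csv(tmp_path / "ratios.csv", index=False)
        table = sp.read_ratio_table(tmp_path / "ratios.csv")
        assert table == {"haloperidol": 2.0, "olanzapine": 1.5}
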