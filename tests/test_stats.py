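"""Statistics contracts: trend contrast, Kruskal-Dunn, Holm-Sidak, n-guard."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fiberquant import stats as fqs


def _table(*groups, labels=None):
    labels = labels or [f"g{i}" for i in range(len(groups))]
    return fqs.DoseGroupTable(group_labels=list(labels),
                              values=[np.asarray(g, float) for g in groups])


class TestAnovaLinearTrend:
    def test_identical_means_give_p_one(self):
        t = _table([1.0, 2.0, 3.0], [3.0, 2.0, 1.0], [2.0, 1.0, 3.0])
        res = fqs.anova_linear_trend(t)
        assert res.t_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_two_groups_equal_pooled_t_test(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 6), rng.normal(0.8, 1, 7)
        res = fqs.anova_linear_trend(_table(a, b))
        t_ref, p_ref = sps.ttest_ind(b, a, equal_var=True)
        assert res.p_value == pytest.approx(p_ref, rel=1e-10)
        assert abs(res.t_stat) == pytest.approx(abs(t_ref), rel=1e-10)

    def test_matches_permutation_oracle(self):
        # fixed seeded 4x5 dataset with a real slope; oracle = permutation
        # distribution of the trend t statistic (1e4 label permutations)
        rng = np.random.default_rng(11)
        groups = [rng.normal(0.45 * i, 1.0, 5) for i in range(4)]
        table = _table(*groups)
        res = fqs.anova_linear_trend(table)

        pooled = np.concatenate(groups)
        n = [len(g) for g in groups]
        edges = np.cumsum([0] + n)
        c = fqs.trend_coefficients(4)

        def t_of(values):
            gs = [values[edges[i]:edges[i + 1]] for i in range(4)]
            means = np.array([g.mean() for g in gs])
            sse = sum(((g - g.mean()) ** 2).sum() for g in gs)
            mse = sse / (len(values) - 4)
            return (c * means).sum() / np.sqrt(mse * (c ** 2 / np.array(n)).sum())

        t_obs = t_of(pooled)
        perm_rng = np.random.default_rng(99)
        hits = sum(abs(t_of(perm_rng.permutation(pooled))) >= abs(t_obs)
                   for _ in range(10_000))
        p_perm = hits / 10_000
        mc_sd = np.sqrt(max(p_perm, 1e-4) * (1 - p_perm) / 10_000)
        assert res.p_value == pytest.approx(p_perm, abs=max(0.02, 4 * mc_sd))

    def test_null_type_one_error_near_nominal(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_sims = 2000
        for _ in range(n_sims):
            groups = [rng.normal(0, 1, 8) for _ in range(4)]
            if fqs.anova_linear_trend(_table(*groups)).p_value < 0.05:
                rejections += 1
        assert 0.035 <= rejections / n_sims <= 0.065

    def test_power_increases_with_slope(self):
        rng = np.random.default_rng(21)
        rates = []
        for slope in (0.0, 0.4, 0.8):
            rej = 0
            for _ in range(400):
                groups = [rng.normal(slope * i, 1.0, 6) for i in range(4)]
                rej += fqs.anova_linear_trend(_table(*groups)).p_value < 0.05
            rates.append(rej / 400)
        assert rates[0] < rates[1] < rates[2]

    def test_contrast_invariant_to_constant_shift(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(i, 1, 5) for i in range(3)]
        a = fqs.anova_linear_trend(_table(*groups))
        shifted = [g + 100.0 for g in groups]
        b = fqs.anova_linear_trend(_table(*shifted))
        assert a.t_stat == pytest.approx(b.t_stat)
        assert a.p_value == pytest.approx(b.p_value)
        assert fqs.trend_coefficients(5).sum() == pytest.approx(0.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fqs.anova_linear_trend(_table([1.0, 2.0], []))


class TestKruskalDunn:
    def test_identical_values_all_p_one(self):
        res = fqs.kruskal_dunn(_table([5.0] * 4, [5.0] * 4))
        assert res.h_stat == 0.0
        assert all(p == 1.0 for p in res.p_adjusted)

    def test_separated_groups_match_hand_computed_z(self):
        # ranks 1..5 vs 6..10: mean ranks 3 and 8,
        # z = (3 - 8) / sqrt((N(N+1)/12) * (1/5 + 1/5))
        res = fqs.kruskal_dunn(_table([1, 2, 3, 4, 5], [6, 7, 8, 9, 10]))
        se = np.sqrt((10 * 11 / 12) * (1 / 5 + 1 / 5))
        assert res.z_stats[0] == pytest.approx(-5.0 / se)

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(13)
        rejections = 0
        n_sims = 500
        for _ in range(n_sims):
            groups = [rng.normal(0, 1, 10) for _ in range(3)]
            if fqs.kruskal_dunn(_table(*groups)).h_p_value < 0.05:
                rejections += 1
        rate = rejections / n_sims
        assert 0.02 <= rate <= 0.08   # 0.05 +- ~3 Monte-Carlo SD

    def test_requested_pairs_only_and_bonferroni_family(self):
        rng = np.random.default_rng(17)
        t = _table(rng.normal(0, 1, 6), rng.normal(1, 1, 6),
                   rng.normal(2, 1, 6), labels=["a", "b", "c"])
        full = fqs.kruskal_dunn(t)
        assert len(full.comparisons) == 3
        one = fqs.kruskal_dunn(t, comparisons=[("a", "c")])
        assert len(one.p_adjusted) == 1
        # same z, smaller family -> no larger adjusted p
        idx = full.comparisons.index(("a", "c"))
        assert one.z_stats[0] == pytest.approx(full.z_stats[idx])
        assert one.p_adjusted[0] <= full.p_adjusted[idx] + 1e-12


class TestHolmSidak:
    def test_single_comparison_unadjusted(self):
        assert fqs.holm_sidak([0.03]) == [pytest.approx(0.03)]

    def test_monotone_in_step_down_order(self):
        p = [0.001, 0.04, 0.02, 0.5, 0.3]
        adj = fqs.holm_sidak(p)
        order = np.argsort(p)
        stepped = [adj[i] for i in order]
        assert all(a <= b + 1e-12 for a, b in zip(stepped, stepped[1:]))
        assert all(a >= r for a, r in zip(adj, p))

    def test_first_step_is_sidak_of_smallest(self):
        p = [0.01, 0.2, 0.3]
        adj = fqs.holm_sidak(p)
        assert adj[0] == pytest.approx(1 - (1 - 0.01) ** 3)


class TestTwoWayHolmSidak:
    @staticmethod
    def _ecc_frame(group_offsets, n_per_group=5, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, off in group_offsets.items():
            for subj in range(n_per_group):
                for step in range(1, 11):
                    drop = 100.0 - off * (step - 1)
                    rows.append({"group": g, "step": step,
                                 "subject": f"{g}{subj}",
                                 "value": drop + rng.normal(0, 2)})
        return pd.DataFrame(rows)

    def test_identical_groups_nothing_significant(self):
        df = self._ecc_frame({"ctrl": 0.0, "treated": 0.0}, seed=1)
        res = fqs.twoway_holm_sidak(df)
        assert (res.per_step["p_adj"] > 0.05).all()

    def test_separated_groups_detected_at_late_steps(self):
        df = self._ecc_frame({"ctrl": 6.0, "treated": 0.5}, seed=2)
        res = fqs.twoway_holm_sidak(df)
        late = res.per_step[res.per_step["step"] == "10"]
        assert (late["p_adj"] < 0.05).all()

    def test_adjusted_never_below_raw(self):
        df = self._ecc_frame({"a": 2.0, "b": 0.0, "c": 1.0}, seed=3)
        res = fqs.twoway_holm_sidak(df)
        assert (res.per_step["p_adj"] >= res.per_step["p_raw"] - 1e-12).all()

    def test_subject_ids_enable_repeated_measures(self):
        df = self._ecc_frame({"a": 3.0, "b": 0.0}, seed=4)
        res = fqs.twoway_holm_sidak(df, subject_col="subject")
        assert res.repeated_measures
        assert not res.notes


class TestSmallNGuard:
    def test_n_three_skipped(self):
        t = _table([1, 2, 3], [4, 5, 6])
        decision = fqs.small_n_guard(t)
        assert not decision.analyzed

    def test_n_four_analyzed(self):
        t = _table([1, 2, 3, 4], [4, 5, 6, 7])
        assert fqs.small_n_guard(t).analyzed

    def test_mixed_names_offender(self):
        t = _table([1, 2, 3, 4, 5], [4, 5], labels=["low", "high"])
        decision = fqs.small_n_guard(t)
        assert not decision.analyzed
        assert decision.offending_groups == ["high"]


class TestStars:
    @pytest.mark.parametrize("p,stars", [
        (0.2, "ns"), (0.04, "*"), (0.005, "**"), (0.0005, "***"),
        (0.00005, "****"),
    ])
    def test_figure_legend_convention(self, p, stars):
        assert fqs.p_to_stars(p) == stars
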