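import numpy as np
import pandas as pd
import pytest

from vpcoupling.group_stats import TestResult as StatResult
from vpcoupling.group_stats import (
    bonferroni_pairwise,
    mixed_anova,
    one_sample_t,
    pearson_corr,
)


def split_plot_oracle(y):
    """Textbook split-plot formulas for a 2-group x n-subject x 2-level design.

    ``y[g][s][w]``; independent of the Möbius margin machinery in the
    implementation.  Returns F for (group, within, within x group).
    """
    y = np.asarray(y, float)
    g_n, s_n, w_n = y.shape
    grand = y.mean()
    m_g = y.mean(axis=(1, 2))
    m_gs = y.mean(axis=2)
    m_w = y.mean(axis=(0, 1))
    m_gw = y.mean(axis=1)
    ss_g = s_n * w_n * np.sum((m_g - grand) ** 2)
    ss_sg = w_n * np.sum((m_gs - m_g[:, None]) ** 2)
    ss_w = g_n * s_n * np.sum((m_w - grand) ** 2)
    ss_wg = s_n * np.sum(
        (m_gw - m_g[:, None] - m_w[None, :] + grand) ** 2
    )
    resid = y - m_gs[:, :, None] - m_gw[:, None, :] + m_g[:, None, None]
    ss_err = np.sum(resid**2)
    df_sg, df_err = g_n * (s_n - 1), g_n * (s_n - 1) * (w_n - 1)
    return (
        (ss_g / (g_n - 1)) / (ss_sg / df_sg),
        (ss_w / (w_n - 1)) / (ss_err / df_err),
        (ss_wg / ((g_n - 1) * (w_n - 1))) / (ss_err / df_err),
    )


def long_format(y):
    rows = []
    for g in range(y.shape[0]):
        for s in range(y.shape[1]):
            for w in range(y.shape[2]):
                rows.append(
                    {
                        "subject": f"g{g}s{s}",
                        "group": f"g{g}",
                        "w": f"w{w}",
                        "y": y[g, s, w],
                    }
                )
    return pd.DataFrame(rows)


class TestOneSampleT:
    def test_symmetric_values_give_zero(self):
        assert one_sample_t([-2.0, -1.0, 1.0, 2.0]).statistic == pytest.approx(0.0)

    def test_hand_computed_example(self):
        res = one_sample_t([1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(2.0 / (1.0 / np.sqrt(3)), rel=1e-6)
        assert res.df == (2,)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([5.0, 5.0])


class TestPearson:
    def test_perfect_correlation(self):
        assert pearson_corr([1, 2, 3], [2, 4, 6]).statistic == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        res = pearson_corr([-1, 0, 1, 0], [0, 1, 0, -1])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        res = pearson_corr([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.statistic == pytest.approx(0.6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr([1, 1, 1], [1, 2, 3])


class TestBonferroni:
    def test_identical_cells_nonsignificant(self, rng):
        v = rng.normal(size=10)
        res = bonferroni_pairwise({"a": v, "b": v}, paired=True)
        assert res[0].p == 1.0

    def test_three_cells_three_comparisons_scaled(self, rng):
        from scipy import stats

        cells = {k: rng.normal(size=8) for k in "abc"}
        res = bonferroni_pairwise(cells)
        assert len(res) == 3
        raw = stats.ttest_ind(cells["a"], cells["b"]).pvalue
        assert res[0].p == pytest.approx(min(raw * 3, 1.0))

    def test_only_planted_pair_significant(self, rng):
        cells = {
            "a": rng.normal(0, 1, 20),
            "b": rng.normal(0, 1, 20),
            "c": rng.normal(5, 1, 20),
        }
        res = {r.effect: r.p for r in bonferroni_pairwise(cells)}
        assert res["a vs b"] > 0.05
        assert res["a vs c"] < 0.05 and res["b vs c"] < 0.05


class TestMixedAnova:
    def test_matches_textbook_split_plot_oracle(self, rng):
        y = rng.normal(size=(2, 6, 2)) + np.array([0.0, 1.0])[None, None, :]
        f_g, f_w, f_wg = split_plot_oracle(y)
        res = {r.effect: r for r in mixed_anova(long_format(y), "y", "subject", "group", ["w"])}
        assert res["group"].statistic == pytest.approx(f_g)
        assert res["w"].statistic == pytest.approx(f_w)
        assert res["w * group"].statistic == pytest.approx(f_wg)
        assert res["group"].df == (1, 10)
        assert res["w"].df == (1, 10)

    def test_matches_pingouin_three_level_within(self, rng):
        pg = pytest.importorskip("pingouin")
        y = rng.normal(size=(2, 9, 3))
        df = long_format(y)
        mine = {r.effect: r for r in mixed_anova(df, "y", "subject", "group", ["w"])}
        ref = pg.mixed_anova(
            data=df, dv="y", within="w", subject="subject", between="group"
        ).set_index("Source")
        assert mine["group"].statistic == pytest.approx(ref.loc["group", "F"])
        assert mine["w"].statistic == pytest.approx(ref.loc["w", "F"])
        assert mine["w * group"].statistic == pytest.approx(ref.loc["Interaction", "F"])
        assert mine["w"].p == pytest.approx(ref.loc["w", "p_unc"])

    def test_flat_data_gives_zero_f(self):
        y = np.zeros((2, 4, 2))
        y += np.arange(4)[None, :, None]  # subject offsets only
        res = mixed_anova(long_format(y), "y", "subject", "group", ["w"])
        for r in res:
            assert r.statistic == pytest.approx(0.0, abs=1e-20)

    def test_single_group_within_f_equals_paired_t_squared(self, rng):
        from scipy import stats

        y = rng.normal(size=(1, 12, 2))
        df = long_format(y)
        res = mixed_anova(df, "y", "subject", "group", ["w"])
        assert len(res) == 1
        t = stats.ttest_rel(y[0, :, 0], y[0, :, 1])
        assert res[0].statistic == pytest.approx(t.statistic**2)
        assert res[0].p == pytest.approx(t.pvalue)

    def test_group_effect_power_grows_with_effect_size(self, rng):
        # only the group F should grow when a pure group shift is planted
        f_group, f_w = [], []
        for shift in (0.0, 2.0):
            y = rng.normal(size=(2, 10, 2))
            y[1] += shift
            res = {r.effect: r for r in mixed_anova(long_format(y), "y", "subject", "group", ["w"])}
            f_group.append(res["group"].statistic)
            f_w.append(res["w"].statistic)
        assert f_group[1] > 10 * f_group[0]
        assert f_w[1] < 10 * max(f_w[0], 1.0)

    def test_four_way_design_runs_with_expected_effects(self, rng):
        rows = []
        for g in range(2):
            for s in range(5):
                for a in range(2):
                    for b in range(2):
                        for c in range(2):
                            rows.append(
                                {
                                    "subject": f"g{g}s{s}",
                                    "group": f"g{g}",
                                    "a": a, "b": b, "c": c,
                                    "y": rng.normal(),
                                }
                            )
        res = mixed_anova(pd.DataFrame(rows), "y", "subject", "group", ["a", "b", "c"])
        # 1 between + 7 within combos x 2 (effect, effect x group)
        assert len(res) == 15
        for r in res:
            assert 0.0 <= r.p <= 1.0
            assert r.df[0] == 1 and r.df[1] == 8

    def test_unbalanced_design_rejected(self, rng):
        y = rng.normal(size=(2, 4, 2))
        df = long_format(y).iloc[:-1]  # drop one cell
        with pytest.raises(ValueError):
            mixed_anova(df, "y", "subject", "group", ["w"])

    def test_gg_correction_only_inflates_p(self, rng):
        # with a real within effect (F > 1) shrinking both df's raises p
        y = rng.normal(size=(2, 9, 4)) + np.arange(4)[None, None, :] * 0.5
        df = long_format(y)
        plain = {r.effect: r.p for r in mixed_anova(df, "y", "subject", "group", ["w"])}
        gg = {r.effect: r.p for r in mixed_anova(df, "y", "subject", "group", ["w"], correction="gg")}
        assert gg["w"] >= plain["w"] - 1e-12


class TestResultType:
    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            StatResult("x", 1.0, (1,), 1.5)
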