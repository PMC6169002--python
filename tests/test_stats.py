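"""Surrogate testing, repeated-measures ANOVA and correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cmcoupling import (
    EmbeddingSpec,
    gen_coupled_ar,
    pearson_corr,
    rm_anova,
    summarize_conditions,
    surrogate_test,
)
from cmcoupling.stats import holm_correction

FS = 2000.0
SPEC = EmbeddingSpec(d=1, tau=1, u=10.0, k=4, theiler=5)


def brute_force_rm_anova(x):
    """Independent SS computation by explicit loops (s subjects x c conds)."""
    s, c = x.shape
    gm = x.mean()
    ss_cond = sum(s * (x[:, j].mean() - gm) ** 2 for j in range(c))
    ss_subj = sum(c * (x[i, :].mean() - gm) ** 2 for i in range(s))
    ss_tot = sum((x[i, j] - gm) ** 2 for i in range(s) for j in range(c))
    ss_err = ss_tot - ss_cond - ss_subj
    f = (ss_cond / (c - 1)) / (ss_err / ((c - 1) * (s - 1)))
    return f


def long_table(x):
    s, c = x.shape
    return pd.DataFrame(
        [
            {"subject": i, "condition": f"c{j}", "value": x[i, j]}
            for i in range(s) for j in range(c)
        ]
    )


class TestRmAnova:
    def test_no_effect_gives_f_zero(self):
        x = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 4))
        res = rm_anova(long_table(x))
        assert res.F == 0.0 and res.p_value == 1.0

    def test_matches_brute_force_on_fixture(self):
        # 4 subjects x 3 conditions
        x = np.array(
            [
                [5.0, 7.0, 9.0],
                [4.0, 6.0, 7.0],
                [6.0, 9.0, 10.0],
                [5.0, 8.0, 9.0],
            ]
        )
        res = rm_anova(long_table(x))
        assert res.F == pytest.approx(brute_force_rm_anova(x), abs=1e-10)
        assert res.df_condition == 2 and res.df_error == 6

    def test_matches_statsmodels(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(5)
        x = rng.normal(size=(6, 4)) + rng.normal(size=(6, 1))
        table = long_table(x)
        ours = rm_anova(table)
        sm = AnovaRM(table, depvar="value", subject="subject",
                     within=["condition"]).fit()
        f_sm = float(sm.anova_table["F Value"].iloc[0])
        p_sm = float(sm.anova_table["Pr > F"].iloc[0])
        assert ours.F == pytest.approx(f_sm, rel=1e-8)
        assert ours.p_value == pytest.approx(p_sm, rel=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.integers(2, 6), st.integers(2, 5),
        st.integers(0, 2**31 - 1),
    )
    def test_agrees_with_brute_force_on_random_tables(self, s, c, seed):
        x = np.random.default_rng(seed).normal(size=(s, c))
        res = rm_anova(long_table(x))
        assert res.F == pytest.approx(brute_force_rm_anova(x), abs=1e-10)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            rm_anova(long_table(np.array([[1.0, 2.0, 3.0]])))

    def test_missing_cell_named_in_error(self):
        table = long_table(np.ones((3, 3))).drop(index=4)
        with pytest.raises(ValueError, match="missing cells"):
            rm_anova(table)

    def test_trial_replicates_averaged_per_cell(self):
        x = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        t1 = long_table(x)
        # duplicating every row with +-delta leaves cell means unchanged
        t2 = pd.concat([t1.assign(value=t1.value + 0.5),
                        t1.assign(value=t1.value - 0.5)])
        a, b = rm_anova(t1), rm_anova(t2)
        assert a.F == pytest.approx(b.F, rel=1e-12)


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        res = pearson_corr(x, 2 * x + 1)
        assert res.rho == pytest.approx(1.0)
        assert res.p_value < 1e-10

    def test_independent_gaussians_small_rho(self):
        rng = np.random.default_rng(3)
        res = pearson_corr(rng.standard_normal(100), rng.standard_normal(100))
        assert abs(res.rho) < 0.3  # |r| >= 0.3 has prob < 1% under the null

    def test_rho_squared(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(50)
        y = x + rng.standard_normal(50)
        res = pearson_corr(x, y)
        assert res.rho_squared == pytest.approx(res.rho**2)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr(np.array([1.0, 2.0]), np.array([1.0, 2.0]))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr(np.ones(10), np.arange(10.0))


class TestSummarize:
    def test_hand_arithmetic(self):
        t = pd.DataFrame({"condition": ["a"] * 3, "value": [1.0, 2.0, 3.0]})
        out = summarize_conditions(t)
        assert out.loc["a", "mean"] == 2.0
        assert out.loc["a", "sd"] == 1.0
        assert out.loc["a", "n"] == 3

    def test_single_value_flagged_degenerate(self):
        t = pd.DataFrame({"condition": ["a"], "value": [5.0]})
        out = summarize_conditions(t)
        assert out.loc["a", "sd"] == 0.0
        assert bool(out.loc["a", "degenerate"])

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(11)
        rows = []
        for subj in range(9):
            for cond in range(5):
                rows.append({"condition": cond,
                             "value": rng.normal(cond, 1.0)})
        t = pd.DataFrame(rows)
        out = summarize_conditions(t)
        for cond in range(5):
            vals = t[t.condition == cond].value.to_numpy()
            assert out.loc[cond, "mean"] == pytest.approx(vals.mean())
            assert out.loc[cond, "sd"] == pytest.approx(vals.std(ddof=1))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_conditions(pd.DataFrame({"condition": [], "value": []}))


class TestSurrogates:
    def test_strong_coupling_detected(self):
        x, y = gen_coupled_ar(3000, c_xy=0.8, lag=20, seed=1)
        res = surrogate_test(x, y, SPEC, n_surrogates=39, fs=FS, seed=0)
        assert res.p_value <= 0.05
        assert len(res.surrogate_values) == 39

    def test_null_p_rarely_small(self):
        # on uncoupled data small p-values occur at roughly the nominal rate
        rejections = 0
        for data_seed in range(8):
            rng = np.random.default_rng(100 + data_seed)
            x, y = rng.standard_normal(1200), rng.standard_normal(1200)
            res = surrogate_test(x, y, SPEC, n_surrogates=19, fs=FS,
                                 seed=data_seed)
            rejections += res.p_value <= 0.05
        assert rejections <= 2

    def test_reproducible(self):
        x, y = gen_coupled_ar(1500, c_xy=0.5, lag=20, seed=2)
        a = surrogate_test(x, y, SPEC, fs=FS, seed=3)
        b = surrogate_test(x, y, SPEC, fs=FS, seed=3)
        assert a.p_value == b.p_value
        assert np.array_equal(a.surrogate_values, b.surrogate_values)

    def test_too_few_surrogates_rejected(self):
        with pytest.raises(ValueError):
            surrogate_test(np.zeros(100), np.zeros(100), SPEC,
                           n_surrogates=0, fs=FS)

    def test_bias_corrected_value(self):
        x, y = gen_coupled_ar(1500, c_xy=0.5, lag=20, seed=4)
        res = surrogate_test(x, y, SPEC, fs=FS, seed=5)
        assert res.bias_corrected_value == pytest.approx(
            res.value - np.mean(res.surrogate_values)
        )


class TestHolm:
    def test_monotone_and_bounded(self):
        p = [0.01, 0.04, 0.03, 0.5]
        adj = holm_correction(p)
        assert np.all(adj >= p)
        assert np.all(adj <= 1.0)
        assert adj[0] == pytest.approx(0.04)
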