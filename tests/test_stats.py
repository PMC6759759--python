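"""Blocked ANOVA, Tukey HSD and Welch's t against oracles and statsmodels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from phageres.stats import (
    AliasedTermError,
    blocked_anova,
    tukey_hsd,
    welch_t,
)


def one_factor(groups: dict[str, list[float]]) -> pd.DataFrame:
    rows = [
        {"y": v, "g": name} for name, values in groups.items() for v in values
    ]
    return pd.DataFrame(rows)


class TestBlockedAnova:
    def test_hand_computed_toy(self):
        # SSB = 1.5, SSW = 4 on (1, 4) df
        res = blocked_anova(one_factor({"a": [1, 2, 3], "b": [2, 3, 4]}), "y", ["g"])
        term = res.term("g")
        assert term.sum_sq == pytest.approx(1.5)
        assert res.residual_ss == pytest.approx(4.0)
        assert term.F == pytest.approx(1.5)
        assert (term.df, res.residual_df) == (1, 4)

    def test_constant_response_all_F_zero(self):
        res = blocked_anova(one_factor({"a": [2, 2, 2], "b": [2, 2, 2]}), "y", ["g"])
        assert res.term("g").F == 0.0 and res.term("g").p == 1.0

    def test_aliased_term_reported(self):
        df = one_factor({"a": [1, 2, 3], "b": [2, 3, 4]})
        df["g2"] = df["g"]  # perfect copy of g -> no new rank
        with pytest.raises(AliasedTermError, match="g2"):
            blocked_anova(df, "y", ["g", "g2"])

    def test_saturated_model_rejected(self):
        df = one_factor({"a": [1.0], "b": [2.0], "c": [3.0]})
        with pytest.raises(ValueError, match="observations"):
            blocked_anova(df, "y", ["g"])

    @settings(max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_sum_of_squares_conservation(self, seed):
        rng = np.random.default_rng(seed)
        n = 24
        df = pd.DataFrame(
            {
                "y": rng.normal(size=n),
                "a": rng.choice(["x", "y", "z"], n),
                "b": rng.choice(["u", "v"], n),
            }
        )
        if df["a"].nunique() < 2 or df["b"].nunique() < 2:
            return
        res = blocked_anova(df, "y", ["a", "b"])
        assert sum(t.sum_sq for t in res.terms) + res.residual_ss == pytest.approx(
            res.total_ss
        )

    @settings(max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_balanced_type1_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        levels_a, levels_b, reps = ["a1", "a2", "a3"], ["b1", "b2"], 3
        rows = [
            {"y": rng.normal(), "a": a, "b": b}
            for a in levels_a
            for b in levels_b
            for _ in range(reps)
        ]
        df = pd.DataFrame(rows)
        ab = blocked_anova(df, "y", ["a", "b"])
        ba = blocked_anova(df, "y", ["b", "a"])
        assert ab.term("a").sum_sq == pytest.approx(ba.term("a").sum_sq)
        assert ab.term("b").sum_sq == pytest.approx(ba.term("b").sum_sq)

    def test_matches_statsmodels_type1_on_unbalanced_data(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(42)
        df = pd.DataFrame(
            {
                "y": rng.normal(size=30),
                "a": rng.choice(["x", "y", "z"], 30, p=[0.5, 0.3, 0.2]),
                "b": rng.choice(["u", "v"], 30, p=[0.7, 0.3]),
            }
        )
        mine = blocked_anova(df, "y", ["a", "b"])
        sm_tab = sm.stats.anova_lm(smf.ols("y ~ C(a) + C(b)", df).fit(), typ=1)
        assert mine.term("a").sum_sq == pytest.approx(sm_tab.loc["C(a)", "sum_sq"])
        assert mine.term("b").sum_sq == pytest.approx(sm_tab.loc["C(b)", "sum_sq"])
        assert mine.residual_ss == pytest.approx(sm_tab.loc["Residual", "sum_sq"])
        assert mine.term("b").F == pytest.approx(sm_tab.loc["C(b)", "F"])

    def test_interaction_term(self):
        rng = np.random.default_rng(3)
        rows = [
            {"y": rng.normal() + (1.0 if (a == "a2" and b == "b2") else 0.0),
             "a": a, "b": b}
            for a in ("a1", "a2")
            for b in ("b1", "b2")
            for _ in range(5)
        ]
        df = pd.DataFrame(rows)
        res = blocked_anova(df, "y", ["a", "b", "a:b"])
        assert res.term("a:b").df == 1
        assert sum(t.sum_sq for t in res.terms) + res.residual_ss == pytest.approx(
            res.total_ss
        )

    def test_power_on_planted_effect(self):
        """delta=1, sigma=0.3, 6/cell balanced two-factor: detected in >=95%."""
        hits, n_runs = 0, 200
        for seed in range(n_runs):
            rng = np.random.default_rng(20_000 + seed)
            rows = [
                {
                    "y": rng.normal(scale=0.3) + (1.0 if t == "t2" else 0.0),
                    "t": t,
                    "block": b,
                }
                for t in ("t1", "t2")
                for b in ("b1", "b2", "b3")
                for _ in range(6)
            ]
            res = blocked_anova(pd.DataFrame(rows), "y", ["block", "t"])
            if res.term("t").p < 0.01:
                hits += 1
        assert hits >= 0.95 * n_runs


class TestTukey:
    def test_two_levels_equal_pooled_t(self):
        df = one_factor({"a": [1.0, 2.0, 3.5], "b": [2.0, 4.0, 5.0, 6.0]})
        res = blocked_anova(df, "y", ["g"])
        (cmp,) = tukey_hsd(res, "g", df, "y")
        t, p = sps.ttest_ind(
            df.loc[df.g == "a", "y"], df.loc[df.g == "b", "y"], equal_var=True
        )
        assert cmp.q == pytest.approx(np.sqrt(2) * abs(t))
        assert cmp.p_adj == pytest.approx(p, abs=1e-9)

    def test_identical_level_means_p_one(self):
        df = one_factor({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        res = blocked_anova(df, "y", ["g"])
        (cmp,) = tukey_hsd(res, "g", df, "y")
        assert cmp.diff == 0.0 and cmp.p_adj == pytest.approx(1.0)

    def test_separation_limit_three_levels(self):
        eps = 1e-4
        df = one_factor(
            {"a": [0.0, eps, -eps], "b": [0.0, eps, -eps], "c": [5.0, 5.0 + eps, 5.0 - eps]}
        )
        res = blocked_anova(df, "y", ["g"])
        by_pair = {(c.level_a, c.level_b): c for c in tukey_hsd(res, "g", df, "y")}
        assert by_pair[("a", "c")].p_adj < 1e-6
        assert by_pair[("b", "c")].p_adj < 1e-6
        assert by_pair[("a", "b")].p_adj > 0.999

    def test_antisymmetric_diffs_and_summary_oracle(self):
        rng = np.random.default_rng(8)
        df = one_factor(
            {k: list(rng.normal(size=n)) for k, n in (("a", 5), ("b", 7), ("c", 4))}
        )
        res = blocked_anova(df, "y", ["g"])
        comparisons = tukey_hsd(res, "g", df, "y")
        means = df.groupby("g")["y"].mean()
        ns = df.groupby("g")["y"].size()
        mse = res.residual_mean_sq
        for c in comparisons:
            assert c.diff == pytest.approx(
                means[c.level_b] - means[c.level_a], abs=1e-10
            )
            assert c.se == pytest.approx(
                np.sqrt(mse * (1 / ns[c.level_a] + 1 / ns[c.level_b])), abs=1e-10
            )

    def test_p_matches_statsmodels_pairwise_tukeyhsd(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(9)
        df = one_factor({k: list(rng.normal(size=6)) for k in ("a", "b", "c")})
        res = blocked_anova(df, "y", ["g"])
        mine = tukey_hsd(res, "g", df, "y")
        sm_res = pairwise_tukeyhsd(df["y"], df["g"])
        for c, p_sm in zip(mine, sm_res.pvalues):
            assert c.p_adj == pytest.approx(p_sm, abs=1e-6)

    def test_unfitted_factor_rejected(self):
        df = one_factor({"a": [1, 2, 3], "b": [2, 3, 4]})
        res = blocked_anova(df, "y", ["g"])
        with pytest.raises(KeyError):
            tukey_hsd(res, "other", df, "y")


class TestWelch:
    def test_closed_form_toy(self):
        res = welch_t([1, 2, 3], [2, 4, 6])
        assert res.t == pytest.approx(-1.549, abs=1e-3)
        assert res.df == pytest.approx(2.94, abs=0.01)

    def test_identical_samples(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_antisymmetry(self):
        a, b = [1.0, 2.5, 3.0, 4.0], [2.0, 4.0, 6.5]
        ab, ba = welch_t(a, b), welch_t(b, a)
        assert ab.t == pytest.approx(-ba.t)
        assert ab.df == pytest.approx(ba.df)
        assert ab.p == pytest.approx(ba.p)

    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=12), rng.normal(1.0, 2.0, size=9)
        mine = welch_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert mine.t == pytest.approx(ref.statistic)
        assert mine.p == pytest.approx(ref.pvalue)
        assert mine.df == pytest.approx(ref.df)

    def test_zero_variance_undefined(self):
        res = welch_t([1.0, 1.0], [2.0, 2.0])
        assert res.undefined and np.isnan(res.t)
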