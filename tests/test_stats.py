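"""Mixed ANOVA sums of squares, GG epsilon, effect sizes, follow-up tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from chronoerp.stats import (
    StatResult,
    UnbalancedDesignError,
    format_result,
    mixed_anova,
    oneway_anova,
    pairwise_bonferroni,
    partial_eta_squared,
    pearson_r,
    sums_of_squares,
)


def long_table(rng, n_per_group=4, groups=("g1", "g2", "g3"), lev1=("a", "b", "c"),
               lev2=None, effect=0.0):
    rows = []
    sid = 0
    for g in groups:
        for _ in range(n_per_group):
            sid += 1
            subj_off = rng.normal(0, 2)
            for i, l1 in enumerate(lev1):
                for l2 in (lev2 or ["_"]):
                    val = subj_off + rng.normal(0, 1) + effect * i * (g == "g1")
                    row = {"subject": f"s{sid}", "group": g, "w1": l1, "value": val}
                    if lev2:
                        row["w2"] = l2
                    rows.append(row)
    return pd.DataFrame(rows)


class TestPartialEtaSquared:
    @pytest.mark.parametrize(
        "F, df1, df2, expected",
        [(67.8, 2, 44, 0.755), (26.9, 3, 43, 0.652), (0.0, 2, 10, 0.0)],
    )
    def test_values(self, F, df1, df2, expected):
        assert partial_eta_squared(F, df1, df2) == pytest.approx(expected, abs=5e-4)

    def test_monotone_in_F(self):
        vals = [partial_eta_squared(F, 2, 44) for F in (0.5, 1.0, 5.0, 50.0)]
        assert vals == sorted(vals)


class TestMixedAnova:
    def test_within_effect_zero_when_levels_identical(self):
        rng = np.random.default_rng(0)
        rows = []
        for g in ("g1", "g2"):
            for s in range(4):
                base = rng.normal(0, 3)
                for l1 in ("a", "b", "c"):
                    rows.append({"subject": f"{g}{s}", "group": g, "w1": l1, "value": base})
        res = {r.effect: r for r in mixed_anova(pd.DataFrame(rows), within=["w1"])}
        assert res["w1"].F == pytest.approx(0.0, abs=1e-18)

    def test_two_level_within_has_epsilon_one(self):
        rng = np.random.default_rng(1)
        t = long_table(rng, lev1=("a", "b"))
        res = {r.effect: r for r in mixed_anova(t, within=["w1"])}
        assert res["w1"].gg_epsilon == 1.0

    def test_matches_pingouin_one_within(self):
        import pingouin as pg

        rng = np.random.default_rng(2)
        t = long_table(rng, effect=1.5)
        ours = {r.effect: r for r in mixed_anova(t, within=["w1"])}
        theirs = pg.mixed_anova(t, dv="value", within="w1", subject="subject", between="group")
        pg_map = {"group": "Group", "w1": "w1", "Interaction": "w1*Group"}
        for key, eff in pg_map.items():
            row = theirs[theirs["Source"] == key].iloc[0]
            assert ours[eff].F == pytest.approx(row["F"], rel=1e-9)
            assert ours[eff].p_uncorrected == pytest.approx(row["p_unc"], rel=1e-9)

    def test_epsilon_matches_pingouin(self):
        """The GG epsilon formula agrees with pingouin on the same covariance."""
        import pingouin as pg

        from chronoerp.stats import _gg_epsilon, _helmert

        rng = np.random.default_rng(3)
        wide = pd.DataFrame(rng.standard_normal((12, 4)) @ rng.standard_normal((4, 4)),
                            columns=list("abcd"))
        S = np.cov(wide.to_numpy().T, ddof=1)
        ours = _gg_epsilon(S, _helmert(4))
        theirs = float(pg.epsilon(wide, correction="gg"))
        assert ours == pytest.approx(theirs, rel=1e-9)

    def test_two_within_against_hand_decomposition(self):
        """Brute-force cell-mean sums of squares, written out independently."""
        rng = np.random.default_rng(4)
        t = long_table(rng, n_per_group=4, lev1=("a", "b", "c"), lev2=("x", "y"), effect=1.0)
        res = {r.effect: r for r in mixed_anova(t, within=["w1", "w2"])}

        groups, l1s, l2s = ["g1", "g2", "g3"], ["a", "b", "c"], ["x", "y"]
        subj = {g: sorted(t.loc[t.group == g, "subject"].unique()) for g in groups}
        n, a, b = 4, 3, 2

        def cell(g=None, s=None, w1=None, w2=None):
            q = t
            for col, v in (("group", g), ("subject", s), ("w1", w1), ("w2", w2)):
                if v is not None:
                    q = q[q[col] == v]
            return q["value"].mean()

        mu = cell()
        ss_w1 = len(groups) * n * b * sum((cell(w1=l) - mu) ** 2 for l in l1s)
        ss_w1g = b * n * sum(
            (cell(g=g, w1=l) - cell(w1=l) - cell(g=g) + mu) ** 2 for g in groups for l in l1s
        )
        ss_w1s = b * sum(
            (cell(s=s, w1=l) - cell(g=g, w1=l) - cell(s=s) + cell(g=g)) ** 2
            for g in groups for s in subj[g] for l in l1s
        )
        ss_w1w2 = len(groups) * n * sum(
            (cell(w1=l1, w2=l2) - cell(w1=l1) - cell(w2=l2) + mu) ** 2
            for l1 in l1s for l2 in l2s
        )
        assert res["w1"].ss_effect == pytest.approx(ss_w1, rel=1e-9)
        assert res["w1*Group"].ss_effect == pytest.approx(ss_w1g, rel=1e-9)
        assert res["w1"].ss_error == pytest.approx(ss_w1s, rel=1e-9)
        assert res["w1*w2"].ss_effect == pytest.approx(ss_w1w2, rel=1e-9)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(seed=st_.integers(0, 1000))
    def test_sums_of_squares_conserved(self, seed):
        rng = np.random.default_rng(seed)
        t = long_table(rng, lev1=("a", "b", "c"), effect=0.7)
        parts = sums_of_squares(t, within=["w1"])
        total = parts.pop("_total")
        comp = sum(v for k, v in parts.items())
        assert comp == pytest.approx(total, rel=1e-9)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(seed=st_.integers(0, 1000))
    def test_gg_epsilon_bounds(self, seed):
        rng = np.random.default_rng(seed)
        k = 4
        t = long_table(rng, n_per_group=6, lev1=tuple("abcd"))
        res = {r.effect: r for r in mixed_anova(t, within=["w1"])}
        eps = res["w1"].gg_epsilon
        assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_unbalanced_raises(self):
        rng = np.random.default_rng(5)
        t = long_table(rng)
        t = t.drop(index=t.index[0])
        with pytest.raises(UnbalancedDesignError):
            mixed_anova(t, within=["w1"])

    def test_missing_cells_excluded_listwise(self, caplog):
        rng = np.random.default_rng(6)
        t = long_table(rng)
        t.loc[t.index[0], "value"] = np.nan
        res = mixed_anova(t, within=["w1"])  # excluded subject, still balanced
        assert all(np.isfinite(r.F) for r in res)


class TestFollowUps:
    def test_bonferroni_adjustment_caps_at_one(self):
        rng = np.random.default_rng(7)
        frames = []
        for lvl, shift in (("a", 0.0), ("b", 2.0), ("c", 0.1)):
            frames.append(pd.DataFrame({
                "subject": [f"s{i}" for i in range(8)],
                "cond": lvl,
                "value": rng.normal(shift, 1, 8),
            }))
        data = pd.concat(frames)
        out = pairwise_bonferroni(data, "cond", [("a", "b"), ("a", "c"), ("b", "c")], dv="value")
        m = 3
        for _, row in out.iterrows():
            assert row["p_bonferroni"] == pytest.approx(min(1.0, row["p_uncorrected"] * m))

    def test_paired_t_against_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.2, 1.8, 3.5, 3.9, 5.4])
        d = x - y
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        data = pd.DataFrame({
            "subject": list(range(5)) * 2,
            "cond": ["a"] * 5 + ["b"] * 5,
            "value": np.concatenate([x, y]),
        })
        out = pairwise_bonferroni(data, "cond", [("a", "b")], dv="value")
        assert out.loc[0, "t"] == pytest.approx(t_oracle, rel=1e-12)

    def test_identical_samples_give_p_one(self):
        x = np.arange(5.0)
        data = pd.DataFrame({
            "subject": list(range(5)) * 2,
            "cond": ["a"] * 5 + ["b"] * 5,
            "value": np.concatenate([x, x]),
        })
        out = pairwise_bonferroni(data, "cond", [("a", "b")], dv="value")
        assert out.loc[0, "p_uncorrected"] == 1.0

    def test_oneway_anova_effect_size(self):
        rng = np.random.default_rng(8)
        res = oneway_anova({g: rng.normal(i, 1, 10) for i, g in enumerate("abc")})
        assert res.df_effect == 2 and res.df_error == 27
        assert 0 <= res.partial_eta_sq <= 1


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(5), np.arange(5.0))

    def test_p_value_matches_t_transform(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(30)
        y = x + rng.standard_normal(30)
        r, p = pearson_r(x, y)
        from scipy import stats as sps

        t = r * np.sqrt(28 / (1 - r**2))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), 28), rel=1e-9)


def test_format_result_reads_like_a_results_section():
    r = StatResult("Response", 67.8, 2, 44, 1e-10, 0.9, 2e-9, 0.752)
    s = format_result(r)
    assert "F(2, 44) = 67.80" in s and "eta_p^2 = 0.75" in s
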