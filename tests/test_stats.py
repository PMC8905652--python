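"""t-tests, ANOVA partitioning, sphericity correction, effect size, power."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from anova_oracle import mixed_anova_oracle, rm_anova_oracle
from syllastream import stats as st


class TestOneSampleT:
    @pytest.mark.parametrize("mean,sd,n,expected_t", [
        (61.4, 20.12, 21, 2.596),   # explicit high-TP cell
        (65.5, 20.08, 21, 3.537),   # explicit low-TP cell
    ])
    def test_from_summary_cells(self, mean, sd, n, expected_t):
        res = st.one_sample_t_from_summary(mean, sd, n, mu=50.0)
        assert res.t == pytest.approx(expected_t, abs=0.001)
        assert res.df == n - 1
        assert 0 < res.p < 0.05

    def test_all_at_chance(self):
        res = st.one_sample_t([50.0] * 10)
        assert res.t == 0.0 and res.p == 1.0

    def test_matches_scipy(self, rng):
        from scipy import stats as sps

        x = rng.normal(55, 10, size=15)
        mine = st.one_sample_t(x, mu=50.0)
        t, p = sps.ttest_1samp(x, 50.0)
        assert mine.t == pytest.approx(t) and mine.p == pytest.approx(p)

    def test_zero_variance_convention(self):
        res = st.one_sample_t([60.0, 60.0, 60.0])
        assert res.t == math.inf and res.p == 0.0

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            st.one_sample_t([50.0])


class TestEffectSizeAndPower:
    @pytest.mark.parametrize("F,df1,df2,eta", [
        (4.791, 1, 39, 0.109),
        (11.979, 1, 39, 0.235),
    ])
    def test_partial_eta_examples(self, F, df1, df2, eta):
        assert st.partial_eta_sq(F, df1, df2) == pytest.approx(eta, abs=0.001)

    def test_partial_eta_zero(self):
        assert st.partial_eta_sq(0.0, 1, 39) == 0.0

    @pytest.mark.parametrize("F,df1,df2,pw", [
        (4.791, 1, 39, 0.569),
        (11.979, 1, 39, 0.921),
    ])
    def test_observed_power_examples(self, F, df1, df2, pw):
        assert st.observed_power(F, df1, df2) == pytest.approx(pw, abs=0.005)

    def test_power_limits(self):
        assert st.observed_power(0.0, 1, 39) == pytest.approx(0.05)
        assert st.observed_power(1000.0, 1, 39) == pytest.approx(1.0, abs=1e-6)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(p=hst.floats(0, 1), m=hst.integers(1, 20))
    def test_bonferroni_properties(self, p, m):
        adj = st.bonferroni(p, m)
        assert adj == min(1.0, m * p)
        assert st.bonferroni(p, 1) == p


class TestGGEpsilon:
    def test_compound_symmetry_gives_one(self):
        cov = 0.5 * np.ones((4, 4)) + 2.0 * np.eye(4)
        assert st.gg_epsilon(cov) == pytest.approx(1.0)

    def test_two_levels_trivially_one(self):
        assert st.gg_epsilon(np.array([[1.0, 0.2], [0.2, 2.0]])) == 1.0

    def test_violating_covariance_matches_formula(self):
        """Direct evaluation of the defining formula on a constructed
        3-level covariance violating sphericity."""
        S = np.array([[4.0, 1.0, 0.5],
                      [1.0, 2.0, 0.3],
                      [0.5, 0.3, 1.0]])
        k = 3
        # textbook form on the double-centered covariance
        Sc = S - S.mean(0) - S.mean(1)[:, None] + S.mean()
        eps_direct = (np.trace(Sc) ** 2 /
                      ((k - 1) * (Sc * Sc).sum()))
        assert st.gg_epsilon(S) == pytest.approx(eps_direct, abs=1e-12)
        assert st.gg_epsilon(S) < 1.0


def long_format(Y, factor_names, group=None):
    rows = []
    it = np.ndindex(*Y.shape)
    for idx in it:
        row = {"subject": f"s{idx[0]}", "y": Y[idx]}
        if group is not None:
            row["subject"] = f"{group}_s{idx[0]}"
            row["group"] = group
        for name, level in zip(factor_names, idx[1:]):
            row[name] = f"{name}{level}"
        rows.append(row)
    return pd.DataFrame(rows)


class TestRMAnova:
    def test_2x2x2_matches_definitional_oracle(self, rng):
        Y = rng.normal(size=(6, 2, 2, 2)) + rng.normal(size=(6, 1, 1, 1))
        table = st.rm_anova(long_format(Y, ["task", "tp", "half"]),
                            dv="y", within=["task", "tp", "half"]
                            ).set_index("effect")
        oracle = rm_anova_oracle(Y, ["task", "tp", "half"])
        for effect, (ss, ss_err, df1, df2, F) in oracle.items():
            row = table.loc[effect]
            assert row.SS == pytest.approx(ss, abs=1e-9)
            assert row.SS_error == pytest.approx(ss_err, abs=1e-9)
            assert (row.df1, row.df2) == (df1, df2)
            assert row.F == pytest.approx(F, abs=1e-9)

    def test_matches_pingouin_two_within(self, rng):
        import pingouin as pg

        Y = rng.normal(size=(8, 2, 3))
        df = long_format(Y, ["A", "B"])
        mine = st.rm_anova(df, dv="y", within=["A", "B"]).set_index("effect")
        theirs = pg.rm_anova(data=df, dv="y", within=["A", "B"],
                             subject="subject", detailed=True)
        for _, r in theirs.iterrows():
            row = mine.loc[r["Source"].replace("Interaction", "A * B")
                           if r["Source"] == "Interaction" else r["Source"]]
            assert row.F == pytest.approx(r["F"], rel=1e-9)
            assert row.SS == pytest.approx(r["SS"], rel=1e-9)

    def test_factor_order_symmetry(self, rng):
        Y = rng.normal(size=(5, 2, 2))
        df = long_format(Y, ["A", "B"])
        t1 = st.rm_anova(df, dv="y", within=["A", "B"]).set_index("effect")
        t2 = st.rm_anova(df, dv="y", within=["B", "A"]).set_index("effect")
        for effect in ("A", "B"):
            assert t1.loc[effect, "SS"] == pytest.approx(
                t2.loc[effect, "SS"], rel=1e-12)
        assert t1.loc["A * B", "F"] == pytest.approx(
            t2.loc["B * A", "F"], rel=1e-12)

    def test_all_two_level_effects_have_unit_epsilon(self, rng):
        Y = rng.normal(size=(6, 2, 2, 2))
        table = st.rm_anova(long_format(Y, ["a", "b", "c"]), dv="y",
                            within=["a", "b", "c"])
        assert (table["eps"] == 1.0).all()


class TestMixedAnova:
    def _toy(self, rng, n=5):
        Ys = [rng.normal(size=(n, 2, 2)) + (0.8 if g else 0.0)
              + rng.normal(size=(n, 1, 1)) for g in range(2)]
        df = pd.concat([long_format(Y, ["task", "tp"], group=f"g{g}")
                        for g, Y in enumerate(Ys)], ignore_index=True)
        return Ys, df

    def test_matches_definitional_oracle(self, rng):
        Ys, df = self._toy(rng)
        table = st.mixed_anova(df, dv="y", between="group",
                               within=["task", "tp"]).set_index("effect")
        oracle = mixed_anova_oracle(Ys, "group", ["task", "tp"])
        for effect, (ss, ss_err, df1, df2, F) in oracle.items():
            row = table.loc[effect]
            assert row.SS == pytest.approx(ss, abs=1e-9)
            assert row.SS_error == pytest.approx(ss_err, abs=1e-9)
            assert (row.df1, row.df2) == (df1, df2)
            assert row.F == pytest.approx(F, abs=1e-9)

    def test_matches_pingouin_balanced_one_within(self, rng):
        import pingouin as pg

        rows = []
        for g in range(2):
            for i in range(7):
                base = rng.normal()
                for j, w in enumerate(["w0", "w1", "w2"]):
                    rows.append(dict(subject=f"g{g}s{i}", group=f"g{g}", w=w,
                                     y=base + 0.4 * j + rng.normal()))
        df = pd.DataFrame(rows)
        mine = st.mixed_anova(df, dv="y", between="group",
                              within=["w"]).set_index("effect")
        theirs = pg.mixed_anova(data=df, dv="y", within="w",
                                subject="subject", between="group").set_index(
                                    "Source")
        assert mine.loc["group", "F"] == pytest.approx(
            theirs.loc["group", "F"], rel=1e-9)
        assert mine.loc["w", "F"] == pytest.approx(
            theirs.loc["w", "F"], rel=1e-9)
        assert mine.loc["group * w", "F"] == pytest.approx(
            theirs.loc["Interaction", "F"], rel=1e-9)

    def test_location_invariance(self, rng):
        _, df = self._toy(rng)
        t1 = st.mixed_anova(df, dv="y", between="group", within=["task", "tp"])
        df2 = df.assign(y=df["y"] + 100.0)
        t2 = st.mixed_anova(df2, dv="y", between="group", within=["task", "tp"])
        np.testing.assert_allclose(t1["F"], t2["F"], rtol=1e-8)

    def test_eta_identity(self, rng):
        """partial_eta_sq(F, df1, df2) == SS / (SS + SS_error), row by row."""
        _, df = self._toy(rng)
        table = st.mixed_anova(df, dv="y", between="group",
                               within=["task", "tp"])
        for _, r in table.iterrows():
            assert st.partial_eta_sq(r.F, r.df1, r.df2) == pytest.approx(
                r.SS / (r.SS + r.SS_error), rel=1e-9)
            assert r.eta_p2 == pytest.approx(r.SS / (r.SS + r.SS_error))

    def test_missing_cell_named(self, rng):
        _, df = self._toy(rng)
        df = df[~((df.task == "task0") & (df.tp == "tp1"))]
        with pytest.raises(ValueError, match="cell"):
            st.mixed_anova(df, dv="y", between="group", within=["task", "tp"])

    def test_effect_size_recovery(self, rng):
        """Mean estimated eta_p^2 over replicates of the model's own data
        approaches an independently simulated design value."""
        delta, sigma, n = 1.0, 1.0, 12

        def etas(n_reps, generator):
            out = []
            for _ in range(n_reps):
                eff = np.array([-delta / 2, delta / 2])
                Y = (generator.normal(0, 1, size=(n, 1))
                     + eff[None, :] + generator.normal(0, sigma, size=(n, 2)))
                # direct definitional eta on the difference scores
                z = (Y[:, 1] - Y[:, 0]) / np.sqrt(2)
                ss_eff = n * z.mean() ** 2
                ss_err = ((z - z.mean()) ** 2).sum()
                out.append(ss_eff / (ss_eff + ss_err))
            return np.mean(out)

        design_value = etas(4000, np.random.default_rng(1))
        # now through the package's rm_anova on 200 replicates
        gen = np.random.default_rng(2)
        vals = []
        for _ in range(200):
            eff = np.array([-delta / 2, delta / 2])
            Y = (gen.normal(0, 1, size=(n, 1)) + eff[None, :]
                 + gen.normal(0, sigma, size=(n, 2)))
            table = st.rm_anova(long_format(Y.reshape(n, 2), ["A"]),
                                dv="y", within=["A"])
            vals.append(table.loc[table.effect == "A", "eta_p2"].item())
        mc_se = np.std(vals) / np.sqrt(len(vals))
        assert np.mean(vals) == pytest.approx(design_value, abs=3 * mc_se + 0.01)


class TestPairwise:
    def test_adjustment_and_difference(self, rng):
        rows = []
        for i in range(10):
            base = rng.normal()
            for j, lv in enumerate(["a", "b", "c"]):
                rows.append(dict(subject=i, f=lv, y=base + 0.5 * j + rng.normal()))
        out = st.pairwise_bonferroni(pd.DataFrame(rows), dv="y", factor="f")
        assert len(out) == 3
        assert (out["p_adj"] >= out["p_raw"]).all()
        assert (out["p_adj"] <= 1.0).all()
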