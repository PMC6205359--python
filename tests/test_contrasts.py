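"""Design building, nested F tests, ANCOVA models and the Δβ contrast."""

import numpy as np
import pandas as pd
import pytest

import pollsel as ps
from pollsel.contrasts import _ancova_frame, _model_spec
from pollsel.errors import GroupError, ValidationError


class TestBuildDesign:
    def test_factor_covariate_interaction_column_count(self):
        df = pd.DataFrame({"g": ["a", "a", "b", "b"] * 3, "x": np.arange(12.0), "y": 1.0})
        spec = ps.ModelSpec(
            "y", ["x"], {"g": ["a", "b"]},
            {"g": [("g",)], "x": [("x",)], "x:g": [("x", "g")]},
        )
        X, labels, blocks = ps.build_design(df, spec)
        assert X.shape[1] == 4  # intercept, g[b], x, x:g[b]
        assert labels == ["intercept", "g[b]", "x", "x:g[b]"]

    def test_four_level_factor_times_five_covariates_gives_fifteen(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({f"t{i}": rng.standard_normal(40) for i in range(5)})
        df["pop"] = np.repeat(["p1", "p2", "p3", "p4"], 10)
        df["y"] = 1.0
        spec = ps.ModelSpec(
            "y", [f"t{i}" for i in range(5)], {"pop": ["p1", "p2", "p3", "p4"]},
            {"tp": [(f"t{i}", "pop") for i in range(5)]},
        )
        X, labels, blocks = ps.build_design(df, spec)
        assert len(blocks["tp"]) == 15

    def test_matches_hand_built_toy_design(self):
        df = pd.DataFrame(
            {"g": ["a", "b", "a", "b", "a", "b"], "x": [1.0, 2, 3, 4, 5, 6], "y": 0.0}
        )
        spec = ps.ModelSpec(
            "y", ["x"], {"g": ["a", "b"]},
            {"g": [("g",)], "x": [("x",)], "x:g": [("x", "g")]},
        )
        X, _, _ = ps.build_design(df, spec)
        dummy = np.array([0, 1, 0, 1, 0, 1], float)
        expected = np.column_stack([np.ones(6), dummy, df["x"], df["x"] * dummy])
        np.testing.assert_array_equal(X, expected)


class TestTestBlock:
    def test_identical_models_give_f_zero_p_one(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 3))
        y = rng.standard_normal(30)
        fit = ps.fit_ols(y, X)
        res = ps.test_block(fit, fit)
        assert res["F"] == 0.0 and res["p"] == 1.0

    def test_single_column_f_equals_t_squared(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((50, 4))
        y = X @ [0.3, 0, -0.2, 0.1] + rng.standard_normal(50)
        full = ps.fit_ols(y, X, names=list("abcd"))
        reduced = ps.fit_ols(y, X[:, :3], names=list("abc"))
        res = ps.test_block(full, reduced)
        t = full.t[full.names.index("d")]
        assert res["F"] == pytest.approx(t**2, rel=1e-10)
        assert res["p"] == pytest.approx(full.p[full.names.index("d")], rel=1e-10)

    def test_null_block_p_values_are_uniform(self):
        """Under a true null the nested-F p-value is U(0,1)."""
        from scipy import stats

        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(500):
            X = rng.standard_normal((40, 5))
            y = X[:, 0] * 0.5 + rng.standard_normal(40)
            full = ps.fit_ols(y, X)
            reduced = ps.fit_ols(y, X[:, :2])
            pvals.append(ps.test_block(full, reduced)["p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_non_nested_models_rejected(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 3))
        y = rng.standard_normal(30)
        fit_a = ps.fit_ols(y, X[:, :2], names=["a", "b"])
        fit_b = ps.fit_ols(y, X[:, 1:], names=["b", "c"])
        with pytest.raises(ValidationError):
            ps.test_block(fit_b, fit_a)


class TestAncovaModels:
    def test_model_a_denominator_df_matches_design(self, default_cohort):
        """739 open-pollination rows minus 45 parameters = 694."""
        res = ps.ancova_model_a(default_cohort)
        assert res.nobs == 739 and res.df_resid == 694

    def test_model_b_denominator_df_matches_design(self, default_cohort):
        """1485 rows minus 86 parameters = 1399."""
        res = ps.ancova_model_b(default_cohort)
        assert res.nobs == 1485 and res.df_resid == 1399
        assert res.row("corolla_tube_length x morph x pollination")["df_num"] == 1
        assert res.row("trait x population x pollination")["df_num"] == 15

    def test_model_b_without_pollination_terms_reduces_to_model_a(self, default_cohort):
        """On C-only rows the shared blocks give identical F values."""
        res_a = ps.ancova_model_a(default_cohort)
        sub = default_cohort.subset_treatment("C")
        frame = _ancova_frame(sub, ps.TRAITS)
        spec = _model_spec(sub, ps.TRAITS, with_pollination=False)
        X, labels, blocks = ps.build_design(frame, spec)
        full = ps.fit_ols(frame["relative_fitness"].to_numpy(), X, names=labels,
                          add_intercept=False)
        assert full.rss == pytest.approx(res_a.rss, rel=1e-12)

    def test_morph_specific_slope_detected_with_power(self):
        """A corolla-tube-length gradient present in one morph only is
        flagged by its trait x morph term at paper-scale n."""
        hits = 0
        n_runs = 25
        for seed in range(n_runs):
            cfg = ps.default_config()
            for key, p in cfg.cells.items():
                beta = np.zeros(5)
                if key.morph == "L":
                    beta[3] = -0.25
                p.beta_C = beta
                p.beta_HP = beta
            table = ps.simulate_cohort(cfg, seed=100 + seed)
            res = ps.ancova_model_a(table)
            if res.row("corolla_tube_length x morph")["p"] < 0.05:
                hits += 1
        assert hits / n_runs >= 0.8

    def test_sequential_and_marginal_agree_on_last_block(self, toy_table):
        rng = np.random.default_rng(5)
        df = toy_table.df.copy()
        df["female_fitness"] = rng.uniform(10, 100, len(df))
        table = ps.StudyTable(df)
        m = ps.factorial_anova(table, "plant_height", ["morph", "treatment"], test_type="marginal")
        s = ps.factorial_anova(table, "plant_height", ["morph", "treatment"], test_type="sequential")
        last = "morph x treatment"
        assert m.row(last)["F"] == pytest.approx(s.row(last)["F"], rel=1e-10)


class TestDeltaBeta:
    def test_duplicated_arms_give_exact_zero(self, default_cohort):
        df = default_cohort.group(ps.GroupKey("BGTC1", "L", "C")).copy()
        dup = df.copy()
        dup["treatment"] = "HP"
        dup["individual_id"] = dup["individual_id"] + "-hp"
        table = ps.StudyTable(pd.concat([df, dup], ignore_index=True))
        grads = ps.estimate_gradients(table)
        delta = ps.delta_beta(grads, table)
        np.testing.assert_allclose(delta["delta_beta"], 0.0, atol=1e-12)

    def test_subtraction_equals_interaction_coefficient(self, default_cohort, default_gradients):
        delta = ps.delta_beta(default_gradients, default_cohort)
        np.testing.assert_allclose(
            delta["delta_beta"], delta["interaction_coef"], atol=1e-10
        )

    def test_missing_arm_names_group(self, default_cohort):
        df = default_cohort.df
        df = df[~((df.population == "PNP2") & (df.morph == "S") & (df.treatment == "HP"))]
        table = ps.StudyTable(df)
        with pytest.raises(GroupError, match="PNP2"):
            ps.delta_beta(ps.estimate_gradients(table), table)

    def test_row_order_does_not_change_statistics(self, default_cohort, default_gradients):
        delta = ps.delta_beta(default_gradients, default_cohort)
        shuffled = ps.StudyTable(
            default_cohort.df.sample(frac=1.0, random_state=0),
            populations=default_cohort.populations,
        )
        grads2 = ps.estimate_gradients(shuffled)
        delta2 = ps.delta_beta(grads2, shuffled)
        merged = delta.merge(delta2, on=["population", "morph", "trait"])
        np.testing.assert_allclose(merged["delta_beta_x"], merged["delta_beta_y"], atol=1e-10)
        np.testing.assert_allclose(merged["p_x"], merged["p_y"], atol=1e-10)


class TestFactorialAnova:
    def test_one_way_f_equals_squared_t(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            {"grp": ["fly"] * 20 + ["bee"] * 20, "length": rng.uniform(13, 18, 40)}
        )
        res = ps.factorial_anova(df, "length", ["grp"])
        from scipy import stats

        a, b = df.length[:20], df.length[20:]
        t_stat, p = stats.ttest_ind(a, b, equal_var=True)
        assert res.row("grp")["F"] == pytest.approx(t_stat**2, rel=1e-10)
        assert res.row("grp")["p"] == pytest.approx(p, rel=1e-8)

    def test_noiseless_equal_means_give_zero_f(self):
        df = pd.DataFrame(
            {"a": ["x", "y"] * 8, "b": ["u", "u", "v", "v"] * 4, "resp": 5.0}
        )
        res = ps.factorial_anova(df, "resp", ["a", "b"])
        assert (res.table["F"] == 0).all()

    def test_balanced_three_way_matches_hand_anova(self):
        # balanced 2x2x2 with 2 replicates; sequential = textbook sums of squares
        df = pd.DataFrame(
            {
                "A": ["a0"] * 8 + ["a1"] * 8,
                "B": (["b0"] * 4 + ["b1"] * 4) * 2,
                "C_": (["c0"] * 2 + ["c1"] * 2) * 4,
                "y": [3.0, 4, 6, 5, 7, 8, 9, 10, 4, 3, 7, 6, 8, 9, 11, 12],
            }
        )
        res = ps.factorial_anova(df, "y", ["A", "B", "C_"], test_type="sequential")
        # textbook two-level factorial: SS(effect) = n*(contrast mean diff)^2/4
        y = df["y"].to_numpy()
        means = {}
        for name, labels in [("A", df.A), ("B", df.B), ("C_", df.C_)]:
            lv = sorted(set(labels))
            means[name] = y[labels == lv[1]].mean() - y[labels == lv[0]].mean()
        n = 16
        for name in ["A", "B", "C_"]:
            ss = n / 4 * means[name] ** 2
            f_row = res.row(name)
            ms_resid = res.rss / res.df_resid
            assert f_row["F"] == pytest.approx(ss / ms_resid, rel=1e-8)

    def test_log_transform_requires_positive_values(self, toy_table):
        df = toy_table.df.copy()
        df.loc[0, "female_fitness"] = 0.0  # fruitless plant
        table = ps.StudyTable(df)
        with pytest.raises(ValidationError, match="offset"):
            ps.factorial_anova(table, "female_fitness", ["morph"], log10_transform=True)
        res = ps.factorial_anova(
            table, "female_fitness", ["morph"], log10_transform=True, offset=1.0
        )
        assert res.table["p"].between(0, 1).all()


class TestProportionExplained:
    def test_printed_ratios(self):
        delta = pd.DataFrame(
            {
                "population": ["BGTC1", "BGTC2"],
                "morph": ["S", "S"],
                "trait": ["corolla_tube_width"] * 2,
                "beta_C": [0.17, 0.174],
                "delta_beta": [0.13, 0.146],
            }
        )
        out = ps.proportion_explained(delta, pd.DataFrame())
        assert list(out["percent_explained"]) == [76.5, 83.9]

    def test_full_attribution_is_hundred_percent(self):
        delta = pd.DataFrame(
            {"population": ["A"], "morph": ["L"], "trait": ["x"],
             "beta_C": [0.2], "delta_beta": [0.2]}
        )
        assert ps.proportion_explained(delta, pd.DataFrame())["percent_explained"][0] == 100.0

    def test_zero_denominator_is_missing(self):
        delta = pd.DataFrame(
            {"population": ["A"], "morph": ["L"], "trait": ["x"],
             "beta_C": [0.0], "delta_beta": [0.1]}
        )
        assert np.isnan(ps.proportion_explained(delta, pd.DataFrame())["percent_explained"][0])
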