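"""Cohort statistics: ANOVA + Tukey, regression, skewness comparison."""

import numpy as np
import pandas as pd
import pytest

from ulmkit import (compare_skewness, multivariate_regression, two_way_anova_tukey,
                    validate_metrics_table)


def tidy_table(values: dict, metric="m", age_weeks=None, sexes=None):
    """Build a tidy metrics table from {(age_group, region): [values]}."""
    rows = []
    i = 0
    for (age, region), vals in values.items():
        for v in vals:
            rows.append({"subject": f"s{age}{i}", "age_group": age,
                         "sex": (sexes[i % len(sexes)] if sexes else
                                 ("F" if i % 2 else "M")),
                         "age_weeks": (age_weeks if age_weeks is not None
                                       else (27.7 if age == "young" else 106.8)),
                         "region": region, "metric_name": metric, "value": v})
            i += 1
    return pd.DataFrame(rows)


def anova_2x2_oracle(table: pd.DataFrame):
    """From-scratch balanced two-way ANOVA sums-of-squares decomposition."""
    y = table["value"].to_numpy()
    A = table["age_group"].to_numpy()
    B = table["region"].to_numpy()
    grand = y.mean()
    ss_a = sum(len(y[A == a]) * (y[A == a].mean() - grand) ** 2 for a in set(A))
    ss_b = sum(len(y[B == b]) * (y[B == b].mean() - grand) ** 2 for b in set(B))
    ss_cells = sum(len(y[(A == a) & (B == b)])
                   * (y[(A == a) & (B == b)].mean() - grand) ** 2
                   for a in set(A) for b in set(B))
    ss_ab = ss_cells - ss_a - ss_b
    ss_tot = np.sum((y - grand) ** 2)
    ss_err = ss_tot - ss_cells
    df_a, df_b = len(set(A)) - 1, len(set(B)) - 1
    df_ab = df_a * df_b
    df_err = len(y) - len(set(A)) * len(set(B))
    ms = lambda ss, df: ss / df
    return {
        "age_group": (ms(ss_a, df_a) / ms(ss_err, df_err)),
        "region": (ms(ss_b, df_b) / ms(ss_err, df_err)),
        "age_group:region": (ms(ss_ab, df_ab) / ms(ss_err, df_err)),
        "ss": (ss_a, ss_b, ss_ab, ss_err, ss_tot),
    }


class TestTwoWayANOVA:
    def test_identical_values_f_zero_p_one(self):
        t = tidy_table({("young", "r1"): [5.0] * 4, ("young", "r2"): [5.0] * 4,
                        ("aged", "r1"): [5.0] * 4, ("aged", "r2"): [5.0] * 4})
        results = two_way_anova_tukey(t, "m")
        for r in results:
            assert r.statistic == 0.0
            assert r.p_value == 1.0

    def test_matches_sums_of_squares_oracle_on_2x2(self):
        rng = np.random.default_rng(0)
        t = tidy_table({("young", "r1"): list(rng.normal(10, 1, 6)),
                        ("young", "r2"): list(rng.normal(12, 1, 6)),
                        ("aged", "r1"): list(rng.normal(9, 1, 6)),
                        ("aged", "r2"): list(rng.normal(12.5, 1, 6))})
        results = {r.effect: r for r in two_way_anova_tukey(t, "m")}
        oracle = anova_2x2_oracle(t)
        for eff in ("age_group", "region", "age_group:region"):
            assert results[eff].statistic == pytest.approx(oracle[eff], rel=1e-9)
        ss_a, ss_b, ss_ab, ss_err, ss_tot = oracle["ss"]
        assert ss_a + ss_b + ss_ab + ss_err == pytest.approx(ss_tot, rel=1e-9)

    def test_injected_age_effect_detected(self):
        # large effect (5 pooled SDs), n = 8 per cell: should basically always hit
        rng = np.random.default_rng(1)
        hits = 0
        n_rep = 30
        for _ in range(n_rep):
            t = tidy_table({("young", "r1"): list(rng.normal(5, 1, 8)),
                            ("young", "r2"): list(rng.normal(5, 1, 8)),
                            ("aged", "r1"): list(rng.normal(0, 1, 8)),
                            ("aged", "r2"): list(rng.normal(0, 1, 8))})
            res = {r.effect: r for r in two_way_anova_tukey(t, "m")}
            hits += res["age_group"].p_value < 0.05
        assert hits == n_rep

    def test_empty_cells_rejected(self):
        t = tidy_table({("young", "r1"): [1.0, 2.0], ("young", "r2"): [1.0, 2.0],
                        ("aged", "r1"): [1.0, 2.0]})
        with pytest.raises(ValueError, match="cells"):
            two_way_anova_tukey(t, "m")

    def test_tukey_pairwise_present_per_region(self):
        rng = np.random.default_rng(2)
        t = tidy_table({("young", "r1"): list(rng.normal(10, 1, 5)),
                        ("young", "r2"): list(rng.normal(10, 1, 5)),
                        ("aged", "r1"): list(rng.normal(4, 1, 5)),
                        ("aged", "r2"): list(rng.normal(10, 1, 5))})
        res = two_way_anova_tukey(t, "m")
        pw = res[0].pairwise
        assert pw is not None and len(pw) == 2  # one age contrast per region
        r1 = pw[pw["group1"].str.contains("r1") | pw["group2"].str.contains("r1")]
        assert bool(r1["reject"].iloc[0])

    def test_duplicate_keys_rejected(self):
        t = tidy_table({("young", "r1"): [1.0, 2.0]})
        t.loc[1, "subject"] = t.loc[0, "subject"]
        with pytest.raises(ValueError, match="duplicated"):
            validate_metrics_table(t)


class TestRegression:
    def test_exact_linear_age_effect(self):
        ages = np.array([20.0, 40.0, 60.0, 80.0, 100.0, 120.0])
        rows = []
        for i, a in enumerate(ages):
            rows.append({"subject": f"s{i}", "age_group": "young", "age_weeks": a,
                         "sex": "F" if i % 2 else "M", "region": "r1",
                         "metric_name": "m", "value": 2.0 * a})
        res = multivariate_regression(pd.DataFrame(rows), "m", "r1")
        assert res.loc["age_weeks", "coef"] == pytest.approx(2.0, abs=1e-9)
        sex_term = [ix for ix in res.index if "sex" in ix][0]
        assert res.loc[sex_term, "coef"] == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        ages = rng.uniform(20, 120, 6)
        sexes = ["F", "M", "F", "M", "F", "M"]
        vals = rng.normal(0, 1, 6)
        rows = [{"subject": f"s{i}", "age_group": "g", "age_weeks": a, "sex": s,
                 "region": "r1", "metric_name": "m", "value": v}
                for i, (a, s, v) in enumerate(zip(ages, sexes, vals))]
        res = multivariate_regression(pd.DataFrame(rows), "m", "r1")
        X = np.column_stack([np.ones(6), [1.0 if s == "M" else 0.0 for s in sexes],
                             ages])
        beta = np.linalg.solve(X.T @ X, X.T @ vals)
        assert res.loc["Intercept", "coef"] == pytest.approx(beta[0], rel=1e-9)
        sex_term = [ix for ix in res.index if "sex" in ix][0]
        assert res.loc[sex_term, "coef"] == pytest.approx(beta[1], rel=1e-9)
        assert res.loc["age_weeks", "coef"] == pytest.approx(beta[2], rel=1e-9)

    def test_single_sex_rejected(self):
        rows = [{"subject": f"s{i}", "age_group": "g", "age_weeks": 20.0 + i,
                 "sex": "F", "region": "r1", "metric_name": "m", "value": float(i)}
                for i in range(6)]
        with pytest.raises(ValueError, match="collinear"):
            multivariate_regression(pd.DataFrame(rows), "m", "r1")


class TestCompareSkewness:
    def test_identical_groups_p_near_one(self):
        g = np.array([1.0, 1.1, 0.9, 1.05])
        res = compare_skewness(g, g)
        assert res.p_value > 0.99

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(30):
            young = rng.normal(0.98, 0.1, 10)
            aged = rng.normal(0.98 + 0.3, 0.1, 10)  # 3 pooled SDs
            hits += compare_skewness(young, aged).p_value < 0.05
        assert hits == 30

    def test_welch_satterthwaite_hand_oracle(self):
        a = np.array([1.0, 2.0, 4.0])
        b = np.array([2.5, 3.5, 7.0])
        res = compare_skewness(a, b)
        n1 = n2 = 3
        v1, v2 = a.var(ddof=1), b.var(ddof=1)
        t_hand = (a.mean() - b.mean()) / np.sqrt(v1 / n1 + v2 / n2)
        df_hand = ((v1 / n1 + v2 / n2) ** 2
                   / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)))
        assert res.statistic == pytest.approx(t_hand, rel=1e-9)
        assert res.df[0] == pytest.approx(df_hand, rel=1e-9)

    def test_tiny_degenerate_group_flagged(self):
        with pytest.raises(ValueError):
            compare_skewness(np.array([1.0, 1.0]), np.array([1.0, 2.0]))
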