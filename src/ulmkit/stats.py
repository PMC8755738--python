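"""Group-level statistics on regional metrics.

Two-way ANOVA (age group x region, Type II sums of squares by default for
the unbalanced cohorts typical of aging studies) with Tukey HSD pairwise
post-tests for the age contrast within each region; ordinary least squares
with age and sex as covariates; and a Welch two-sample t-test for the
velocity-distribution skewness comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class TestResult:
    """One statistical effect: statistic, degrees of freedom, p-value."""

    effect: str
    statistic: float
    df: tuple
    p_value: float
    pairwise: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


REQUIRED_COLUMNS = ("subject", "age_group", "sex", "region", "metric_name", "value")


def validate_metrics_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the tidy metrics table: required columns, no duplicated keys."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"metrics table missing columns: {missing}")
    keys = table[["subject", "region", "metric_name"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0].tolist()
        raise ValueError(f"duplicated (subject, region, metric) key: {dup}")
    return table


def two_way_anova_tukey(table: pd.DataFrame, metric_name: str,
                        ss_type: int = 2, tukey: bool = True) -> list[TestResult]:
    """Two-factor ANOVA (age_group x region) on one metric, plus Tukey HSD.

    Returns TestResults for the two main effects and the interaction; the
    age main effect carries the Tukey-adjusted pairwise comparisons of
    age_group within each region (age_group:region cells). ``tukey=False``
    skips the post-test (useful in large calibration simulations).
    """
    df = validate_metrics_table(table)
    df = df[df["metric_name"] == metric_name].copy()
    if df.empty:
        raise ValueError(f"no rows for metric {metric_name!r}")
    cells = df.groupby(["age_group", "region"], observed=True).size()
    expected = [(a, r) for a in df["age_group"].unique() for r in df["region"].unique()]
    missing = [c for c in expected if c not in cells.index or cells.get(c, 0) < 2]
    if missing:
        raise ValueError(f"cells with < 2 observations: {missing}")

    model = smf.ols("value ~ C(age_group) * C(region)", data=df).fit()
    if np.isclose(model.ssr, 0.0) and np.isclose(model.ess, 0.0):
        # no variance anywhere: F = 0, p = 1 for every effect
        results = [TestResult(effect=e, statistic=0.0, df=(np.nan, np.nan), p_value=1.0)
                   for e in ("age_group", "region", "age_group:region")]
    else:
        anova = sm.stats.anova_lm(model, typ=ss_type)
        results = []
        name_map = {"C(age_group)": "age_group", "C(region)": "region",
                    "C(age_group):C(region)": "age_group:region"}
        df_resid = float(anova.loc["Residual", "df"])
        for raw, name in name_map.items():
            F = float(anova.loc[raw, "F"])
            p = float(anova.loc[raw, "PR(>F)"])
            if not np.isfinite(F):  # zero residual variance with real effects
                F, p = np.inf, 0.0
            results.append(TestResult(effect=name, statistic=F,
                                      df=(float(anova.loc[raw, "df"]), df_resid),
                                      p_value=p))

    groups = df["age_group"].astype(str) + "|" + df["region"].astype(str)
    if tukey and df["value"].nunique() > 1:
        tk = pairwise_tukeyhsd(df["value"].to_numpy(), groups.to_numpy())
        tk_df = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        # keep the age contrast within each region
        g1 = tk_df["group1"].str.split("|", expand=True)
        g2 = tk_df["group2"].str.split("|", expand=True)
        within = (g1[1] == g2[1]) & (g1[0] != g2[0])
        results[0].pairwise = tk_df[within].reset_index(drop=True)
    return results


def multivariate_regression(table: pd.DataFrame, metric_name: str, region: str,
                            age_column: str = "age_weeks") -> pd.DataFrame:
    """OLS of one regional metric on age (weeks) and sex.

    Returns a coefficient table (coef, stderr, t, p) for intercept, age and
    sex. Requires >= 4 subjects and both sexes represented.
    """
    df = validate_metrics_table(table)
    df = df[(df["metric_name"] == metric_name) & (df["region"] == region)].copy()
    if len(df) < 4:
        raise ValueError("need at least 4 subjects")
    if df["sex"].nunique() < 2:
        raise ValueError("collinear design: both sexes must be present")
    if age_column not in df.columns:
        raise ValueError(f"table has no {age_column!r} column")
    model = smf.ols(f"value ~ {age_column} + C(sex)", data=df).fit()
    out = pd.DataFrame({
        "coef": model.params, "stderr": model.bse,
        "t": model.tvalues, "p_value": model.pvalues,
    })
    return out


def compare_skewness(young: np.ndarray, aged: np.ndarray) -> TestResult:
    """Welch two-sample t-test on per-subject velocity-distribution skewness."""
    young = np.asarray(young, dtype=float).reshape(-1)
    aged = np.asarray(aged, dtype=float).reshape(-1)
    if len(young) < 2 or len(aged) < 2:
        raise ValueError("need >= 2 subjects per group")
    if (len(young) == 2 and np.ptp(young) == 0) or (len(aged) == 2 and np.ptp(aged) == 0):
        raise ValueError("a group with zero variance and n = 2 cannot be tested")
    t, p = sps.ttest_ind(young, aged, equal_var=False)
    # Welch-Satterthwaite df
    v1, v2 = young.var(ddof=1), aged.var(ddof=1)
    n1, n2 = len(young), len(aged)
    num = (v1 / n1 + v2 / n2) ** 2
    den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    dof = num / den if den > 0 else np.nan
    if np.isnan(p):
        p = 1.0
        t = 0.0
    return TestResult(effect="skewness_young_vs_aged", statistic=float(t),
                      df=(float(dof),), p_value=float(p))
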