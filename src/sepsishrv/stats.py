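"""Normality-gated group statistics, correlations and survival analysis.

The procedure mirrors standard practice for small-animal cohorts: every
variable is gated through a Kolmogorov–Smirnov normality test (Lilliefors
correction, since mean and SD are estimated from the sample); normally
distributed variables get Student's t (two groups) or one-way ANOVA with
Bonferroni-corrected pairwise post hocs (three groups); otherwise
Mann–Whitney / Kruskal–Wallis with Bonferroni-adjusted pairwise rank tests.
Associations use Spearman's rho; survival uses the Kaplan–Meier
product-limit estimator with a log-rank test.

Pairwise significance markers follow the table convention of the source
cohort: ``a`` = p < alpha vs sham, ``b`` = p < alpha vs sepsis good
prognosis, on Bonferroni-adjusted p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "ComparisonResult",
    "ThreeGroupResult",
    "SurvivalResult",
    "severity_score",
    "test_normality",
    "compare_two_groups",
    "compare_three_groups",
    "spearman_matrix",
    "km_logrank",
    "cohort_comparison_table",
]

GROUP_ORDER = ("sham", "sepsis_good", "sepsis_bad")


def severity_score(marks) -> int:
    """Clinical severity: sum of six items each scored 0/1/2 (range 0–12).

    Items: hunched position, bloated abdomen, conjunctival injection,
    piloerection, lack of movement, lack of alertness.
    """
    marks = list(marks)
    if len(marks) != 6:
        raise ValueError("exactly 6 severity components required")
    if any(m not in (0, 1, 2) for m in marks):
        raise ValueError("each component must be 0, 1 or 2")
    return int(sum(marks))


def test_normality(values, alpha: float = 0.05) -> str:
    """Lilliefors-corrected KS test; returns 'normal' or 'non_normal'."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 4:
        raise ValueError("at least 4 observations required")
    if np.ptp(values) == 0:
        return "non_normal"  # degenerate: zero variance
    _, p = lilliefors(values, dist="norm")
    return "normal" if p >= alpha else "non_normal"


test_normality.__test__ = False  # library function, not a pytest case


@dataclass
class ComparisonResult:
    variable: str
    test_name: str
    statistic: float
    p_value: float
    adjusted_p: float | None = None
    group_means: dict[str, float] = field(default_factory=dict)
    group_sems: dict[str, float] = field(default_factory=dict)
    markers: dict[str, str] = field(default_factory=dict)


def _summaries(named: dict[str, np.ndarray]) -> tuple[dict, dict]:
    means = {k: float(np.mean(v)) for k, v in named.items()}
    sems = {
        k: float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan
        for k, v in named.items()
    }
    return means, sems


def _gate_parametric(groups: list[np.ndarray], gate: str, alpha: float) -> bool:
    if gate == "always-parametric":
        return True
    if gate == "always-nonparametric":
        return False
    if gate != "ks":
        raise ValueError(f"unknown gate {gate!r}")
    return all(test_normality(g, alpha) == "normal" for g in groups)


def compare_two_groups(
    values_a,
    values_b,
    gate: str = "ks",
    alpha: float = 0.05,
    variable: str = "",
    names: tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Unpaired t test when both groups pass normality, else Mann–Whitney."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    if _gate_parametric([a, b], gate, alpha):
        stat, p = sps.ttest_ind(a, b)
        test_name = "t_test"
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        test_name = "mann_whitney"
    means, sems = _summaries({names[0]: a, names[1]: b})
    return ComparisonResult(
        variable=variable,
        test_name=test_name,
        statistic=float(stat),
        p_value=float(p),
        group_means=means,
        group_sems=sems,
    )


@dataclass
class ThreeGroupResult:
    variable: str
    omnibus: ComparisonResult
    pairwise: list[ComparisonResult]
    markers: dict[str, str]  # group -> concatenated marker letters


def compare_three_groups(
    groups,
    gate: str = "ks",
    alpha: float = 0.05,
    variable: str = "",
    names: tuple[str, str, str] = GROUP_ORDER,
) -> ThreeGroupResult:
    """Omnibus three-group comparison with all-pairs Bonferroni post hocs.

    One-way ANOVA + pairwise t tests when every group passes the normality
    gate, otherwise Kruskal–Wallis + pairwise Mann–Whitney; each pairwise p
    is Bonferroni-multiplied by 3 (the number of contrasts).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [g[np.isfinite(g)] for g in arrays]
    if len(arrays) != 3:
        raise ValueError("exactly three groups required")
    if any(g.size < 3 for g in arrays):
        raise ValueError("each group needs at least 3 observations")

    parametric = _gate_parametric(arrays, gate, alpha)
    named = dict(zip(names, arrays))
    means, sems = _summaries(named)
    if parametric:
        stat, p = sps.f_oneway(*arrays)
        omnibus_name = "anova"
    else:
        stat, p = sps.kruskal(*arrays)
        omnibus_name = "kruskal_wallis"
    omnibus = ComparisonResult(
        variable=variable,
        test_name=omnibus_name,
        statistic=float(stat),
        p_value=float(p),
        group_means=means,
        group_sems=sems,
    )

    pairs = [(0, 1), (0, 2), (1, 2)]
    pairwise: list[ComparisonResult] = []
    for i, j in pairs:
        if parametric:
            s, pv = sps.ttest_ind(arrays[i], arrays[j])
            tname = "t_test_bonferroni"
        else:
            s, pv = sps.mannwhitneyu(arrays[i], arrays[j], alternative="two-sided")
            tname = "mann_whitney_bonferroni"
        res = ComparisonResult(
            variable=variable,
            test_name=tname,
            statistic=float(s),
            p_value=float(pv),
            adjusted_p=float(min(1.0, 3.0 * pv)),
            group_means={names[i]: means[names[i]], names[j]: means[names[j]]},
            group_sems={names[i]: sems[names[i]], names[j]: sems[names[j]]},
        )
        pairwise.append(res)

    markers = {name: "" for name in names}
    # 'a': differs from the first (sham) group; 'b': differs from the second
    if pairwise[0].adjusted_p < alpha:
        markers[names[1]] += "a"
    if pairwise[1].adjusted_p < alpha:
        markers[names[2]] += "a"
    if pairwise[2].adjusted_p < alpha:
        markers[names[2]] += "b"
    return ThreeGroupResult(
        variable=variable, omnibus=omnibus, pairwise=pairwise, markers=markers
    )


def spearman_matrix(
    table: pd.DataFrame, vars_x: list[str], vars_y: list[str], min_n: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Spearman rank correlations.

    Returns ``(rho, p)`` DataFrames indexed by ``vars_x`` with columns
    ``vars_y``; pairs with fewer than ``min_n`` complete observations are
    NaN.  Ties are mid-ranked and p comes from the large-sample
    approximation (scipy default).
    """
    rho = pd.DataFrame(index=vars_x, columns=vars_y, dtype=float)
    pmat = pd.DataFrame(index=vars_x, columns=vars_y, dtype=float)
    for vx in vars_x:
        for vy in vars_y:
            sub = table[[vx, vy]].dropna()
            if len(sub) < min_n:
                continue
            r, p = sps.spearmanr(sub[vx], sub[vy])
            rho.loc[vx, vy] = r
            pmat.loc[vx, vy] = p
    return rho, pmat


@dataclass
class SurvivalResult:
    curves: dict[str, pd.DataFrame]  # group -> (time, survival) step function
    survival_at_horizon: dict[str, float]
    logrank_statistic: float
    logrank_p: float  # NaN when no events occurred


def km_logrank(table: pd.DataFrame, horizon: float | None = None) -> SurvivalResult:
    """Kaplan–Meier product-limit curves per group and a log-rank test.

    ``table`` needs columns ``group, time_h, event`` (event 1 = death,
    0 = censored).  With no events anywhere the curves are identically 1
    and the log-rank p is NaN.
    """
    groups = table["group"].unique()
    if len(groups) < 2:
        raise ValueError("at least two groups required")
    if horizon is None:
        horizon = float(table["time_h"].max())
    curves: dict[str, pd.DataFrame] = {}
    surv_at_h: dict[str, float] = {}
    for g in groups:
        sub = table[table["group"] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_h"], event_observed=sub["event"], label=str(g))
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time_h", "survival"]
        curves[str(g)] = sf
        surv_at_h[str(g)] = float(kmf.predict(horizon))
    if int(table["event"].sum()) == 0:
        return SurvivalResult(curves, surv_at_h, np.nan, np.nan)
    res = multivariate_logrank_test(
        table["time_h"], table["group"], table["event"]
    )
    return SurvivalResult(
        curves, surv_at_h, float(res.test_statistic), float(res.p_value)
    )


def cohort_comparison_table(
    cohort: pd.DataFrame,
    variables: list[str] | None = None,
    gate: str = "ks",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tidy three-group comparison over cohort variables.

    One row per variable: omnibus test, p, and the a/b marker per sepsis
    group; listwise deletion within each variable.
    """
    if variables is None:
        skip = {"animal_id", "group", "truncated_fields",
                "n_segments", "n_ectopic_replaced"}
        variables = [
            c for c in cohort.columns
            if c not in skip and pd.api.types.is_numeric_dtype(cohort[c])
        ]
    rows = []
    for var in variables:
        groups = [
            cohort.loc[cohort["group"] == g, var].dropna().to_numpy()
            for g in GROUP_ORDER
        ]
        if np.ptp(np.concatenate([g for g in groups if g.size])) == 0:
            rows.append({"variable": var, "test": "skipped",
                         "note": "constant across all animals"})
            continue
        try:
            res = compare_three_groups(groups, gate=gate, alpha=alpha, variable=var)
        except ValueError as exc:
            rows.append({"variable": var, "test": "skipped", "note": str(exc)})
            continue
        row = {
            "variable": var,
            "test": res.omnibus.test_name,
            "statistic": res.omnibus.statistic,
            "p_value": res.omnibus.p_value,
        }
        for g in GROUP_ORDER:
            row[f"mean_{g}"] = res.omnibus.group_means[g]
            row[f"sem_{g}"] = res.omnibus.group_sems[g]
            row[f"markers_{g}"] = res.markers[g]
        rows.append(row)
    return pd.DataFrame(rows)
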