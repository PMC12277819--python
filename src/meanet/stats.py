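"""Group comparisons for MEA metrics.

Kruskal-Wallis (chi-square approximation, tie-corrected) for coupling-strength
distributions; paired t for drug effects within assembloids; Welch t for
unpaired two-group contrasts; and a two-factor (genotype x condition)
fixed-effects decomposition with Sidak-adjusted per-condition contrasts for
bar-plot metrics.  Zero-variance degenerate inputs return flagged,
non-crashing results (statistic 0, p = 1) so that synthetic edge cases never
abort a pipeline run.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import ComparisonResult


def _all_identical(groups: Sequence[Sequence[float]]) -> bool:
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    return bool(np.all(pooled == pooled[0]))


def kruskal_wallis(groups: Sequence[Sequence[float]], label: str = "") -> ComparisonResult:
    """Kruskal-Wallis rank-sum test with chi-square approximation.

    Average ranks for ties with the standard tie-correction divisor
    1 - sum(t^3 - t)/(N^3 - N); df = #groups - 1.  All-identical data is a
    degenerate case (tie divisor 0) reported as H = 0, p = 1, flagged.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    sizes = tuple(len(g) for g in groups)
    if sum(sizes) < 3:
        raise ValueError("need total N >= 3")
    if _all_identical(groups):
        return ComparisonResult("kruskal_wallis", 0.0, float(len(groups) - 1), 1.0,
                                sizes, degenerate=True, label=label)
    h, p = sps.kruskal(*groups)
    return ComparisonResult("kruskal_wallis", float(h), float(len(groups) - 1),
                            float(p), sizes, label=label)


def paired_t(before: Sequence[float], after: Sequence[float], label: str = "") -> ComparisonResult:
    """Two-sided paired t test on after - before differences (df = n - 1)."""
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape or b.size < 2:
        raise ValueError("need equal-length paired samples of size >= 2")
    d = a - b
    if np.all(d == d[0]) and (d[0] == 0 or np.std(d, ddof=1) == 0):
        # zero-variance differences: direction (sign of the common d) is
        # reported via the statistic's sign convention but p is undefined
        stat = 0.0 if d[0] == 0 else float(np.sign(d[0]) * np.inf)
        return ComparisonResult("paired_t", stat, float(d.size - 1), 1.0,
                                (b.size, a.size), degenerate=True, label=label)
    t, p = sps.ttest_rel(a, b)
    return ComparisonResult("paired_t", float(t), float(d.size - 1), float(p),
                            (b.size, a.size), label=label)


def welch_t(group_a: Sequence[float], group_b: Sequence[float], label: str = "") -> ComparisonResult:
    """Two-sided unpaired t test with Welch's correction (Satterthwaite df)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return ComparisonResult("welch_t", 0.0, float(a.size + b.size - 2),
                                    1.0, (a.size, b.size), degenerate=True, label=label)
        stat = float(np.sign(np.mean(a) - np.mean(b)) * np.inf)
        return ComparisonResult("welch_t", stat, float(a.size + b.size - 2),
                                0.0, (a.size, b.size), degenerate=True, label=label)
    res = sps.ttest_ind(a, b, equal_var=False)
    return ComparisonResult("welch_t", float(res.statistic), float(res.df),
                            float(res.pvalue), (a.size, b.size), label=label)


def sidak_adjust(p: float, m: int) -> float:
    """Sidak multiple-comparison adjustment: 1 - (1 - p)^m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0 <= p <= 1):
        raise ValueError("p must be in [0, 1]")
    return float(1.0 - (1.0 - p) ** m)


def condition_genotype_comparison(
    metric_table: pd.DataFrame, metric: str = "value"
) -> list[ComparisonResult]:
    """Two-way fixed-effects comparison of a per-assembloid metric.

    Expects one row per assembloid x condition with columns ``assembloid``,
    ``genotype``, ``condition`` and the metric column.  Returns the genotype,
    condition and interaction F tests plus per-condition genotype contrasts
    (Welch t) with Sidak-adjusted p over the number of contrasts.  The
    assembloid is the experimental unit; electrodes are never pooled here.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    required = {"assembloid", "genotype", "condition", metric}
    missing = required - set(metric_table.columns)
    if missing:
        raise ValueError(f"metric table missing columns: {sorted(missing)}")
    df = metric_table.rename(columns={metric: "_y"}).dropna(subset=["_y"]).copy()
    genotypes = sorted(df["genotype"].unique())
    conditions = sorted(df["condition"].unique())
    if len(genotypes) < 2 or len(conditions) < 2:
        raise ValueError("need >= 2 levels of genotype and condition")
    cells = df.groupby(["genotype", "condition"], observed=True).size()
    absent = [
        (g, c) for g in genotypes for c in conditions if (g, c) not in cells.index
    ]
    if absent:
        raise ValueError(f"missing (genotype, condition) cells: {absent}")

    results: list[ComparisonResult] = []
    if df["_y"].nunique() == 1:
        for eff in ("genotype", "condition", "genotype:condition"):
            results.append(ComparisonResult(f"anova_{eff}", 0.0, np.nan, 1.0,
                                            (len(df),), degenerate=True, label=metric))
    else:
        model = smf.ols("_y ~ C(genotype) * C(condition)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        name_map = {
            "C(genotype)": "genotype",
            "C(condition)": "condition",
            "C(genotype):C(condition)": "genotype:condition",
        }
        for row, eff in name_map.items():
            results.append(
                ComparisonResult(
                    test_name=f"anova_{eff}",
                    statistic=float(table.loc[row, "F"]),
                    df=float(table.loc[row, "df"]),
                    p_value=float(table.loc[row, "PR(>F)"]),
                    group_sizes=(len(df),),
                    label=metric,
                )
            )

    if len(genotypes) == 2:
        m = len(conditions)
        g0, g1 = genotypes
        for cond in conditions:
            a = df.loc[(df.genotype == g0) & (df.condition == cond), "_y"]
            b = df.loc[(df.genotype == g1) & (df.condition == cond), "_y"]
            r = welch_t(a, b, label=f"{metric}:{cond}:{g0}-vs-{g1}")
            results.append(
                ComparisonResult(
                    test_name="welch_t", statistic=r.statistic, df=r.df,
                    p_value=r.p_value, group_sizes=r.group_sizes,
                    adjustment="sidak", p_adjusted=sidak_adjust(r.p_value, m),
                    degenerate=r.degenerate, label=r.label,
                )
            )
    return results


def comparisons_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Tidy table of comparison results for TSV export."""
    return pd.DataFrame(
        {
            "test": [r.test_name for r in results],
            "label": [r.label for r in results],
            "statistic": [r.statistic for r in results],
            "df": [r.df for r in results],
            "p_value": [r.p_value for r in results],
            "adjustment": [r.adjustment for r in results],
            "p_adjusted": [r.p_adjusted if r.p_adjusted is not None else np.nan
                           for r in results],
            "group_sizes": ["x".join(map(str, r.group_sizes)) for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )
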