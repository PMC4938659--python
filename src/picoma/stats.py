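"""Statistical battery for MA fitness data.

Covers the analyses run on an MA experiment and its stress assays:

* one-way ANOVA on control growth across bottleneck times (set-up drift);
* Pearson trend tests of relative fitness against cumulative generations,
  per line and for the across-line mean series;
* per line × condition Student/Welch tests of MA growth against control
  growth, with Bonferroni–Holm correction and selection coefficients;
* Fisher–Snedecor variance-ratio tests between a stress condition and
  the standard condition (genotype-by-environment dispersion);
* Wilcoxon rank-sum confirmation that a condition is actually stressful
  (controls grow significantly more slowly than in standard conditions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .fitness import selection_coefficient

__all__ = [
    "TrendResult",
    "VarianceTestResult",
    "StressCheckResult",
    "control_drift_anova",
    "per_line_trend",
    "mean_trend",
    "holm_adjust",
    "st_significance_battery",
    "variance_ratio_test",
    "stress_confirmation",
    "classify_lines",
]


@dataclass(frozen=True)
class TrendResult:
    line_id: str
    rho: float
    p_value: float
    n_points: int
    undefined: bool = False


@dataclass(frozen=True)
class VarianceTestResult:
    condition: str
    reference_condition: str
    f_statistic: float
    p_value: float
    df_condition: int
    df_reference: int


@dataclass(frozen=True)
class StressCheckResult:
    p_value: float
    stressful: bool
    growth_reduction_percent: float
    undefined: bool = False


def control_drift_anova(control_records: pd.DataFrame) -> tuple[float, float]:
    """One-way ANOVA of control growth factor G on bottleneck index.

    Tests whether the set-up drifted between bottleneck times.  Expects
    columns ``bottleneck`` and ``g``; needs >= 2 groups with >= 2
    observations each.  Computed from sums of squares so degenerate
    inputs follow a defined contract: identical constant groups give
    (F=0, p=1); zero within-group variance with real between-group
    differences is an error.
    """
    df = control_records.dropna(subset=["g"])
    groups = [g["g"].to_numpy(dtype=float) for _, g in df.groupby("bottleneck")]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 bottleneck groups with >= 2 replicates each")
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = sum(len(g) for g in groups) - len(groups)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        raise ValueError("zero within-group variance: F statistic undefined")
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f, df_between, df_within))
    return float(f), p


def per_line_trend(
    generations: Sequence[float], g_r: Sequence[float], line_id: str = ""
) -> TrendResult:
    """Pearson correlation of relative fitness against cumulative generations.

    A systematic decline of G_r with generations is the signature of
    deleterious mutation accumulation.  Zero variance in either variable
    makes the correlation undefined; the result is flagged rather than
    returned as a silent NaN.
    """
    x = np.asarray(generations, dtype=float)
    y = np.asarray(g_r, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need >= 3 paired points for a trend test")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TrendResult(line_id, float("nan"), float("nan"), x.size, undefined=True)
    r = sps.pearsonr(x, y)
    return TrendResult(line_id, float(r.statistic), float(r.pvalue), x.size)


def mean_trend(ma_table: pd.DataFrame, line_id: str = "mean") -> TrendResult:
    """Trend test on the across-line mean G_r series per bottleneck.

    Expects columns ``bottleneck``, ``generations`` and ``g_r`` (one row
    per line × bottleneck, as produced by ``relative_fitness_table`` with
    a generations column attached).
    """
    mean_series = (
        ma_table.dropna(subset=["g_r"])
        .groupby("bottleneck")
        .agg(generations=("generations", "mean"), g_r=("g_r", "mean"))
    )
    return per_line_trend(mean_series["generations"], mean_series["g_r"], line_id)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni–Holm step-down adjusted p-values (family = the input)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def st_significance_battery(
    assay: pd.DataFrame,
    alpha: float = 0.01,
    *,
    inoculum_cells: float = 50_000,
    elapsed_days: float = 7.0,
    st_variant: Literal["ratio", "product"] = "ratio",
    welch: bool = True,
    family: Literal["condition", "global"] = "condition",
) -> pd.DataFrame:
    """Per line × condition selection-coefficient tests against the control.

    The assay table has columns condition, line_id, replicate, cells,
    is_control; every well grew from a common inoculum for a fixed number
    of days, so growth factors G are computed per well and MA replicates
    are compared to control replicates with a two-sample t-test (Welch by
    default).  P-values are Holm-adjusted within each condition across
    lines (or globally with ``family="global"``).  S_T is computed from
    the replicate-mean growth factors.

    Comparisons with fewer than two replicates on either side are skipped
    with a warning.  Returns a DataFrame sorted by condition and line
    with columns s_t, t_statistic, p_raw, p_adjusted, significant.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = assay.copy()
    df = df[df["cells"] > 0]
    df["g"] = np.exp(np.log(df["cells"] / inoculum_cells) / elapsed_days)

    rows: list[dict] = []
    for condition, sub in df.groupby("condition", sort=True):
        control_g = sub.loc[sub["is_control"], "g"].to_numpy(dtype=float)
        if control_g.size < 2:
            warnings.warn(f"condition {condition!r}: <2 control replicates, skipped")
            continue
        g_control = control_g.mean()
        for line_id, line_sub in sub[~sub["is_control"]].groupby("line_id", sort=True):
            ma_g = line_sub["g"].to_numpy(dtype=float)
            if ma_g.size < 2:
                warnings.warn(
                    f"line {line_id!r} in {condition!r}: <2 replicates, skipped"
                )
                continue
            t_res = sps.ttest_ind(ma_g, control_g, equal_var=not welch)
            rows.append(
                {
                    "condition": condition,
                    "line_id": line_id,
                    "s_t": selection_coefficient(
                        ma_g.mean(), g_control, variant=st_variant
                    ),
                    "t_statistic": float(t_res.statistic),
                    "p_raw": float(t_res.pvalue),
                }
            )
    result = pd.DataFrame(
        rows, columns=["condition", "line_id", "s_t", "t_statistic", "p_raw"]
    )
    if result.empty:
        result["p_adjusted"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
        return result
    if family == "global":
        result["p_adjusted"] = holm_adjust(result["p_raw"])
    else:
        result["p_adjusted"] = result.groupby("condition")["p_raw"].transform(
            lambda p: holm_adjust(p.to_numpy())
        )
    result["significant"] = result["p_adjusted"] < alpha
    return result.sort_values(["condition", "line_id"]).reset_index(drop=True)


def variance_ratio_test(
    condition_values: Sequence[float],
    reference_values: Sequence[float],
    condition: str = "condition",
    reference_condition: str = "reference",
) -> VarianceTestResult:
    """Fisher–Snedecor two-sided test of a variance change versus reference.

    F = var(condition) / var(reference) with (n1-1, n2-1) degrees of
    freedom; two-sided p = 2 · min(P(F' ≥ F), P(F' ≤ F)), capped at 1.
    An inflated variance under stress indicates mutations whose effects
    are revealed only in that environment.
    """
    x = np.asarray(condition_values, dtype=float)
    y = np.asarray(reference_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 values per group")
    var_x = x.var(ddof=1)
    var_y = y.var(ddof=1)
    if var_y == 0:
        raise ValueError("zero reference variance")
    f = var_x / var_y
    df1, df2 = x.size - 1, y.size - 1
    if var_x == var_y and df1 == df2:
        return VarianceTestResult(
            condition, reference_condition, 1.0, 1.0, df1, df2
        )
    p = 2.0 * min(sps.f.sf(f, df1, df2), sps.f.cdf(f, df1, df2))
    return VarianceTestResult(
        condition, reference_condition, float(f), float(min(p, 1.0)), df1, df2
    )


def stress_confirmation(
    control_standard: Sequence[float], control_condition: Sequence[float]
) -> StressCheckResult:
    """Check that a condition is stressful for the control populations.

    Wilcoxon rank-sum test of control growth in the condition against the
    standard condition.  A condition is stressful when the difference is
    significant (p < 0.05) AND the mean condition growth is lower — a
    significantly *faster* condition (as low salinity can be) is not
    stress.  Growth-reduction percent is 100·(1 - mean_cond/mean_std).
    """
    std = np.asarray(control_standard, dtype=float)
    cond = np.asarray(control_condition, dtype=float)
    if std.size < 2 or cond.size < 2:
        raise ValueError("need >= 2 values per group")
    reduction = 100.0 * (1.0 - cond.mean() / std.mean())
    pooled = np.concatenate([std, cond])
    if np.ptp(pooled) == 0:
        return StressCheckResult(float("nan"), False, reduction, undefined=True)
    p = float(sps.ranksums(cond, std).pvalue)
    stressful = p < 0.05 and cond.mean() < std.mean()
    return StressCheckResult(p, stressful, reduction)


def classify_lines(results: pd.DataFrame) -> pd.DataFrame:
    """Per-line counts of significantly negative / positive / n.s. conditions.

    Input is the battery output (columns line_id, condition, s_t,
    significant).  A line can be counted in both directions if its S_T is
    significantly negative in one condition and positive in another.  The
    aggregate — how many lines are significant in >= 1 condition per
    direction — is available from the returned table as
    ``(out["n_negative"] > 0).sum()`` and likewise for positive.
    """
    if results.empty:
        return pd.DataFrame(
            columns=["line_id", "n_negative", "n_positive", "n_nonsignificant"]
        )
    sig = results["significant"].to_numpy(dtype=bool)
    neg = sig & (results["s_t"].to_numpy() < 0)
    pos = sig & (results["s_t"].to_numpy() > 0)
    out = (
        pd.DataFrame(
            {
                "line_id": results["line_id"],
                "n_negative": neg.astype(int),
                "n_positive": pos.astype(int),
                "n_nonsignificant": (~sig).astype(int),
            }
        )
        .groupby("line_id", as_index=False)
        .sum()
        .sort_values("line_id")
        .reset_index(drop=True)
    )
    return out
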