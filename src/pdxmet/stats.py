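"""Group-comparison statistics mirroring the study conventions.

Imaging metrics (T2w components, ADC, L/P AUC ratio, growth rate) are
compared across lines by one-way ANOVA with Tukey's post-hoc test and
reported as mean +- SD; metabolic assays use Welch's unequal-variance
t-test (pairwise) or two-way ANOVA (metabolite x group) and are reported
as mean +- SE. Significance is fixed at p < 0.05 with no correction
beyond Tukey.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ComparisonResult", "growth_rate", "compare_groups",
           "two_way_anova", "ALPHA"]

ALPHA = 0.05


@dataclass
class ComparisonResult:
    metric: str
    test: str
    statistic: float
    pvalue: float
    group_stats: pd.DataFrame  # group, n, mean, sd, se
    posthoc: pd.DataFrame | None = None  # Tukey pairs, when requested
    significant: bool = False
    error_convention: str = "sd"  # sd for imaging metrics, se for metabolic
    notes: str = ""
    extra: dict = field(default_factory=dict)


def growth_rate(volumes, days) -> float:
    """Tumor growth rate (cc/day): OLS slope over the last 3 measurements.

    Requires at least 3 volume/time pairs and refuses fewer; earlier
    measurements are ignored by construction.
    """
    volumes = np.asarray(volumes, dtype=float)
    days = np.asarray(days, dtype=float)
    if volumes.size != days.size:
        raise ValueError("volumes and days must align")
    if volumes.size < 3:
        raise ValueError("growth rate needs at least 3 measurements")
    slope, _ = np.polyfit(days[-3:], volumes[-3:], 1)
    return float(slope)


def _group_arrays(df: pd.DataFrame, value: str, group: str) -> dict[str, np.ndarray]:
    out = {}
    for g, sub in df.groupby(group, sort=True):
        vals = sub[value].dropna().to_numpy(dtype=float)
        if vals.size:
            out[str(g)] = vals
    return out


def _group_stats(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for g, vals in groups.items():
        sd = float(vals.std(ddof=1)) if vals.size > 1 else np.nan
        rows.append({"group": g, "n": int(vals.size),
                     "mean": float(vals.mean()), "sd": sd,
                     "se": sd / np.sqrt(vals.size) if vals.size > 1 else np.nan})
    return pd.DataFrame(rows)


def compare_groups(df: pd.DataFrame, value: str, group: str,
                   test: str = "anova_tukey", metric: str | None = None
                   ) -> ComparisonResult:
    """Compare a metric across groups with the named procedure.

    ``test`` is one of ``"anova_tukey"`` (one-way ANOVA, Tukey post hoc),
    ``"welch_t"`` (unequal-variance t-test, 2 groups), ``"students_t"``
    (unpaired t-test, 2 groups). Raises ``ValueError`` when group sizes
    are insufficient for the requested procedure.
    """
    metric = metric or value
    groups = _group_arrays(df, value, group)
    if test == "anova_tukey":
        if len(groups) < 2 or any(v.size < 2 for v in groups.values()):
            raise ValueError("ANOVA needs >= 2 groups with >= 2 observations each")
        f_stat, pval = sps.f_oneway(*groups.values())
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        flat = df.dropna(subset=[value])
        tk = pairwise_tukeyhsd(flat[value].to_numpy(dtype=float),
                               flat[group].astype(str).to_numpy(), alpha=ALPHA)
        posthoc = pd.DataFrame(tk.summary().data[1:],
                               columns=tk.summary().data[0])
        return ComparisonResult(metric=metric, test=test, statistic=float(f_stat),
                                pvalue=float(pval), group_stats=_group_stats(groups),
                                posthoc=posthoc, significant=bool(pval < ALPHA))
    if test in ("welch_t", "students_t"):
        if len(groups) != 2:
            raise ValueError("t-tests need exactly 2 groups")
        if any(v.size < 2 for v in groups.values()):
            raise ValueError("t-tests need >= 2 observations per group")
        a, b = groups.values()
        t_stat, pval = sps.ttest_ind(a, b, equal_var=(test == "students_t"))
        return ComparisonResult(metric=metric, test=test, statistic=float(t_stat),
                                pvalue=float(pval), group_stats=_group_stats(groups),
                                significant=bool(pval < ALPHA),
                                error_convention="se" if test == "welch_t" else "sd")
    raise ValueError(f"unknown test {test!r}")


def two_way_anova(df: pd.DataFrame, value: str, factor_a: str,
                  factor_b: str) -> pd.DataFrame:
    """Two-way ANOVA (e.g., metabolite x group) via an OLS fit.

    Returns the type-II ANOVA table with F statistics and p-values for
    both main effects and their interaction.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = df[[value, factor_a, factor_b]].dropna().rename(
        columns={value: "y", factor_a: "fa", factor_b: "fb"})
    if data["fa"].nunique() < 2 or data["fb"].nunique() < 2:
        raise ValueError("two-way ANOVA needs >= 2 levels per factor")
    model = smf.ols("y ~ C(fa) * C(fb)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(index={"C(fa)": factor_a, "C(fb)": factor_b,
                                "C(fa):C(fb)": f"{factor_a}:{factor_b}"})
    return table
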