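"""Cohort-level statistics for treatment-response read-outs.

Endpoint-only quantities (histology H-scores) are compared across arms by
one-way ANOVA with Tukey's HSD correction for the pairwise contrasts;
longitudinal imaging metrics are tested by ANCOVA — a linear model of the
post-treatment value with the pre-treatment value as covariate and the
treatment arm as factor.  p < 0.05 is the significance convention
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["AnovaTukeyResult", "AncovaResult", "anova_tukey", "ancova_longitudinal",
           "ALPHA"]

ALPHA = 0.05


@dataclass
class AnovaTukeyResult:
    """One-way ANOVA with Tukey HSD pairwise contrasts."""

    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame         # group1, group2, meandiff, p_adj, significant
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        self.significant = bool(self.p_value < ALPHA)


def anova_tukey(values, groups) -> AnovaTukeyResult:
    """One-way ANOVA F-test plus Tukey honestly-significant-difference
    adjusted pairwise p-values.

    Requires at least two groups with at least two values each and
    non-zero within-group variance (the F statistic is undefined
    otherwise).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have the same length")
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if np.any(counts < 2):
        raise ValueError("every group needs at least 2 values")
    ss_within = sum(np.sum((values[groups == g] - values[groups == g].mean()) ** 2)
                    for g in uniq)
    if ss_within == 0:
        raise ValueError("zero within-group variance: ANOVA degenerate")

    df = pd.DataFrame({"value": values, "group": groups.astype(str)})
    fit = smf.ols("value ~ C(group)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=1)
    f_stat = float(table["F"].iloc[0])
    p = float(table["PR(>F)"].iloc[0])

    tk = pairwise_tukeyhsd(values, groups.astype(str), alpha=ALPHA)
    pairs = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    pairwise = pd.DataFrame({
        "group1": pairs["group1"],
        "group2": pairs["group2"],
        "meandiff": pairs["meandiff"].astype(float),
        "p_adj": np.asarray(tk.pvalues, dtype=float),
        "significant": np.asarray(tk.reject, dtype=bool),
    })
    return AnovaTukeyResult(f_statistic=f_stat, p_value=p, pairwise=pairwise)


@dataclass
class AncovaResult:
    """Group effect from the model post ~ pre + group."""

    f_statistic: float
    p_value: float
    coefficients: pd.Series        # OLS coefficients of the fitted model
    adjusted_means: pd.Series      # per-arm predicted post at the mean pre
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        self.significant = bool(self.p_value < ALPHA)


def ancova_longitudinal(post, pre, groups) -> AncovaResult:
    """ANCOVA of post-treatment values with the pre-treatment covariate.

    Fits ``post ~ pre + C(group)`` by OLS and reports the group-effect
    F-test (type II, so the covariate is always adjusted for) together
    with per-arm adjusted means (predicted post at the grand-mean pre).
    Every tumor must have both a pre and a post value.
    """
    post = np.asarray(post, dtype=float)
    pre = np.asarray(pre, dtype=float)
    groups = np.asarray(groups)
    if not (len(post) == len(pre) == len(groups)):
        raise ValueError("post, pre and groups must have the same length")
    if np.any(~np.isfinite(pre)) or np.any(~np.isfinite(post)):
        raise ValueError("missing pre/post value: longitudinal pairing incomplete")
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 groups")

    df = pd.DataFrame({"post": post, "pre": pre, "group": groups.astype(str)})
    fit = smf.ols("post ~ pre + C(group)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    f_stat = float(table.loc["C(group)", "F"])
    p = float(table.loc["C(group)", "PR(>F)"])
    ss_group = float(table.loc["C(group)", "sum_sq"])
    ss_total = float(np.sum((post - post.mean()) ** 2))
    if ss_total == 0 or ss_group <= 1e-10 * ss_total:
        # the covariate explains (essentially) everything: the group sum of
        # squares is numerically zero, the F ratio is 0/0 noise, and there
        # is no group effect to detect
        f_stat, p = 0.0, 1.0

    grid = pd.DataFrame({"pre": df["pre"].mean(),
                         "group": np.unique(df["group"])})
    adjusted = pd.Series(fit.predict(grid).to_numpy(), index=grid["group"].to_numpy())
    return AncovaResult(f_statistic=f_stat, p_value=p,
                        coefficients=fit.params, adjusted_means=adjusted)
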