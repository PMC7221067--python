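"""Normality-gated statistical dispatch for phenotype measurements.

Group comparisons (triglycerides, body mass, activity levels, densitometry
ratios, climbing scores) are routed by a Shapiro-Wilk gate: if every group
looks Gaussian (p >= alpha_norm) the parametric branch runs (unpaired t-test
for two groups, one-way ANOVA for more), otherwise the rank-based branch
(Mann-Whitney U, Kruskal-Wallis).  The gate decision and per-group normality
p-values are always part of the result, so the routing is auditable.

Two-factor layouts (e.g. genotype x age) get a two-way ANOVA with
interaction followed by Sidak-adjusted pairwise comparisons,
p_adj = 1 - (1 - p)^m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

__all__ = [
    "DispatchResult",
    "dispatch_test",
    "two_way_with_sidak",
    "sidak_adjust",
    "climbing_score",
]


def sidak_adjust(p, m: int):
    """Sidak multiple-comparison adjustment, p_adj = 1 - (1-p)^m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 - (1.0 - np.asarray(p, dtype=float)) ** m


@dataclass
class DispatchResult:
    """Outcome of a gated comparison, with the gate's audit trail."""

    test: str
    statistic: float
    p_value: float
    parametric: bool
    normality_p: dict[str, float]
    groups: list[str]
    effect_direction: Optional[str] = None    # two-group only: which mean is larger
    anova_table: Optional[pd.DataFrame] = None
    posthoc: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        return {
            "test": self.test, "statistic": self.statistic, "p_value": self.p_value,
            "parametric": self.parametric, "groups": ",".join(self.groups),
            "effect_direction": self.effect_direction,
            **{f"shapiro_p[{g}]": p for g, p in self.normality_p.items()},
        }


def _groups_from_frame(ms: pd.DataFrame) -> dict[str, np.ndarray]:
    if not {"group", "value"} <= set(ms.columns):
        raise ValueError("measurement frame needs 'group' and 'value' columns")
    out = {str(g): sub["value"].to_numpy(dtype=float)
           for g, sub in ms.groupby("group", sort=False)}
    for g, v in out.items():
        if len(v) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples")
    return out


def dispatch_test(ms: pd.DataFrame, alpha_norm: float = 0.05,
                  welch: bool = False) -> DispatchResult:
    """Shapiro-Wilk-gated two-group or k-group comparison.

    All groups must pass normality (p >= alpha_norm) for the parametric
    branch; a single failing group switches the whole comparison to the
    rank-based branch.
    """
    groups = _groups_from_frame(ms)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    norm_p = {g: float(stats.shapiro(v).pvalue) for g, v in groups.items()}
    parametric = all(p >= alpha_norm for p in norm_p.values())
    values = list(groups.values())
    labels = list(groups)

    direction = None
    if len(groups) == 2:
        m0, m1 = values[0].mean(), values[1].mean()
        direction = f"{labels[0]} > {labels[1]}" if m0 > m1 else f"{labels[1]} > {labels[0]}"
        if parametric:
            res = stats.ttest_ind(values[0], values[1], equal_var=not welch)
            name = "welch-t" if welch else "t-test"
        else:
            res = stats.mannwhitneyu(values[0], values[1], alternative="two-sided")
            name = "mann-whitney"
    else:
        if parametric:
            res = stats.f_oneway(*values)
            name = "one-way-anova"
        else:
            res = stats.kruskal(*values)
            name = "kruskal-wallis"
    return DispatchResult(
        test=name, statistic=float(res.statistic), p_value=float(res.pvalue),
        parametric=parametric, normality_p=norm_p, groups=labels,
        effect_direction=direction,
    )


def two_way_with_sidak(ms: pd.DataFrame, factor_a: str = "group",
                       factor_b: str = "factor2") -> DispatchResult:
    """Two-way ANOVA (main effects + interaction) with Sidak post hoc.

    Post hoc compares levels of ``factor_a`` pairwise within each level of
    ``factor_b`` by unpaired t-tests, Sidak-adjusted over all m comparisons.
    The headline statistic/p reported is the interaction term.
    """
    for col in (factor_a, factor_b, "value"):
        if col not in ms.columns:
            raise ValueError(f"missing column {col!r}")
    counts = ms.groupby([factor_a, factor_b], sort=False).size()
    levels_a = ms[factor_a].unique()
    levels_b = ms[factor_b].unique()
    if len(counts) < len(levels_a) * len(levels_b):
        raise ValueError("incomplete two-factor layout: empty cell")

    d = ms.rename(columns={factor_a: "A", factor_b: "B"})
    model = ols("value ~ C(A) * C(B)", data=d).fit()
    table = sm.stats.anova_lm(model, typ=2)

    rows = []
    for lb in levels_b:
        sub = ms[ms[factor_b] == lb]
        for i, a1 in enumerate(levels_a):
            for a2 in levels_a[i + 1:]:
                v1 = sub.loc[sub[factor_a] == a1, "value"]
                v2 = sub.loc[sub[factor_a] == a2, "value"]
                t = stats.ttest_ind(v1, v2)
                rows.append({factor_b: lb, "level_1": a1, "level_2": a2,
                             "t": float(t.statistic), "p_raw": float(t.pvalue)})
    posthoc = pd.DataFrame(rows)
    posthoc["p_sidak"] = sidak_adjust(posthoc["p_raw"].to_numpy(), len(posthoc))

    inter = table.index[table.index.str.contains(":")][0]
    return DispatchResult(
        test="two-way-anova+sidak",
        statistic=float(table.loc[inter, "F"]),
        p_value=float(table.loc[inter, "PR(>F)"]),
        parametric=True,
        normality_p={},
        groups=[str(a) for a in levels_a],
        anova_table=table,
        posthoc=posthoc,
    )


def climbing_score(trials: pd.DataFrame) -> float:
    """Reduce a 5-trial climbing session to one score.

    Each trial contributes the mean normalized height of its flies at the
    4-s mark; the score is the mean over the 5 trials (one datum per
    vial-session).  Invariant to fly and trial ordering.
    """
    if not {"trial", "height"} <= set(trials.columns):
        raise ValueError("climbing frame needs 'trial' and 'height' columns")
    per_trial = trials.groupby("trial")["height"].mean()
    if len(per_trial) != 5:
        raise ValueError(f"expected exactly 5 trials, got {len(per_trial)}")
    lo, hi = trials["height"].min(), trials["height"].max()
    if lo < 0 or hi > 1:
        raise ValueError("heights must be normalized to [0, 1]")
    return float(per_trial.mean())
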