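"""Kaplan-Meier estimation and lifespan comparison machinery.

Wraps lifelines' product-limit estimator and weighted rank tests behind the
tidy event-table convention used throughout the package: a DataFrame with
columns fly_id, genotype, condition, time, event (1 = death, 0 = right
censored), and optionally time_unit.  Starvation-resistance tables use the
same machinery with time in hours; the unit is a property of the data.

The log-rank test is the unweighted risk-set test; Gehan-Wilcoxon applies
Gehan-Breslow weights (weight = number at risk), emphasizing early deaths.
Families of pairwise comparisons are corrected with Bonferroni (default) or
Holm.  Maximum lifespan has no universal definition, so every summary is
tagged with the definition used (top-decile mean death age by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from statsmodels.stats.multitest import multipletests

__all__ = [
    "KMCurve",
    "MedianLifespan",
    "MaxLifespan",
    "SurvTestResult",
    "AdditivityReport",
    "km_estimate",
    "median_lifespan",
    "maximum_lifespan",
    "logrank_test",
    "gehan_wilcoxon_test",
    "multi_compare",
    "lifespan_summary",
    "additivity_report",
]

REQUIRED_COLUMNS = ("genotype", "time", "event")


def _validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"survival table missing columns: {missing}")
    if (table["time"] <= 0).any():
        raise ValueError("event times must be > 0")
    if not table["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 (censored) or 1 (death)")


def _group(table: pd.DataFrame, group: str) -> pd.DataFrame:
    sub = table[table["genotype"] == group]
    if sub.empty:
        raise ValueError(f"no records for group {group!r}")
    return sub


@dataclass
class KMCurve:
    """Product-limit survival estimate for one group."""

    group: str
    times: np.ndarray          # distinct observed times, ascending
    survival: np.ndarray       # S(t) just after each time
    at_risk: np.ndarray
    observed: np.ndarray       # deaths at each time

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t (right-continuous)."""
        i = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])


def km_estimate(table: pd.DataFrame, group: str) -> KMCurve:
    """Kaplan-Meier curve for one genotype, ties by simultaneous decrement."""
    _validate_table(table)
    sub = _group(table, group)
    if int(sub["event"].sum()) < 1:
        raise ValueError(f"group {group!r} has no death events")
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time"], event_observed=sub["event"])
    et = kmf.event_table.drop(index=0.0, errors="ignore")
    times = et.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].reindex(et.index).to_numpy()
    return KMCurve(
        group=group,
        times=times,
        survival=surv,
        at_risk=et["at_risk"].to_numpy(dtype=int),
        observed=et["observed"].to_numpy(dtype=int),
    )


@dataclass
class MedianLifespan:
    """Smallest time with S(t) <= 0.5; flagged undefined if never reached."""

    time: float
    defined: bool


def median_lifespan(curve: KMCurve) -> MedianLifespan:
    below = curve.survival <= 0.5
    if below.any():
        return MedianLifespan(float(curve.times[np.argmax(below)]), defined=True)
    return MedianLifespan(float("nan"), defined=False)


@dataclass
class MaxLifespan:
    """Maximum-lifespan summary, always tagged with its definition."""

    group: str
    value: float
    definition: str
    n_deaths: int
    fell_back: bool = False


def maximum_lifespan(table: pd.DataFrame, group: str,
                     definition: str = "top_decile_mean") -> MaxLifespan:
    """Summarize the longest-lived tail of the dying flies.

    ``top_decile_mean``: mean death age of the longest-lived 10% of dying
    flies (needs >= 10 deaths, otherwise falls back to ``last_death`` with a
    flag); ``last_death``: age of the last death; ``percentile_90``: linear
    interpolation percentile of death ages.
    """
    _validate_table(table)
    sub = _group(table, group)
    deaths = np.sort(sub.loc[sub["event"] == 1, "time"].to_numpy(dtype=float))
    if deaths.size == 0:
        raise ValueError(f"group {group!r} has no death events")
    if definition == "top_decile_mean":
        if deaths.size < 10:
            return MaxLifespan(group, float(deaths[-1]), "last_death",
                               deaths.size, fell_back=True)
        k = max(1, int(np.ceil(0.1 * deaths.size)))
        return MaxLifespan(group, float(deaths[-k:].mean()), definition, deaths.size)
    if definition == "last_death":
        return MaxLifespan(group, float(deaths[-1]), definition, deaths.size)
    if definition == "percentile_90":
        return MaxLifespan(group, float(np.percentile(deaths, 90)), definition,
                           deaths.size)
    raise ValueError(f"unknown maximum-lifespan definition {definition!r}")


@dataclass
class SurvTestResult:
    """One two-group survival-curve comparison."""

    group_a: str
    group_b: str
    test: str                  # "log-rank" or "gehan-wilcoxon"
    statistic: float
    df: int
    p_raw: float
    n_a: int
    n_b: int
    p_adjusted: Optional[float] = None
    correction: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "group_a": self.group_a, "group_b": self.group_b, "test": self.test,
            "statistic": self.statistic, "df": self.df, "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted, "correction": self.correction,
            "n_a": self.n_a, "n_b": self.n_b,
        }


def _rank_test(table: pd.DataFrame, group_a: str, group_b: str,
               weightings: Optional[str], name: str) -> SurvTestResult:
    _validate_table(table)
    a, b = _group(table, group_a), _group(table, group_b)
    for g, sub in ((group_a, a), (group_b, b)):
        if int(sub["event"].sum()) < 1:
            raise ValueError(f"group {g!r} has no death events")
    res = _ll_logrank(
        a["time"], b["time"],
        event_observed_A=a["event"], event_observed_B=b["event"],
        weightings=weightings,
    )
    return SurvTestResult(
        group_a=group_a, group_b=group_b, test=name,
        statistic=float(res.test_statistic), df=1, p_raw=float(res.p_value),
        n_a=len(a), n_b=len(b),
    )


def logrank_test(table: pd.DataFrame, group_a: str, group_b: str) -> SurvTestResult:
    """Unweighted log-rank chi-square (1 df), two-sided."""
    return _rank_test(table, group_a, group_b, None, "log-rank")


def gehan_wilcoxon_test(table: pd.DataFrame, group_a: str, group_b: str) -> SurvTestResult:
    """Gehan-Breslow-Wilcoxon test: risk-set sums weighted by number at risk."""
    return _rank_test(table, group_a, group_b, "wilcoxon", "gehan-wilcoxon")


def _adjust(pvals: Sequence[float], method: str) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if method == "bonferroni":
        return np.minimum(1.0, p * len(p))
    if method == "holm":
        return multipletests(p, method="holm")[1]
    raise ValueError(f"unknown correction method {method!r}")


def multi_compare(table: pd.DataFrame, comparisons: Iterable[tuple[str, str]],
                  method: str = "bonferroni",
                  tests: Sequence[str] = ("log-rank", "gehan-wilcoxon"),
                  ) -> list[SurvTestResult]:
    """Run both rank tests on each pair, correcting within each test family.

    The correction spans the ``m = len(comparisons)`` pairs; log-rank and
    Gehan-Wilcoxon families are corrected separately.
    """
    pairs = list(comparisons)
    if not pairs:
        raise ValueError("at least one comparison required")
    seen = set()
    for a, b in pairs:
        key = frozenset((a, b))
        if key in seen:
            raise ValueError(f"duplicate comparison {a!r} vs {b!r}")
        seen.add(key)
    runners = {"log-rank": logrank_test, "gehan-wilcoxon": gehan_wilcoxon_test}
    results: list[SurvTestResult] = []
    for test in tests:
        family = [runners[test](table, a, b) for a, b in pairs]
        adjusted = _adjust([r.p_raw for r in family], method)
        for r, p_adj in zip(family, adjusted):
            r.p_adjusted = float(p_adj)
            r.correction = method
        results.extend(family)
    return results


def lifespan_summary(table: pd.DataFrame, groups: Optional[Sequence[str]] = None,
                     max_definition: str = "top_decile_mean") -> pd.DataFrame:
    """Median (KM-based) and tagged maximum lifespan per group."""
    _validate_table(table)
    if groups is None:
        groups = list(table["genotype"].unique())
    rows = []
    for g in groups:
        med = median_lifespan(km_estimate(table, g))
        mx = maximum_lifespan(table, g, max_definition)
        rows.append({
            "group": g, "n": int((table["genotype"] == g).sum()),
            "median": med.time, "median_defined": med.defined,
            "maximum": mx.value, "max_definition": mx.definition,
        })
    return pd.DataFrame(rows)


@dataclass
class AdditivityReport:
    """Decision on whether a double mutant adds to its single mutants.

    non-additive: both singles extend (differ from control) yet the double
    is indistinguishable from either single.  additive-consistent: the
    double differs from both singles and survives longer.  Otherwise
    inconclusive.  Decisions use corrected log-rank p-values.
    """

    verdict: str
    alpha: float
    correction: str
    tests: list[SurvTestResult]

    def p_adjusted(self, a: str, b: str, test: str = "log-rank") -> float:
        for r in self.tests:
            if r.test == test and {r.group_a, r.group_b} == {a, b}:
                return r.p_adjusted
        raise KeyError(f"no {test} comparison {a!r} vs {b!r}")


def additivity_report(table: pd.DataFrame, control: str, single_a: str,
                      single_b: str, double: str, alpha: float = 0.05,
                      method: str = "bonferroni") -> AdditivityReport:
    """Test whether a double mutant's lifespan effect exceeds its singles'."""
    for g in (control, single_a, single_b, double):
        _group(table, g)  # raises on missing group
    pairs = [(single_a, control), (single_b, control), (double, control),
             (double, single_a), (double, single_b)]
    tests = multi_compare(table, pairs, method=method)
    rep = AdditivityReport(verdict="inconclusive", alpha=alpha,
                           correction=method, tests=tests)
    sig = lambda a, b: rep.p_adjusted(a, b) < alpha
    singles_extend = sig(single_a, control) and sig(single_b, control)
    double_vs_singles = sig(double, single_a), sig(double, single_b)
    if singles_extend and not any(double_vs_singles):
        rep.verdict = "non-additive"
    elif all(double_vs_singles):
        med = {g: median_lifespan(km_estimate(table, g)) for g in
               (single_a, single_b, double)}
        vals = {g: (m.time if m.defined else np.inf) for g, m in med.items()}
        if vals[double] > max(vals[single_a], vals[single_b]):
            rep.verdict = "additive-consistent"
    return rep
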