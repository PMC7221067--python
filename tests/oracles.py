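"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid lifelines/statsmodels code paths: risk sets are
enumerated time-by-time with plain loops, and the Kaplan-Meier product is
accumulated directly from its definition.
"""

from __future__ import annotations

import numpy as np


def rank_test_statistic(t_a, e_a, t_b, e_b, gehan: bool = False) -> float:
    """Chi-square of the (weighted) two-sample rank test by risk-set enumeration.

    At each distinct death time: n at risk (total and in group A), d deaths
    (total and in A); contribution O-E = d_A - d * nA/n with hypergeometric
    variance; Gehan weights each term by n at risk.
    """
    t = np.concatenate([np.asarray(t_a, float), np.asarray(t_b, float)])
    e = np.concatenate([np.asarray(e_a, int), np.asarray(e_b, int)])
    in_a = np.concatenate([np.ones(len(t_a), bool), np.zeros(len(t_b), bool)])
    obs_minus_exp = 0.0
    var = 0.0
    for tj in np.unique(t[e == 1]):
        at_risk = t >= tj
        n = int(at_risk.sum())
        n1 = int((at_risk & in_a).sum())
        dying = (t == tj) & (e == 1)
        d = int(dying.sum())
        d1 = int((dying & in_a).sum())
        w = float(n) if gehan else 1.0
        obs_minus_exp += w * (d1 - d * n1 / n)
        if n > 1:
            var += w * w * d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return obs_minus_exp**2 / var


def km_survival(times, events, eval_times) -> np.ndarray:
    """Product-limit S(t) accumulated straight from its definition."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = []
    for t in np.asarray(eval_times, float):
        s = 1.0
        for tj in np.unique(times[(events == 1) & (times <= t)]):
            n = (times >= tj).sum()
            d = ((times == tj) & (events == 1)).sum()
            s *= 1.0 - d / n
        out.append(s)
    return np.array(out)


def empirical_survival(times, eval_times) -> np.ndarray:
    """Fraction still alive strictly after each evaluation time."""
    times = np.asarray(times, float)
    return np.array([(times > t).mean() for t in np.asarray(eval_times, float)])
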