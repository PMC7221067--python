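"""Flow-through respirometry trace processing.

Turns raw 1-Hz CO2 recordings of single flies into mass-corrected metabolic
rate (MR) and an activity index, extracts standard metabolic rate (SMR), and
tests metabolic-rate homeostasis by regressing MR on activity per 5-minute
segment.

Unit chain
----------
CO2 excess (ppm) above the drifting analyzer baseline is converted to a
volumetric flux::

    VCO2 (uL/h) = ppm * 1e-6 * flow (mL/min) * 60 (min/h) * 1000 (uL/mL)

then to catabolic power with the oxyjoule relation, assuming a respiratory
quotient RQ so that VO2 = VCO2 / RQ::

    power (uW) = VO2 (uL/h) * (16 + 5.164 * RQ) J/mL * 1e-3 / 3600 * 1e6

At RQ = 1 the combined coefficient is 5.87889 uW per uL CO2/h (21.164 J per
mL O2).  Power is finally divided by live mass (mg) raised to the 0.856
allometric exponent for tracheate arthropods, giving uW * mg^-0.856.

Activity is summarized through the absolute difference sum (ADS), the
cumulative sum of |x[i] - x[i-1]| of the activity analog; the activity index
of a window of N samples is ADS range / N * 60, i.e. the mean absolute
first difference per minute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RespTrace",
    "CorrectedTrace",
    "SmrEstimate",
    "HomeostasisResult",
    "oxyjoule_coefficient",
    "uw_per_ul_h",
    "ppm_to_flux",
    "flux_to_power",
    "mass_correct",
    "compute_ads",
    "activity_index",
    "baseline_correct",
    "segment_metrics",
    "standard_metabolic_rate",
    "homeostasis_regression",
]

#: Default allometric mass-scaling exponent for tracheate arthropods.
MASS_EXPONENT = 0.856

#: Default segment length in seconds ("each point is a 5-min recording").
SEGMENT_S = 300


def oxyjoule_coefficient(rq: float = 1.0) -> float:
    """Energy equivalent of oxygen, J per mL O2, as (16 + 5.164 * RQ)."""
    if rq <= 0:
        raise ValueError("respiratory quotient must be > 0")
    return 16.0 + 5.164 * rq


def uw_per_ul_h(rq: float = 1.0) -> float:
    """Microwatt produced per uL CO2 / h, folding in VO2 = VCO2 / RQ."""
    # J/mL O2 * 1e-3 mL/uL / 3600 s/h * 1e6 uW/W == coeff / 3.6
    return oxyjoule_coefficient(rq) / rq / 3.6


def ppm_to_flux(co2_excess_ppm, flow_ml_min: float):
    """Convert CO2 excess (ppm) at a given STP flow (mL/min) to uL CO2 / h.

    flux = ppm * 1e-6 * flow * 60 * 1000 = ppm * flow * 0.06.
    Accepts scalars or arrays; linear, so negative excursions pass through.
    """
    if flow_ml_min <= 0:
        raise ValueError("flow_ml_min must be > 0")
    return np.multiply(co2_excess_ppm, flow_ml_min * 0.06)


def flux_to_power(vco2_ul_h, rq: float = 1.0, *, allow_negative: bool = False):
    """Convert CO2 flux (uL/h) to metabolic power (uW) via the oxyjoule relation."""
    v = np.asarray(vco2_ul_h, dtype=float)
    if not allow_negative and np.any(v < 0):
        raise ValueError("negative CO2 flux; pass allow_negative=True to retain")
    out = v * uw_per_ul_h(rq)
    return float(out) if np.isscalar(vco2_ul_h) else out


def mass_correct(power_uw, mass_mg: float, exponent: float = MASS_EXPONENT):
    """Divide power by mass^exponent to remove the allometric size effect."""
    if mass_mg <= 0:
        raise ValueError("mass_mg must be > 0")
    return np.divide(power_uw, mass_mg**exponent)


def compute_ads(activity) -> np.ndarray:
    """Absolute difference sum of an activity series.

    ADS[0] = 0 and ADS[k] = sum_{i<=k} |activity[i] - activity[i-1]|;
    non-decreasing by construction and invariant to constant offsets.
    """
    a = np.asarray(activity, dtype=float)
    if a.ndim != 1 or a.size < 2:
        raise ValueError("activity series must be 1-D with length >= 2")
    ads = np.empty_like(a)
    ads[0] = 0.0
    np.cumsum(np.abs(np.diff(a)), out=ads[1:])
    return ads


def activity_index(ads, n: int) -> float:
    """Activity index = (max(ADS) - min(ADS)) / n * 60.

    ``n`` is the number of samples (= seconds at 1 Hz), so the index is the
    mean absolute first difference of the activity analog per minute.
    """
    ads = np.asarray(ads, dtype=float)
    if len(ads) != n:
        raise ValueError(f"n={n} does not match ADS length {len(ads)}")
    if n < 2:
        raise ValueError("need at least 2 samples")
    return float((ads.max() - ads.min()) / n * 60.0)


@dataclass
class RespTrace:
    """One synchronized 1-Hz respirometry recording of a single fly.

    Baseline windows are half-open index ranges ``(start, stop)`` into the
    channels; the fly segment is everything between them.
    """

    time_s: np.ndarray
    co2_ppm: np.ndarray
    activity: np.ndarray
    temp_c: np.ndarray
    flow_ml_min: float
    baseline_pre: tuple[int, int]
    baseline_post: tuple[int, int]
    fly_id: str = "fly"
    genotype: str = "control"
    age_class: str = "young"
    live_mass_mg: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("time_s", "co2_ppm", "activity", "temp_c"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.time_s)
        if any(len(getattr(self, c)) != n for c in ("co2_ppm", "activity", "temp_c")):
            raise ValueError("all channels must have equal length")
        step = np.diff(self.time_s)
        if n >= 2 and not np.allclose(step, 1.0):
            bad = int(np.flatnonzero(~np.isclose(step, 1.0))[0])
            raise ValueError(f"time must increase in unit (1 s) steps; first bad step at index {bad}")
        if self.flow_ml_min <= 0:
            raise ValueError("flow_ml_min must be > 0")
        if self.live_mass_mg <= 0:
            raise ValueError("live_mass_mg must be > 0")
        p0, p1 = self.baseline_pre
        q0, q1 = self.baseline_post
        if not (0 <= p0 < p1 <= q0 < q1 <= n):
            raise ValueError(
                "baseline windows must be non-empty, disjoint and flank the fly segment"
            )
        if self.age_class not in ("young", "old"):
            raise ValueError("age_class must be 'young' or 'old'")

    @property
    def fly_slice(self) -> slice:
        """Index range of the fly segment (between the baseline windows)."""
        return slice(self.baseline_pre[1], self.baseline_post[0])

    @property
    def n_samples(self) -> int:
        return len(self.time_s)


@dataclass
class CorrectedTrace:
    """Baseline-corrected CO2 excess over the fly segment, with drift provenance."""

    time_s: np.ndarray
    co2_excess_ppm: np.ndarray
    drift_intercept: float
    drift_slope: float


def baseline_correct(trace: RespTrace, method: str = "window_means") -> CorrectedTrace:
    """Remove linear analyzer drift using the flanking baseline windows.

    ``window_means`` (default) draws the drift line through the two points
    (center of pre-window, mean pre ppm) and (center of post-window, mean
    post ppm).  ``regression`` fits ordinary least squares to all baseline
    samples instead.  The corrected series is raw minus line, restricted to
    the fly segment; negative values are retained, never clipped.
    """
    for name, (a, b) in (("pre", trace.baseline_pre), ("post", trace.baseline_post)):
        if b - a < 1:
            raise ValueError(f"baseline {name} window is empty")
    bad = np.flatnonzero(~np.isfinite(trace.co2_ppm))
    if bad.size:
        raise ValueError(f"non-finite CO2 ppm value at index {int(bad[0])}")

    t = trace.time_s
    pre = slice(*trace.baseline_pre)
    post = slice(*trace.baseline_post)
    if method == "window_means":
        t1, y1 = t[pre].mean(), trace.co2_ppm[pre].mean()
        t2, y2 = t[post].mean(), trace.co2_ppm[post].mean()
        slope = (y2 - y1) / (t2 - t1)
        intercept = y1 - slope * t1
    elif method == "regression":
        tt = np.concatenate([t[pre], t[post]])
        yy = np.concatenate([trace.co2_ppm[pre], trace.co2_ppm[post]])
        slope, intercept = np.polyfit(tt, yy, 1)
    else:
        raise ValueError(f"unknown drift method {method!r}")

    fly = trace.fly_slice
    line = intercept + slope * t[fly]
    return CorrectedTrace(
        time_s=t[fly].copy(),
        co2_excess_ppm=trace.co2_ppm[fly] - line,
        drift_intercept=float(intercept),
        drift_slope=float(slope),
    )


def _mr_series(trace: RespTrace, rq: float, mass_exponent: float,
               drift_method: str = "window_means") -> np.ndarray:
    """Mass-corrected instantaneous MR (uW * mg^-exponent) over the fly segment."""
    corrected = baseline_correct(trace, method=drift_method)
    flux = ppm_to_flux(corrected.co2_excess_ppm, trace.flow_ml_min)
    power = flux_to_power(flux, rq, allow_negative=True)
    return mass_correct(power, trace.live_mass_mg, mass_exponent)


def _activity_rate(trace: RespTrace) -> np.ndarray:
    """Per-sample |first difference| of the activity analog over the fly segment.

    The leading sample is assigned 0, so consecutive windows partition the
    cumulative ADS channel exactly: the sum of this rate over a window equals
    the increment of the full-segment ADS across that window.
    """
    a = trace.activity[trace.fly_slice]
    return np.abs(np.diff(a, prepend=a[:1]))


@dataclass
class SmrEstimate:
    """Standard metabolic rate with the estimator's parameters logged."""

    smr: float
    window_s: int
    quiescence_quantile: float
    used_fallback: bool


def segment_metrics(trace: RespTrace, *, segment_s: int = SEGMENT_S, rq: float = 1.0,
                    mass_exponent: float = MASS_EXPONENT,
                    drift_method: str = "window_means") -> pd.DataFrame:
    """Tile the fly segment into consecutive windows of ``segment_s`` seconds.

    Each row carries the window's mean mass-corrected MR (full conversion
    chain, averaged) and its activity index; the trailing partial window is
    dropped.  Returns a tidy frame with columns fly_id, genotype, age_class,
    segment, t0_s, mean_mr, activity_index.
    """
    cols = ["fly_id", "genotype", "age_class", "segment", "t0_s", "mean_mr", "activity_index"]
    mr = _mr_series(trace, rq, mass_exponent, drift_method)
    n_seg = len(mr) // segment_s
    if n_seg == 0:
        warnings.warn(
            f"fly segment shorter than {segment_s} s; no segments produced", stacklevel=2
        )
        return pd.DataFrame(columns=cols)
    rate = _activity_rate(trace)
    t0 = trace.time_s[trace.fly_slice][0]
    m = n_seg * segment_s
    mean_mr = mr[:m].reshape(n_seg, segment_s).mean(axis=1)
    idx = rate[:m].reshape(n_seg, segment_s).sum(axis=1) / segment_s * 60.0
    return pd.DataFrame(
        {
            "fly_id": trace.fly_id,
            "genotype": trace.genotype,
            "age_class": trace.age_class,
            "segment": np.arange(n_seg),
            "t0_s": t0 + np.arange(n_seg) * segment_s,
            "mean_mr": mean_mr,
            "activity_index": idx,
        }
    )


def standard_metabolic_rate(trace: RespTrace, *, window_s: int = SEGMENT_S,
                            quiescence_quantile: float = 0.2, rq: float = 1.0,
                            mass_exponent: float = MASS_EXPONENT,
                            drift_method: str = "window_means") -> SmrEstimate:
    """Standard metabolic rate: lowest quiescent running-average MR.

    Slides a ``window_s`` window in 1-s steps over the fly segment, keeps the
    windows whose activity index falls in the lowest ``quiescence_quantile``
    of all windows of this recording, and returns the minimum of their mean
    mass-corrected MR.  If no window qualifies the global minimum window mean
    is returned with ``used_fallback=True``.
    """
    mr = _mr_series(trace, rq, mass_exponent, drift_method)
    if len(mr) < window_s:
        raise ValueError(f"fly segment shorter than one {window_s}-s window")
    rate = _activity_rate(trace)
    kernel_means = _sliding_means(mr, window_s)
    idx = _sliding_means(rate, window_s) * 60.0
    threshold = np.quantile(idx, quiescence_quantile)
    quiescent = idx <= threshold
    if quiescent.any():
        return SmrEstimate(float(kernel_means[quiescent].min()), window_s,
                           quiescence_quantile, used_fallback=False)
    return SmrEstimate(float(kernel_means.min()), window_s, quiescence_quantile,
                       used_fallback=True)


def _sliding_means(x: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate([[0.0], np.cumsum(x)])
    return (c[w:] - c[:-w]) / w


@dataclass
class HomeostasisResult:
    """Per-group regression of metabolic rate on activity index.

    ``verdict`` is "lost" when the slope is significantly positive at level
    ``alpha`` (MR rises with activity, i.e. homeostasis is absent) and
    "maintained" otherwise.
    """

    group: str
    n_segments: int
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    ci_low: float
    ci_high: float
    alpha: float
    verdict: str

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "n_segments": self.n_segments,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "p_slope": self.p_slope,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "alpha": self.alpha,
            "verdict": self.verdict,
        }


def homeostasis_regression(segments: pd.DataFrame, group: str,
                           alpha: float = 0.05) -> HomeostasisResult:
    """Ordinary least-squares fit of mean MR on activity index for one group.

    Segments are pooled across flies of the group.  Reports the slope with a
    two-sided t-test against zero and a 95% confidence interval; homeostasis
    is declared lost when the slope is positive with p < alpha.
    """
    x = np.asarray(segments["activity_index"], dtype=float)
    y = np.asarray(segments["mean_mr"], dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 segments for the homeostasis regression")
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: activity index has zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(model.params[1])
    p = float(model.pvalues[1])
    ci = model.conf_int(alpha=0.05)
    verdict = "lost" if (p < alpha and slope > 0) else "maintained"
    return HomeostasisResult(
        group=group,
        n_segments=len(x),
        slope=slope,
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_slope=p,
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        alpha=alpha,
        verdict=verdict,
    )
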