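"""Synthetic respirometry traces, survival cohorts and climbing trials.

Every generator is a pure function of (spec, seed) and writes its ground
truth into the output, so downstream estimators can be checked against the
parameters that produced the data.

The CO2 trace generator inverts the exact conversion chain of
:mod:`flymet.respirometry`: a per-sample metabolic power ``smr_uW +
activity_coupling_uW * rate`` (``rate`` = the activity analog's absolute
first difference per minute) is converted back to a ppm excess and laid on
top of a linearly drifting baseline.  Because the respirometry module
attributes activity diffs to 5-minute windows by partitioning the cumulative
ADS channel, window-mean power satisfies ``smr + coupling * activity_index``
exactly, and noise-free round trips recover the generating parameters to
machine precision.

Activity is a two-state (rest/active) telegraph process: bout onsets occur
at ``bout_rate_per_min`` while resting, bouts last ``bout_mean_s`` on
average (geometric durations at 1 Hz), and accelerometer-like jitter is
present only while active.

Death times follow a Gompertz law with hazard h(t) = a * exp(b t), sampled
by inverting S(t) = exp(-(a/b) (e^{bt} - 1)); b = 0 degenerates to an
exponential with rate a.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .respirometry import RespTrace, uw_per_ul_h

__all__ = [
    "RespSynthSpec",
    "CohortSynthSpec",
    "gen_resp_trace",
    "gen_cohort",
    "gen_climbing_trials",
    "gompertz_survival",
]


@dataclass
class RespSynthSpec:
    """Parameters of one synthetic single-fly recording (1 Hz).

    ``smr_uW`` is the fly's true resting power and ``activity_coupling_uW``
    the true slope of power over the activity index; both are recoverable by
    the respirometry pipeline.  Durations are seconds; the fly segment is
    ``duration_s - baseline_pre_s - baseline_post_s``.
    """

    duration_s: int = 1800
    baseline_pre_s: int = 120
    baseline_post_s: int = 120
    baseline_level_ppm: float = 2.0
    drift_ppm_per_s: float = 0.001
    smr_uW: float = 15.0
    activity_coupling_uW: float = 0.0
    bout_rate_per_min: float = 0.5
    bout_mean_s: float = 30.0
    activity_amp: float = 1.0
    noise_sd_ppm: float = 0.05
    mass_mg: float = 1.2
    flow_ml_min: float = 50.0
    temp_c: float = 25.0
    fly_id: str = "sim"
    genotype: str = "control"
    age_class: str = "young"
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= self.baseline_pre_s + self.baseline_post_s:
            raise ValueError(
                f"duration_s={self.duration_s} must exceed the baseline windows "
                f"({self.baseline_pre_s} + {self.baseline_post_s} s): no fly segment left"
            )
        if min(self.baseline_pre_s, self.baseline_post_s) < 1:
            raise ValueError("baseline windows must be at least 1 s")
        if self.smr_uW <= 0 or self.mass_mg <= 0 or self.flow_ml_min <= 0:
            raise ValueError("smr_uW, mass_mg and flow_ml_min must be > 0")
        if self.activity_amp <= 0 or self.bout_mean_s <= 0:
            raise ValueError("activity_amp and bout_mean_s must be > 0")
        if min(self.activity_coupling_uW, self.bout_rate_per_min,
               self.noise_sd_ppm, self.baseline_level_ppm) < 0:
            raise ValueError("rates, amplitudes and noise must be non-negative")


def _telegraph(rng: np.random.Generator, n: int, p_on: float, p_off: float) -> np.ndarray:
    """Rest/active state sequence with geometric sojourn times."""
    state = np.zeros(n, dtype=bool)
    if p_on <= 0:
        return state
    i, active = 0, False
    while i < n:
        d = int(rng.geometric(p_off if active else p_on))
        if active:
            state[i:i + d] = True
        i += d
        active = not active
    return state


def gen_resp_trace(spec: RespSynthSpec) -> RespTrace:
    """Generate one synthetic recording; ground truth lands in ``trace.meta``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.duration_s
    pre = (0, spec.baseline_pre_s)
    post = (n - spec.baseline_post_s, n)
    fly_len = post[0] - pre[1]

    state = _telegraph(rng, fly_len, min(1.0, spec.bout_rate_per_min / 60.0),
                       min(1.0, 1.0 / spec.bout_mean_s))
    jitter = rng.uniform(0.5, 1.5, size=fly_len)
    activity_fly = np.where(state, spec.activity_amp * jitter, 0.0)

    # per-sample activity rate, matching the pipeline's ADS partitioning
    rate = np.abs(np.diff(activity_fly, prepend=activity_fly[:1])) * 60.0
    power = spec.smr_uW + spec.activity_coupling_uW * rate
    ppm_excess = power / (spec.flow_ml_min * 0.06 * uw_per_ul_h(1.0))

    t = np.arange(n, dtype=float)
    co2 = spec.baseline_level_ppm + spec.drift_ppm_per_s * t
    co2[pre[1]:post[0]] += ppm_excess
    if spec.noise_sd_ppm > 0:
        co2 += rng.normal(0.0, spec.noise_sd_ppm, size=n)

    activity = np.zeros(n)
    activity[pre[1]:post[0]] = activity_fly

    return RespTrace(
        time_s=t,
        co2_ppm=co2,
        activity=activity,
        temp_c=np.full(n, spec.temp_c),
        flow_ml_min=spec.flow_ml_min,
        baseline_pre=pre,
        baseline_post=post,
        fly_id=spec.fly_id,
        genotype=spec.genotype,
        age_class=spec.age_class,
        live_mass_mg=spec.mass_mg,
        meta={"ground_truth": asdict(spec)},
    )


def gompertz_survival(t, a: float, b: float):
    """Closed-form S(t) for the Gompertz hazard h(t) = a e^{bt}."""
    t = np.asarray(t, dtype=float)
    if b == 0:
        return np.exp(-a * t)
    return np.exp(-(a / b) * np.expm1(b * t))


@dataclass
class CohortSynthSpec:
    """Synthetic survival cohort: per-genotype Gompertz parameters.

    ``groups`` maps genotype label to (a, b): baseline hazard a (> 0, per
    time unit) and hazard acceleration b (>= 0).  Censoring is administrative
    (optional fixed ``study_end``) plus independent random loss with
    probability ``censor_prob`` at a uniform time before death.
    """

    groups: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"control": (1.3e-3, 0.1)}
    )
    n_per_group: int = 100
    censor_prob: float = 0.0
    condition: str = "standard"
    time_unit: str = "days"
    study_end: Optional[float] = None
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("at least one genotype group required")
        for g, (a, b) in self.groups.items():
            if a <= 0:
                raise ValueError(f"group {g!r}: baseline hazard a must be > 0")
            if b < 0:
                raise ValueError(f"group {g!r}: hazard acceleration b must be >= 0")
        if not 0 <= self.censor_prob <= 1:
            raise ValueError("censor_prob must be in [0, 1]")
        if self.time_unit not in ("days", "hours"):
            raise ValueError("time_unit must be 'days' or 'hours'")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")


def gen_cohort(spec: CohortSynthSpec) -> pd.DataFrame:
    """Draw a survival event table by inverse-CDF Gompertz sampling.

    Returns a tidy frame (fly_id, genotype, condition, time, event,
    time_unit) with event = 1 for death and 0 for right censoring.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    frames = []
    for genotype, (a, b) in spec.groups.items():
        u = rng.uniform(size=spec.n_per_group)
        if b == 0:
            t = -np.log(u) / a
        else:
            t = np.log1p(-(b / a) * np.log(u)) / b
        event = np.ones(spec.n_per_group, dtype=int)
        if spec.censor_prob > 0:
            lost = rng.uniform(size=spec.n_per_group) < spec.censor_prob
            t = np.where(lost, rng.uniform(size=spec.n_per_group) * t, t)
            event[lost] = 0
        if spec.study_end is not None:
            over = t > spec.study_end
            t = np.where(over, spec.study_end, t)
            event[over] = 0
        frames.append(pd.DataFrame({
            "fly_id": [f"{genotype}_{i:04d}" for i in range(spec.n_per_group)],
            "genotype": genotype,
            "condition": spec.condition,
            "time": t,
            "event": event,
            "time_unit": spec.time_unit,
        }))
    return pd.concat(frames, ignore_index=True)


def gen_climbing_trials(n_flies: int, true_mean: float, sd: float,
                        seed: int = 0) -> pd.DataFrame:
    """Five negative-geotaxis trials of normalized fly heights in [0, 1].

    Heights are Gaussian around ``true_mean`` with spread ``sd``, clipped to
    the vial; columns: trial (1..5), fly, height.
    """
    if not 0 <= true_mean <= 1:
        raise ValueError("true_mean must be in [0, 1]")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if n_flies < 1:
        raise ValueError("n_flies must be >= 1")
    rng = np.random.default_rng(seed)
    heights = np.clip(rng.normal(true_mean, sd, size=(5, n_flies)), 0.0, 1.0)
    trial, fly = np.meshgrid(np.arange(1, 6), np.arange(n_flies), indexing="ij")
    return pd.DataFrame({
        "trial": trial.ravel(),
        "fly": fly.ravel(),
        "height": heights.ravel(),
    })
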