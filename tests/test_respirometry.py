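"""Unit and property tests for the respirometry conversion chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from flymet import (
    RespSynthSpec,
    RespTrace,
    activity_index,
    baseline_correct,
    compute_ads,
    flux_to_power,
    gen_resp_trace,
    homeostasis_regression,
    mass_correct,
    ppm_to_flux,
    segment_metrics,
    standard_metabolic_rate,
)


def make_trace(co2, activity=None, n=None, pre=(0, 100), post=None, **kw):
    n = n if n is not None else len(np.atleast_1d(co2))
    co2 = np.broadcast_to(np.asarray(co2, float), (n,))
    activity = np.zeros(n) if activity is None else np.asarray(activity, float)
    post = post or (n - 100, n)
    return RespTrace(
        time_s=np.arange(n, dtype=float),
        co2_ppm=co2,
        activity=activity,
        temp_c=np.full(n, 25.0),
        flow_ml_min=50.0,
        baseline_pre=pre,
        baseline_post=post,
        **kw,
    )


class TestConversionChain:
    @pytest.mark.parametrize(
        "ppm, flow, expected",
        [(1.0, 50.0, 3.0), (0.0, 50.0, 0.0), (10.0, 50.0, 30.0)],
    )
    def test_ppm_to_flux(self, ppm, flow, expected):
        assert ppm_to_flux(ppm, flow) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "flux, expected",
        [(3.0, 17.637), (0.0, 0.0), (1.0, 5.879)],
    )
    def test_flux_to_power_oxyjoule(self, flux, expected):
        # 21.164 J/mL O2 at RQ=1, VO2 = VCO2
        assert flux_to_power(flux) == pytest.approx(expected, abs=5e-4)

    def test_negative_flux_rejected(self):
        with pytest.raises(ValueError):
            flux_to_power(-1.0)

    @pytest.mark.parametrize(
        "power, mass, exponent, expected",
        [(10.0, 1.0, 0.856, 10.0), (10.0, 2.0, 0.856, 10.0 / 2**0.856), (7.0, 3.0, 0.0, 7.0)],
    )
    def test_mass_correct(self, power, mass, exponent, expected):
        assert mass_correct(power, mass, exponent) == pytest.approx(expected, rel=1e-12)

    def test_mass_correct_two_mg_value(self):
        assert mass_correct(10.0, 2.0) == pytest.approx(5.525, abs=5e-4)

    def test_mass_must_be_positive(self):
        with pytest.raises(ValueError):
            mass_correct(1.0, 0.0)

    @given(st.floats(0.01, 100), st.floats(1e-3, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_chain_is_linear(self, ppm, scale):
        base = flux_to_power(ppm_to_flux(ppm, 50.0))
        scaled = flux_to_power(ppm_to_flux(ppm * scale, 50.0))
        assert scaled == pytest.approx(base * scale, rel=1e-9)


class TestActivityIndex:
    def test_ads_hand_example(self):
        ads = compute_ads([0.0, 1.0, 1.0, 3.0])
        assert ads.tolist() == [0.0, 1.0, 1.0, 3.0]
        assert ads[-1] - ads[0] == 3.0

    def test_ads_constant_is_zero(self):
        assert compute_ads(np.full(50, 3.7)).max() == 0.0

    def test_ads_too_short(self):
        with pytest.raises(ValueError):
            compute_ads([1.0])

    def test_index_hand_example(self):
        ads = np.linspace(0.0, 3.0, 300)
        assert activity_index(ads, 300) == pytest.approx(3.0 / 300 * 60, rel=1e-12)

    def test_index_length_mismatch(self):
        with pytest.raises(ValueError):
            activity_index(np.zeros(10), 11)

    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=200),
           st.floats(-100, 100))
    @settings(max_examples=50, deadline=None)
    def test_ads_nondecreasing_and_offset_invariant(self, series, offset):
        a = np.asarray(series)
        ads = compute_ads(a)
        assert np.all(np.diff(ads) >= 0)
        shifted = compute_ads(a + offset)
        np.testing.assert_allclose(shifted, ads, atol=1e-6)

    def test_index_scales_with_amplitude(self):
        a = np.sin(np.linspace(0, 20, 300))
        one = activity_index(compute_ads(a), 300)
        two = activity_index(compute_ads(2 * a), 300)
        assert two == pytest.approx(2 * one, rel=1e-12)


class TestBaselineCorrection:
    def test_linear_raw_corrects_to_zero(self):
        n = 600
        t = np.arange(n, dtype=float)
        trace = make_trace(400.0 + 0.01 * t, n=n)
        corrected = baseline_correct(trace)
        np.testing.assert_allclose(corrected.co2_excess_ppm, 0.0, atol=1e-9)

    def test_interpolated_line_value(self):
        # pre mean 400 centered at t=50, post mean 410 centered at t=1750
        n = 1801
        co2 = np.zeros(n)
        co2[0:101] = 400.0
        co2[1700:1801] = 410.0
        trace = make_trace(co2, n=n, pre=(0, 101), post=(1700, 1801))
        c = baseline_correct(trace)
        line_at_900 = c.drift_intercept + c.drift_slope * 900.0
        assert line_at_900 == pytest.approx(405.0, abs=1e-9)

    def test_recovers_generator_drift(self, noise_free_spec):
        trace = gen_resp_trace(noise_free_spec)
        c = baseline_correct(trace)
        assert c.drift_slope == pytest.approx(noise_free_spec.drift_ppm_per_s, rel=1e-9)

    def test_baseline_window_means_zero_after_correction(self, noise_free_trace):
        c = baseline_correct(noise_free_trace)
        # re-apply on a trace with the drift line removed everywhere
        t = noise_free_trace.time_s
        line = c.drift_intercept + c.drift_slope * t
        flattened = RespTrace(
            time_s=t, co2_ppm=noise_free_trace.co2_ppm - line,
            activity=noise_free_trace.activity, temp_c=noise_free_trace.temp_c,
            flow_ml_min=noise_free_trace.flow_ml_min,
            baseline_pre=noise_free_trace.baseline_pre,
            baseline_post=noise_free_trace.baseline_post,
            live_mass_mg=noise_free_trace.live_mass_mg,
        )
        for win in (flattened.baseline_pre, flattened.baseline_post):
            assert abs(flattened.co2_ppm[slice(*win)].mean()) < 1e-9

    def test_idempotent(self, noise_free_trace):
        first = baseline_correct(noise_free_trace)
        t = noise_free_trace.time_s
        line = first.drift_intercept + first.drift_slope * t
        again = baseline_correct(RespTrace(
            time_s=t, co2_ppm=noise_free_trace.co2_ppm - line,
            activity=noise_free_trace.activity, temp_c=noise_free_trace.temp_c,
            flow_ml_min=noise_free_trace.flow_ml_min,
            baseline_pre=noise_free_trace.baseline_pre,
            baseline_post=noise_free_trace.baseline_post,
            live_mass_mg=noise_free_trace.live_mass_mg,
        ))
        assert abs(again.drift_slope) < 1e-12
        np.testing.assert_allclose(again.co2_excess_ppm, first.co2_excess_ppm, atol=1e-9)

    def test_nonfinite_ppm_reports_index(self):
        co2 = np.full(600, 400.0)
        co2[123] = np.nan
        trace = make_trace(co2)
        with pytest.raises(ValueError, match="123"):
            baseline_correct(trace)


class TestSegments:
    def test_segment_count(self):
        # 1500-s fly segment tiles into exactly 5 windows
        spec = RespSynthSpec(duration_s=1740, baseline_pre_s=120,
                             baseline_post_s=120, noise_sd_ppm=0.0, seed=1)
        seg = segment_metrics(gen_resp_trace(spec))
        assert len(seg) == 5

    def test_short_segment_warns_and_empty(self):
        spec = RespSynthSpec(duration_s=539, baseline_pre_s=120,
                             baseline_post_s=120, noise_sd_ppm=0.0, seed=1)
        with pytest.warns(UserWarning):
            seg = segment_metrics(gen_resp_trace(spec))
        assert seg.empty

    def test_zero_coupling_segments_equal_smr(self):
        spec = RespSynthSpec(duration_s=2040, noise_sd_ppm=0.0,
                             activity_coupling_uW=0.0, smr_uW=12.0,
                             mass_mg=1.5, seed=2)
        seg = segment_metrics(gen_resp_trace(spec))
        expected = 12.0 / 1.5**0.856
        np.testing.assert_allclose(seg["mean_mr"], expected, rtol=1e-6)

    def test_mass_correction_commutes_with_averaging(self, noise_free_spec):
        from dataclasses import replace
        heavy = replace(noise_free_spec, mass_mg=2.0)
        seg_light = segment_metrics(gen_resp_trace(noise_free_spec))
        seg_heavy = segment_metrics(gen_resp_trace(heavy))
        # same seed, same ppm excess per unit power; scaling power back by
        # mass^0.856 must recover identical mass-corrected means
        np.testing.assert_allclose(
            seg_heavy["mean_mr"] * 2.0**0.856, seg_light["mean_mr"], rtol=1e-9)


class TestSMR:
    def test_constant_trace(self):
        trace = make_trace(400.0, n=900)  # flat: excess 0 everywhere
        est = standard_metabolic_rate(trace)
        assert est.smr == pytest.approx(0.0, abs=1e-9)

    def test_recovers_ground_truth(self):
        # sparse bouts (mean rest ~10 min) guarantee a fully quiescent
        # 300-s window, where mean MR equals the resting power exactly
        spec = RespSynthSpec(duration_s=2040, noise_sd_ppm=0.0,
                             smr_uW=17.637, mass_mg=1.0, activity_coupling_uW=0.5,
                             bout_rate_per_min=0.1, seed=5)
        est = standard_metabolic_rate(gen_resp_trace(spec))
        assert est.smr == pytest.approx(17.637, rel=1e-6)
        assert not est.used_fallback

    def test_smr_below_mean(self, noise_free_trace):
        est = standard_metabolic_rate(noise_free_trace)
        seg = segment_metrics(noise_free_trace)
        assert est.smr <= seg["mean_mr"].mean() + 1e-12


class TestHomeostasisRegression:
    def test_perfect_fit(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        seg = pd.DataFrame({"activity_index": x, "mean_mr": 2 * x + 1})
        res = homeostasis_regression(seg, "g")
        assert res.slope == pytest.approx(2.0, rel=1e-9)
        assert res.intercept == pytest.approx(1.0, rel=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)
        assert res.verdict == "lost"          # perfectly positive slope
        assert res.ci_low <= res.slope <= res.ci_high

    def test_too_few_points(self):
        seg = pd.DataFrame({"activity_index": [1.0, 2.0], "mean_mr": [1.0, 2.0]})
        with pytest.raises(ValueError):
            homeostasis_regression(seg, "g")

    def test_degenerate_regressor(self):
        seg = pd.DataFrame({"activity_index": np.ones(5), "mean_mr": np.arange(5.0)})
        with pytest.raises(ValueError, match="degenerate"):
            homeostasis_regression(seg, "g")

    def test_ci_coverage(self):
        """95% CI covers the true slope in >= 93% of 1000 noisy replicates."""
        rng = np.random.default_rng(99)
        true_slope = 0.5
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            x = rng.uniform(0, 10, 30)
            y = 17.0 + true_slope * x + rng.normal(0, 0.5, 30)
            res = homeostasis_regression(
                pd.DataFrame({"activity_index": x, "mean_mr": y}), "g")
            hits += res.ci_low <= true_slope <= res.ci_high
        assert hits / n_rep >= 0.93
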