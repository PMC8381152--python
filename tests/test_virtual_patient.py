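"""Pulse sampling, cortisol cascade discretization and envelope extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enerloop.virtual_patient import (
    CohortSpec,
    CortisolParams,
    FlatAmplitudeLaw,
    HarmonicAmplitudeLaw,
    PulseTrain,
    derive_binary_events,
    extract_envelopes,
    sample_pulse_train,
    simulate_cortisol,
)


class TestPulseTrainSampling:
    def test_cushing_gap_moments_match_published_range(self, presets):
        """~10^5 sampled gaps reproduce the 59 +/- 11 min inter-arrival law."""
        pt = sample_pulse_train(presets["cushing_no_circadian"], 1440 * 4200, seed=3)
        gaps = np.diff(pt.times).astype(float)
        assert gaps.size > 1e5
        se_mean = gaps.std() / np.sqrt(gaps.size)
        assert abs(gaps.mean() - 59.0) < 3 * se_mean + 0.5  # +0.5 grid rounding
        assert abs(gaps.std() - 11.0) < 0.5

    def test_healthy_amplitude_cv_is_ten_percent(self, presets):
        """sd(H_k)/mu_k ~ 0.1 for the healthy harmonic amplitude law."""
        cohort = presets["healthy"]
        pt = sample_pulse_train(cohort, 1440 * 800, seed=4)
        mu = np.maximum(cohort.amplitude_law.mean_at(pt.times), 0.1)
        ratio = pt.amplitudes / mu
        assert len(pt) > 1e4
        assert ratio.std() == pytest.approx(0.1, rel=0.05)

    def test_zero_variance_amplitudes_are_exactly_the_mean(self):
        cohort = CohortSpec(
            name="degenerate",
            gap_mean_min=60.0,
            gap_sd_min=10.0,
            amplitude_law=FlatAmplitudeLaw(mean=5.0, sd=1e-12),
        )
        pt = sample_pulse_train(cohort, 1440 * 5, seed=0)
        np.testing.assert_allclose(pt.amplitudes, 5.0, rtol=1e-6)

    def test_same_seed_reproduces_bit_identical_train(self, presets):
        a = sample_pulse_train(presets["healthy"], 1440 * 3, seed=9)
        b = sample_pulse_train(presets["healthy"], 1440 * 3, seed=9)
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.amplitudes, b.amplitudes)

    def test_invalid_arguments_rejected(self, presets):
        with pytest.raises(ValueError):
            sample_pulse_train(presets["healthy"], 100, seed=0)
        with pytest.raises(ValueError):
            CohortSpec(
                name="bad",
                gap_mean_min=-1.0,
                gap_sd_min=1.0,
                amplitude_law=FlatAmplitudeLaw(mean=1.0, sd=1.0),
            )


class TestCohortPresets:
    def test_harmonics_average_out_to_baseline(self, presets):
        """Over a full period the circadian terms integrate to zero."""
        k = np.arange(1440)
        for name, baseline in (("healthy", 6.1), ("cushing_circadian", 38.5)):
            law = presets[name].amplitude_law
            assert np.mean(law.mean_at(k)) == pytest.approx(baseline, abs=1e-9)

    def test_flat_cohort_has_no_time_dependence(self, presets):
        law = presets["cushing_no_circadian"].amplitude_law
        assert law.mean_at(0) == law.mean_at(720) == 38.0
        assert law.sd_at(0) == 2.5

    def test_all_presets_satisfy_invariants(self, presets):
        for spec in presets.values():
            assert spec.gamma_shape > 0 and spec.gamma_scale > 0


class TestCortisolSimulation:
    def test_no_pulses_means_no_cortisol(self):
        pulses = PulseTrain(times=np.array([], dtype=int), amplitudes=np.array([]))
        pr = simulate_cortisol(
            pulses, CortisolParams(sigma_psi2=0.0), days=1, seed=0
        )
        np.testing.assert_array_equal(pr.cort2, 0.0)

    def test_single_pulse_matches_biexponential_closed_form(self):
        """The discretized cascade equals the analytic impulse response."""
        z1, z2, h, t0 = 0.12, 0.035, 3.0, 200
        pulses = PulseTrain(times=np.array([t0]), amplitudes=np.array([h]))
        pr = simulate_cortisol(
            pulses, CortisolParams(zeta1=z1, zeta2=z2, sigma_psi2=0.0), 1, seed=0
        )
        t = np.arange(1440)
        dt = t - t0
        expected = np.where(
            dt >= 0, h * z1 / (z1 - z2) * (np.exp(-z2 * dt) - np.exp(-z1 * dt)), 0.0
        )
        np.testing.assert_allclose(pr.cort2, expected, rtol=1e-8, atol=1e-12)
        peak_expected = t0 + round(np.log(z1 / z2) / (z1 - z2))
        assert abs(int(np.argmax(pr.cort2)) - peak_expected) <= 1

    def test_superposition_of_pulses(self):
        params = CortisolParams(sigma_psi2=0.0)
        a = PulseTrain(times=np.array([100]), amplitudes=np.array([2.0]))
        b = PulseTrain(times=np.array([500]), amplitudes=np.array([1.5]))
        ab = PulseTrain(times=np.array([100, 500]), amplitudes=np.array([2.0, 1.5]))
        ya = simulate_cortisol(a, params, 1, seed=0).cort2
        yb = simulate_cortisol(b, params, 1, seed=0).cort2
        yab = simulate_cortisol(ab, params, 1, seed=0).cort2
        np.testing.assert_allclose(yab, ya + yb, rtol=0, atol=1e-12)

    def test_pulse_beyond_horizon_rejected(self):
        pulses = PulseTrain(times=np.array([2000]), amplitudes=np.array([1.0]))
        with pytest.raises(ValueError):
            simulate_cortisol(pulses, CortisolParams(), days=1, seed=0)

    def test_same_seed_is_bit_identical(self, presets):
        pt = sample_pulse_train(presets["healthy"], 1440, seed=5)
        p1 = simulate_cortisol(pt, CortisolParams(), 1, seed=6)
        p2 = simulate_cortisol(pt, CortisolParams(), 1, seed=6)
        np.testing.assert_array_equal(p1.y, p2.y)


class TestEnvelopes:
    def test_constant_series_collapses_to_itself(self):
        y = np.full(500, 3.7)
        r, s = extract_envelopes(y)
        np.testing.assert_array_equal(r, y)
        np.testing.assert_array_equal(s, y)

    def test_triangle_wave_envelopes_hit_extreme_levels(self):
        """Away from the edges, R sits at the crest and S at the trough."""
        t = np.arange(4000)
        y = 5.0 + 2.0 * np.abs(((t / 120.0) % 2) - 1)  # period 240, range [5, 7]
        r, s = extract_envelopes(y, window=60)
        interior = slice(300, 3700)
        np.testing.assert_allclose(r[interior], 7.0, atol=0.05)
        np.testing.assert_allclose(s[interior], 5.0, atol=0.05)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_upper_envelope_dominates_lower_for_random_series(self, seed):
        y = np.random.default_rng(seed).normal(size=700).cumsum()
        r, s = extract_envelopes(y)
        assert np.all(r >= s)

    def test_envelopes_bracket_the_signal_at_extrema_knots(self, healthy_profile):
        _, profile = healthy_profile
        # at every interior local extremum used as a knot the envelopes bracket y
        assert np.all(profile.R >= profile.S)
        mid = profile.y[(profile.y <= profile.R) & (profile.y >= profile.S)]
        assert mid.size > 0.5 * len(profile)  # most of the signal lies inside


class TestBinaryEvents:
    def test_events_mark_exact_pulse_minutes(self):
        pulses = PulseTrain(times=np.array([100, 500]), amplitudes=np.array([1.0, 2.0]))
        c = derive_binary_events(pulses, 1000)
        assert set(np.flatnonzero(c)) == {100, 500}

    def test_event_count_conserved_without_corruption(self, presets):
        pt = sample_pulse_train(presets["healthy"], 1440 * 2, seed=1)
        c = derive_binary_events(pt, 1440 * 2)
        assert c.sum() == len(pt)

    def test_miss_rate_drops_events(self, presets):
        pt = sample_pulse_train(presets["cushing_no_circadian"], 1440 * 30, seed=1)
        c = derive_binary_events(pt, 1440 * 30, miss_rate=0.5, seed=2)
        assert 0 < c.sum() < len(pt)

    def test_no_pulses_gives_all_zeros(self):
        empty = PulseTrain(times=np.array([], dtype=int), amplitudes=np.array([]))
        assert derive_binary_events(empty, 100).sum() == 0
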