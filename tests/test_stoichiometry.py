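"""Trace filtering, step detection, single-dye calibration, stoichiometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import ck_filter_naive
from tirfquant import (
    PipelineConfig,
    Track,
    characteristic_intensity,
    chung_kennedy_filter,
    detect_steps,
    estimate_stoichiometry,
    photobleach_corrected_initial_intensity,
    simulate_trace,
)
from tirfquant.detection import Focus


def track_from_trace(values, start_frame=0, track_id=0):
    foci = [
        Focus(frame_index=start_frame + i, x=10.0, y=10.0, intensity=float(v),
              background=0.0, snr=1.0, roi_halfwidth=8)
        for i, v in enumerate(values)
    ]
    return Track(track_id=track_id, foci=foci)


class TestChungKennedyFilter:
    def test_constant_trace_passes_through(self):
        x = np.full(30, 42.0)
        np.testing.assert_allclose(chung_kennedy_filter(x), x, atol=1e-12)

    def test_noiseless_step_preserved_exactly(self):
        x = np.concatenate([np.full(50, 100.0), np.zeros(50)])
        y = chung_kennedy_filter(x)
        np.testing.assert_allclose(y, x, atol=1e-6)

    def test_matches_naive_formula_on_random_traces(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.normal(50, 10, size=rng.integers(10, 40))
            np.testing.assert_allclose(
                chung_kennedy_filter(x), ck_filter_naive(x), atol=1e-9
            )

    def test_noisy_step_variance_reduced_edge_preserved(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([np.full(60, 100.0), np.zeros(60)])
        noisy = x + rng.normal(0, 10, x.size)
        y = chung_kennedy_filter(noisy)
        assert y[:55].var() < noisy[:55].var()
        assert y[65:].var() < noisy[65:].var()
        # step midpoint: first crossing of the 50-count level stays near 60
        crossing = int(np.argmax(y < 50.0))
        assert abs(crossing - 60) <= 2

    def test_empty_trace_raises(self):
        with pytest.raises(ValueError):
            chung_kennedy_filter(np.array([]))


class TestDetectSteps:
    def test_single_noiseless_step(self):
        x = np.concatenate([np.full(50, 100.0), np.zeros(50)])
        steps = detect_steps(x)
        assert len(steps) == 1
        assert steps[0].frame == 50
        assert abs(steps[0].size - 100.0) < 1e-9

    def test_double_noiseless_staircase(self):
        x = np.concatenate([np.full(30, 200.0), np.full(30, 100.0), np.zeros(30)])
        steps = detect_steps(x)
        assert [s.frame for s in steps] == [30, 60]
        assert all(abs(s.size - 100.0) < 1e-9 for s in steps)

    def test_flat_trace_has_no_steps(self):
        assert detect_steps(np.full(40, 10.0)) == []

    def test_noisy_step_recovered_within_two_frames(self):
        """Step five times the noise sigma is found within +/-2 frames."""
        hits = 0
        n_trials = 200
        for seed in range(n_trials):
            rng = np.random.default_rng(seed)
            x = np.concatenate([np.full(40, 50.0), np.zeros(40)])
            noisy = x + rng.normal(0, 10.0, x.size)
            steps = detect_steps(chung_kennedy_filter(noisy))
            if steps and min(abs(s.frame - 40) for s in steps) <= 2:
                hits += 1
        assert hits >= 0.95 * n_trials


class TestCharacteristicIntensity:
    def test_identical_values(self):
        assert characteristic_intensity(np.full(20, 10.0)) == 10.0

    def test_gaussian_sample_mode_near_mean(self):
        rng = np.random.default_rng(15)
        sample = rng.normal(10.0, 1.0, 500)
        assert 9.5 < characteristic_intensity(sample) < 10.5

    def test_dominant_mode_of_bimodal_sample(self):
        rng = np.random.default_rng(16)
        sample = np.concatenate(
            [rng.normal(10.0, 0.5, 400), rng.normal(20.0, 0.5, 100)]
        )
        i_single = characteristic_intensity(sample)
        assert abs(i_single - 10.0) < 1.0  # the mode, not the mixture mean 12

    def test_empty_sample_raises_with_calibration_hint(self):
        with pytest.raises(ValueError, match="simulate_trace"):
            characteristic_intensity(np.array([]))


class TestStoichiometry:
    def test_collinear_points_give_exact_intercept(self, pipeline_config):
        track = track_from_trace([100.0, 90.0, 80.0, 70.0, 60.0])
        est = estimate_stoichiometry(track, 10.0, pipeline_config)
        assert est.initial_intensity == pytest.approx(100.0, abs=1e-9)
        assert est.stoichiometry == pytest.approx(10.0, abs=1e-9)

    def test_constant_trace_equal_to_single_dye(self, pipeline_config):
        track = track_from_trace([10.0] * 8)
        est = estimate_stoichiometry(track, 10.0, pipeline_config)
        assert est.stoichiometry == pytest.approx(1.0)

    def test_exponential_decay_intercept_within_two_percent(self):
        """OLS on {200, 180, 162, 145.8} vs the hand-computed closed form."""
        y = np.array([200.0, 180.0, 162.0, 145.8])
        # closed-form OLS: slope = S_xy / S_xx with x = 0..3
        xbar, ybar = 1.5, y.mean()
        slope = ((np.arange(4) - xbar) * (y - ybar)).sum() / 5.0
        intercept = ybar - slope * xbar
        got = photobleach_corrected_initial_intensity(y)
        assert got == pytest.approx(intercept, abs=1e-12)
        assert abs(got - 200.0) / 200.0 < 0.02

    def test_late_starting_track_excluded(self, pipeline_config):
        track = track_from_trace([100.0] * 6, start_frame=10)
        assert estimate_stoichiometry(track, 10.0, pipeline_config) is None
        track9 = track_from_trace([100.0] * 6, start_frame=9)
        assert estimate_stoichiometry(track9, 10.0, pipeline_config) is not None

    def test_short_track_excluded(self, pipeline_config):
        track = track_from_trace([100.0] * 3)
        assert estimate_stoichiometry(track, 10.0, pipeline_config) is None

    def test_nonpositive_i_single_raises(self, pipeline_config):
        track = track_from_trace([100.0] * 6)
        with pytest.raises(ValueError):
            estimate_stoichiometry(track, 0.0, pipeline_config)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(scale=st.floats(min_value=0.1, max_value=1e4))
    def test_scale_invariance(self, scale):
        """Multiplying trace and I_single by one constant leaves S unchanged."""
        cfg = PipelineConfig()
        base = [120.0, 100.0, 85.0, 70.0, 60.0]
        est1 = estimate_stoichiometry(track_from_trace(base), 10.0, cfg)
        est2 = estimate_stoichiometry(
            track_from_trace([v * scale for v in base]), 10.0 * scale, cfg
        )
        assert est2.stoichiometry == pytest.approx(est1.stoichiometry, rel=1e-9)


def test_simulated_trace_steps_recovered_end_to_end():
    """Forced two-step staircase detected at the true bleach frames."""
    tr = simulate_trace(2, 300.0, 0.0, 15.0, 60, seed=5,
                        forced_bleach_frames={20: 1, 40: 1})
    steps = detect_steps(chung_kennedy_filter(tr.values))
    frames = [s.frame for s in steps]
    assert len(frames) == 2
    assert abs(frames[0] - 20) <= 2 and abs(frames[1] - 40) <= 2
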