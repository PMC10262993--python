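"""Pupil preprocessing: eye selection, blinks, screening, smoothing, metrics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from voicecue.pupil import (
    EyeTrace,
    PreprocConfig,
    PupilTrace,
    baseline_correct,
    blink_fraction,
    compute_metrics,
    condition_average,
    detect_blinks,
    downsample,
    interpolate_blinks,
    preprocess_trial,
    screen_trial,
    select_eye,
    smooth,
)

CFG = PreprocConfig()
RATE = 120.0
N = 1141  # [-3.0, 6.5] s at 120 Hz
T = (np.arange(N) - 360) / RATE
WIN = (T >= -1.0) & (T <= 6.5)


def eye_trace(d, gx=None, gy=None):
    gx = np.full(N, 960.0) if gx is None else gx
    gy = np.full(N, 540.0) if gy is None else gy
    return EyeTrace(T, d, gx, gy, RATE)


def two_eye(d_left, d_right):
    g = np.full(N, 960.0)
    h = np.full(N, 540.0)
    return PupilTrace(T, d_left, d_right, g, h, g.copy(), h.copy(), RATE)


class TestSelectEye:
    def test_more_valid_samples_wins(self):
        left = np.full(N, 3.0)
        right = np.full(N, 3.0)
        right[:100] = 0.0
        assert select_eye([two_eye(left, right)]) == "left"
        assert select_eye([two_eye(right, left)]) == "right"

    def test_tie_goes_left(self):
        d = np.full(N, 3.0)
        assert select_eye([two_eye(d, d.copy())]) == "left"

    def test_counts_pool_across_trials(self):
        a_left, a_right = np.full(N, 3.0), np.full(N, 3.0)
        a_left[:300] = 0.0  # left worse on trial 1
        b_left, b_right = np.full(N, 3.0), np.full(N, 3.0)
        b_right[:500] = 0.0  # right much worse on trial 2
        assert select_eye([two_eye(a_left, a_right), two_eye(b_left, b_right)]) == "left"

    def test_no_valid_eye_raises(self):
        z = np.zeros(N)
        with pytest.raises(ValueError):
            select_eye([two_eye(z, z.copy())])


class TestDetectBlinks:
    def test_clean_trace_has_no_blinks(self):
        assert detect_blinks(eye_trace(np.full(N, 3.0))) == []

    def test_single_run_boundaries(self):
        d = np.full(N, 3.0)
        d[500:512] = 0.0
        assert detect_blinks(eye_trace(d)) == [(500, 511)]

    def test_separate_runs_stay_distinct(self):
        d = np.full(N, 3.0)
        d[500:505] = 0.0
        d[506:510] = 0.0  # one valid sample between
        assert detect_blinks(eye_trace(d)) == [(500, 504), (506, 509)]

    def test_zeros_outside_window_ignored(self):
        d = np.full(N, 3.0)
        d[0:100] = 0.0  # entirely before -1 s
        assert detect_blinks(eye_trace(d)) == []

    def test_run_straddling_window_edge_is_kept(self):
        d = np.full(N, 3.0)
        d[230:250] = 0.0  # crosses t = -1 s (sample 240)
        assert detect_blinks(eye_trace(d)) == [(230, 249)]


class TestScreening:
    def test_exactly_twenty_percent_blinks_excluded(self):
        d = np.full(N, 3.0)
        n_win = int(WIN.sum())
        k = int(np.ceil(0.20 * n_win))
        d[360:360 + k] = 0.0
        tr = eye_trace(d)
        assert blink_fraction(tr) >= 0.20
        disp = screen_trial(tr)
        assert not disp.kept and disp.reason == "blink_fraction"

    def test_just_below_threshold_kept(self):
        d = np.full(N, 3.0)
        k = int(0.19 * WIN.sum())
        d[360:360 + k] = 0.0
        assert screen_trial(eye_trace(d)).kept

    def test_offscreen_gaze_excluded(self):
        gx = np.full(N, 960.0)
        gx[700:705] = 2500.0
        disp = screen_trial(eye_trace(np.full(N, 3.0), gx=gx))
        assert not disp.kept and disp.reason == "offscreen_gaze"

    def test_blink_zero_gaze_does_not_count_as_saccade(self):
        """Gaze screening runs after interpolation, so the (0,0) gaze the
        tracker reports during a short blink must not trigger exclusion."""
        d = np.full(N, 3.0)
        gx = np.full(N, 960.0)
        gy = np.full(N, 540.0)
        d[600:615] = 0.0
        gx[600:615] = 0.0
        gy[600:615] = 0.0
        assert screen_trial(eye_trace(d, gx=gx, gy=gy)).kept

    def test_offscreen_before_window_ignored(self):
        gx = np.full(N, 960.0)
        gx[0:50] = -500.0  # before -1 s
        assert screen_trial(eye_trace(np.full(N, 3.0), gx=gx)).kept


class TestInterpolation:
    def test_linear_ramp_restored_exactly(self):
        ramp = 3.0 + 0.1 * T
        d = ramp.copy()
        d[520:540] = 0.0
        out = interpolate_blinks(eye_trace(d))
        np.testing.assert_allclose(out.d, ramp, atol=1e-12)

    def test_non_guard_samples_untouched(self):
        rng = np.random.default_rng(0)
        d = 3.0 + 0.1 * rng.standard_normal(N)
        clean = d.copy()
        d[500:510] = 0.0
        out = interpolate_blinks(eye_trace(d))
        lo, hi = 500 - CFG.interp_pre, 509 + CFG.interp_post
        np.testing.assert_array_equal(out.d[:lo], clean[:lo])
        np.testing.assert_array_equal(out.d[hi + 1:], clean[hi + 1:])

    def test_guard_band_samples_are_replaced(self):
        """Valid samples inside the 10-before/16-after guard bands lie on the
        interpolation line, not at their original values."""
        d = np.full(N, 3.0)
        d[505] = 5.0  # spike inside the pre-guard of the blink
        d[510:520] = 0.0
        out = interpolate_blinks(eye_trace(d))
        assert out.d[505] == pytest.approx(3.0)

    def test_blink_at_trace_start_fills_constant(self):
        # trace starting right at the window edge: no left anchor exists,
        # so the fill is constant from the right anchor
        n = 901
        t = np.arange(n) / RATE - 1.0
        d = np.full(n, 3.0)
        d[:30] = 0.0
        g = np.full(n, 960.0)
        out = interpolate_blinks(EyeTrace(t, d, g, g.copy(), RATE))
        np.testing.assert_allclose(out.d[:30], 3.0)

    def test_blink_before_window_left_untouched(self):
        d = np.full(N, 3.0)
        d[:30] = 0.0  # entirely before -1 s: not a blink by definition
        out = interpolate_blinks(eye_trace(d))
        np.testing.assert_array_equal(out.d[:30], 0.0)

    def test_gaze_channels_interpolated_with_pupil(self):
        gx = np.full(N, 960.0)
        gy = np.full(N, 540.0)
        d = np.full(N, 3.0)
        d[600:620] = 0.0
        gx[600:620] = 0.0
        out = interpolate_blinks(eye_trace(d, gx=gx, gy=gy))
        np.testing.assert_allclose(out.gaze_x[600:620], 960.0)

    def test_fully_zero_trace_is_unrecoverable(self):
        with pytest.raises(ValueError):
            interpolate_blinks(eye_trace(np.zeros(N)))


class TestSmoothing:
    def test_constant_trace_unchanged(self):
        np.testing.assert_allclose(smooth(np.full(50, 2.5)), 2.5)

    def test_impulse_response_is_rectangle(self):
        x = np.zeros(101)
        x[50] = 1.0
        y = smooth(x)
        np.testing.assert_allclose(y[45:56], 1.0 / 11.0)
        assert y[44] == 0.0 and y[56] == 0.0

    def test_noise_variance_reduced_by_window_length(self, rng):
        x = rng.standard_normal(200_000)
        y = smooth(x)
        ratio = np.var(y[20:-20]) / np.var(x)
        assert ratio == pytest.approx(1.0 / 11.0, rel=0.05)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth(np.zeros(10), n_points=10)


class TestBaselineAndMetrics:
    def test_baseline_window_mean_zero_after_correction(self):
        rng = np.random.default_rng(3)
        d = 3.0 + 0.2 * rng.standard_normal(N)
        corrected, _ = baseline_correct(d, T)
        m = (T >= -1.0) & (T < 0.0)
        assert abs(corrected[m].mean()) < 1e-12

    def test_constant_trace_baseline(self):
        corrected, base = baseline_correct(np.full(N, 3.05), T)
        assert base == pytest.approx(3.05)
        np.testing.assert_allclose(corrected, 0.0, atol=1e-12)

    def test_ramp_baseline_closed_form(self):
        # r(t) = a + b t sampled on [-1, 0): mean = a + b * mean(t_k)
        a, b = 3.0, 0.4
        m = (T >= -1.0) & (T < 0.0)
        _, base = baseline_correct(a + b * T, T)
        assert base == pytest.approx(a + b * T[m].mean(), abs=1e-12)

    def test_metrics_recover_noise_free_peak(self):
        amp, peak_t = 0.30, 2.0
        d = amp * np.exp(-0.5 * ((T - peak_t) / 0.5) ** 2) * (T > 0)
        met = compute_metrics(d, T)
        assert met.ppd_mm == pytest.approx(amp, abs=1e-6)
        assert met.ppdl_ms == pytest.approx(2000.0, abs=1000.0 / RATE)

    def test_all_zero_trace_gives_zero_metrics(self):
        met = compute_metrics(np.zeros(N), T)
        assert met.ppd_mm == 0.0 and met.mpd_mm == 0.0

    def test_ppdl_tie_break_is_first_maximum(self):
        d = np.zeros(N)
        d[500] = d[800] = 1.0
        met = compute_metrics(d, T)
        assert met.ppdl_ms == pytest.approx(T[500] * 1000.0)

    @given(st.integers(0, 2**31 - 1))
    def test_ppd_at_least_mpd_for_any_trace(self, seed):
        d = np.random.default_rng(seed).standard_normal(N)
        met = compute_metrics(d, T)
        assert met.ppd_mm >= met.mpd_mm

    def test_second_baseline_correction_is_identity(self):
        """Pipeline idempotence past interpolation: baseline of a corrected
        trace is zero, so correcting again changes nothing."""
        rng = np.random.default_rng(8)
        d = smooth(3.0 + 0.1 * rng.standard_normal(N))
        once, _ = baseline_correct(d, T)
        twice, second_base = baseline_correct(once, T)
        assert abs(second_base) < 1e-12
        np.testing.assert_allclose(twice, once, atol=1e-12)


class TestDownsample:
    def test_constant_preserved(self):
        d2, t2 = downsample(np.full(1140, 3.0), T[:1140], RATE)
        np.testing.assert_allclose(d2, 3.0)
        assert len(d2) == 285

    def test_length_floor_division(self):
        d2, _ = downsample(np.zeros(1141), T, RATE)
        assert len(d2) == 1141 // 4

    def test_slow_sinusoid_amplitude_preserved(self):
        # analytic block-mean gain of a 1 Hz tone at 120 -> 30 Hz:
        # sin(N*theta/2) / (N*sin(theta/2)) with N=4, theta=2*pi/120
        t = np.arange(0, 10, 1 / RATE)
        x = np.sin(2 * np.pi * 1.0 * t)
        d2, t2 = downsample(x, t, RATE)
        amp = 2.0 * np.abs(np.mean(d2 * np.exp(-2j * np.pi * 1.0 * t2)))
        theta = 2 * np.pi / RATE
        gain = np.sin(4 * theta / 2) / (4 * np.sin(theta / 2))
        assert amp == pytest.approx(gain, abs=1e-4)
        assert gain > 0.998  # sub-0.2% attenuation at this rate ratio

    def test_timestamps_at_block_centers(self):
        _, t2 = downsample(np.zeros(8), np.arange(8) / RATE, RATE)
        assert t2[0] == pytest.approx(np.mean(np.arange(4) / RATE))

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError):
            downsample(np.zeros(100), np.arange(100.0), 120.0, target=50.0)


class TestTrialPipeline:
    def test_kept_trial_produces_metrics(self):
        d = 3.0 + 0.3 * np.exp(-0.5 * ((T - 1.5) / 0.6) ** 2) * (T > 0)
        res = preprocess_trial(eye_trace(d))
        assert res.disposition.kept
        assert res.metrics.ppd_mm == pytest.approx(0.3, abs=0.02)
        # smoothing leaks a few post-onset samples into the last baseline
        # points, so the baseline is only near-exact
        assert res.baseline_mm == pytest.approx(3.0, abs=1e-3)

    def test_excluded_trial_has_no_metrics(self):
        d = np.full(N, 3.0)
        d[360:660] = 0.0  # ~33% of the window
        res = preprocess_trial(eye_trace(d))
        assert not res.disposition.kept
        assert res.metrics is None

    def test_condition_average_of_identical_trials_is_identity(self):
        d = 3.0 + 0.2 * np.exp(-0.5 * ((T - 1.5) / 0.6) ** 2) * (T > 0)
        pt = preprocess_trial(eye_trace(d))
        meta = {"subject": "S1", "cond": "a"}
        df = condition_average([(meta, pt), (meta, pt)], keys=("subject", "cond"))
        assert df.loc[0, "n_trials"] == 2
        assert df.loc[0, "ppd_mm"] == pytest.approx(pt.metrics.ppd_mm)
        np.testing.assert_allclose(df.loc[0, "trace"], pt.d_corrected)

    def test_condition_average_flags_empty_groups(self):
        d = np.full(N, 3.0)
        d[360:660] = 0.0
        pt = preprocess_trial(eye_trace(d))
        df = condition_average([({"subject": "S1", "cond": "a"}, pt)], keys=("subject", "cond"))
        assert df.loc[0, "n_trials"] == 0
        assert np.isnan(df.loc[0, "ppd_mm"])
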