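"""Synthetic-data generator contracts: determinism, truth labels, series."""
import numpy as np
import pytest

from gaitconverge.evaluation import detect_walking_day, stream
from gaitconverge.simulate import (Bout, DayScript, GaitProfile, TrendSpec,
                                   default_walker_profile,
                                   simulate_parameter_series,
                                   simulate_recording_day)
from gaitconverge.trends import fit_linear_trend


def _plain_profile(**kw):
    kw.setdefault("stride_duration_mean_aff", 1.2)
    kw.setdefault("stride_duration_mean_nonaff", 1.2)
    kw.setdefault("stride_duration_sd", 0.0)
    kw.setdefault("noise_sd", 0.0)
    return GaitProfile(**kw)


class TestRecordingDay:
    def test_no_jitter_stride_count_is_floor_of_bout_over_duration(self):
        streams, truth = simulate_recording_day(
            _plain_profile(), DayScript([Bout("walk", 60.0)]))
        # 60 s at 1.2 s/stride -> 50 strides on each side
        assert truth.stride_times["Aff"].size == 50
        assert truth.stride_times["NonAff"].size == 50
        assert truth.walking_intervals == [(0, 3000)]

    def test_all_strides_inside_walking_intervals(self, walker_day):
        _, _, _, truth = walker_day
        for times in truth.stride_times.values():
            ok = np.zeros(times.size, dtype=bool)
            for a, b in truth.walking_intervals:
                ok |= (times >= a / 50.0) & (times < b / 50.0)
            assert ok.all()

    def test_sitting_only_day_contains_no_walking(self):
        streams, truth = simulate_recording_day(
            default_walker_profile(), DayScript([Bout("sit", 300.0)], seed=3))
        assert truth.walking_intervals == []
        assert truth.stride_times["Aff"].size == 0
        flags = detect_walking_day(streams, "walker")
        assert int(flags.sum()) == 0

    def test_same_seed_gives_bit_identical_streams(self):
        profile = default_walker_profile()
        bouts = []
        for _ in range(10):
            bouts += [Bout("walk", 30.0), Bout("sit", 30.0)]
        script = DayScript(bouts, seed=42)
        s1, t1 = simulate_recording_day(profile, script)
        s2, t2 = simulate_recording_day(profile, script)
        for a, b in zip(s1, s2):
            assert np.array_equal(a.acc, b.acc)
        for role in ("Aff", "NonAff"):
            assert np.array_equal(t1.stride_times[role],
                                  t2.stride_times[role])

    def test_rejects_bout_shorter_than_one_window(self):
        with pytest.raises(ValueError, match="window"):
            simulate_recording_day(default_walker_profile(),
                                   DayScript([Bout("sit", 0.5)]))

    def test_rejects_zero_stride_walk_bout(self):
        profile = GaitProfile(stride_duration_mean_aff=2.5,
                              stride_duration_mean_nonaff=2.5)
        with pytest.raises(ValueError, match="stride"):
            simulate_recording_day(profile, DayScript([Bout("walk", 2.0)]))

    def test_detector_compatibility_in_walk_windows(self, walker_day):
        # >= 90 % of fully-contained walk windows satisfy the indicator rule
        from gaitconverge.walking import annotation_window_labels
        _, _, streams, truth = walker_day
        flags = detect_walking_day(streams, "walker")
        labels, _ = annotation_window_labels(flags.size, truth.annotations)
        assert flags[labels].mean() >= 0.9
        assert (~flags[~labels]).mean() >= 0.9

    def test_one_dominant_thigh_peak_per_true_stride(self, noiseless_bout):
        _, streams, truth = noiseless_bout
        thigh = stream(streams, "thigh", "NonAff")
        y = thigh.axis("y")
        for pt in truth.stride_times["NonAff"]:
            i = int(round(pt * 50))
            lo, hi = max(0, i - 25), min(y.size, i + 26)
            # the stride event is the maximum of its neighborhood
            assert abs(int(np.argmax(y[lo:hi])) + lo - i) <= 1

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            GaitProfile(amplitude_asymmetry=0.0)
        with pytest.raises(ValueError):
            GaitProfile(stride_duration_mean_aff=0.1)
        with pytest.raises(ValueError):
            GaitProfile(sway_amp_aff=-1.0)


class TestParameterSeries:
    def test_analytic_cp_is_line_intersection(self):
        spec = TrendSpec(alpha_aff=8.0, alpha_nonaff=10.0, beta_aff=0.1,
                         beta_nonaff=0.0)
        series = simulate_parameter_series(spec, seed=0)
        assert series.analytic_cp == pytest.approx(20.0)
        assert not series.parallel
        # noiseless values lie exactly on the lines
        assert np.allclose(series.y_aff, 8.0 + 0.1 * series.days)

    def test_equal_slopes_flagged_parallel(self):
        spec = TrendSpec(alpha_aff=1.0, alpha_nonaff=2.0, beta_aff=0.05,
                         beta_nonaff=0.05)
        series = simulate_parameter_series(spec, seed=0)
        assert series.parallel
        assert series.analytic_cp is None

    def test_rejects_single_day(self):
        with pytest.raises(ValueError):
            TrendSpec(alpha_aff=0, alpha_nonaff=1, beta_aff=0, beta_nonaff=1,
                      n_days=1)

    def test_fitted_slope_is_unbiased_over_seeds(self):
        # Monte-Carlo parameter recovery: mean fitted slope within 2 SE
        spec = TrendSpec(alpha_aff=5.0, alpha_nonaff=7.0, beta_aff=0.08,
                         beta_nonaff=0.02, noise_sd=0.5, n_days=30)
        slopes = []
        for seed in range(200):
            series = simulate_parameter_series(spec, seed=seed)
            m = fit_linear_trend(series.days, series.y_aff)
            slopes.append(m.beta)
        days = spec.day_indices
        se_single = spec.noise_sd / np.sqrt(np.sum((days - days.mean()) ** 2))
        se_mean = se_single / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - spec.beta_aff) < 2 * se_mean
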