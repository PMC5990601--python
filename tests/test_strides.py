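"""Stride segmentation: periodicity filter, hill-climb peaks, pairing."""
import numpy as np
import pytest

from gaitconverge.datatypes import WalkingSegment
from gaitconverge.evaluation import (day_stride_sequences, segments_from_truth,
                                     stream, stride_match_fraction)
from gaitconverge.simulate import (Bout, DayScript, GaitProfile,
                                   default_walker_profile,
                                   simulate_recording_day)
from gaitconverge.strides import (hill_climb_peaks, pair_bilateral_strides,
                                  periodicity_filter, strides_from_segment)

FS = 50.0


def pulse_train(period, dur, amp=4.0, width=0.07, t0=0.4):
    t = np.arange(int(dur * FS)) / FS
    y = np.zeros_like(t)
    centers = np.arange(t0, dur - 0.2, period)
    for c in centers:
        y += amp * np.exp(-0.5 * ((t - c) / width) ** 2)
    return t, y, centers


class TestPeriodicityFilter:
    def test_pure_sinusoid_kept(self):
        t = np.arange(500) / FS
        assert periodicity_filter(np.sin(2 * np.pi * t), FS)

    def test_white_noise_rejected_in_most_seeds(self):
        kept = sum(
            periodicity_filter(
                np.random.default_rng(seed).normal(0, 1, 500), FS)
            for seed in range(50))
        assert kept <= 2  # rejected in >= 95 % of seeds

    def test_constant_signal_rejected(self):
        assert not periodicity_filter(np.full(500, 9.4), FS)

    def test_short_segment_rejected(self):
        t = np.arange(80) / FS
        assert not periodicity_filter(np.sin(2 * np.pi * t), FS)


class TestHillClimbPeaks:
    def test_pulse_train_recovered_with_correct_spacing(self):
        t, y, centers = pulse_train(1.2, 12.4)
        peaks = hill_climb_peaks(y, FS, t=t)
        assert peaks.size == centers.size == 10
        gaps = np.diff(peaks)
        assert np.all(np.abs(gaps - 1.2) <= 1.0 / FS + 1e-9)

    def test_close_pulses_thinned_by_min_separation(self):
        t = np.arange(int(4 * FS)) / FS
        y = np.zeros_like(t)
        for c, a in ((2.0, 4.0), (2.1, 3.0)):
            y += a * np.exp(-0.5 * ((t - c) / 0.05) ** 2)
        peaks = hill_climb_peaks(y, FS, t=t)
        assert peaks.size == 1
        assert abs(peaks[0] - 2.0) <= 0.06  # the higher pulse wins

    def test_flat_signal_has_no_peaks(self):
        assert hill_climb_peaks(np.full(500, 9.4), FS).size == 0

    def test_peaks_are_acceleration_maxima(self):
        t, y, centers = pulse_train(1.0, 8.0)
        peaks = hill_climb_peaks(y, FS, t=t)
        for p in peaks:
            assert np.min(np.abs(centers - p)) <= 1.0 / FS + 1e-9


class TestBilateralPairing:
    def _aff_signal(self, t, centers):
        y = np.zeros_like(t)
        for c in centers:
            y += 3.0 * np.exp(-0.5 * ((t - c) / 0.07) ** 2)
        return y

    def test_one_affected_stride_per_interval(self):
        t = np.arange(int(5 * FS)) / FS
        peaks_na = np.array([0.5, 1.5, 2.5, 3.5])
        y_aff = self._aff_signal(t, [1.0, 2.0, 3.0])
        seq = pair_bilateral_strides(peaks_na, y_aff, t, FS)
        assert len(seq.strides_nonaff) == 3
        assert len(seq.strides_aff) == 3
        # within one sample of the constructed affected peaks
        assert np.allclose([s.start_t for s in seq.strides_aff],
                           [1.0, 2.0, 3.0], atol=1.0 / FS + 1e-9)

    def test_surplus_affected_candidates_removed(self):
        t = np.arange(int(5 * FS)) / FS
        peaks_na = np.array([0.5, 1.5, 2.5, 3.5])
        y_aff = self._aff_signal(t, [1.0, 2.0, 3.0])
        # extra, lower-amplitude candidate inside the first interval
        y_aff += 1.5 * np.exp(-0.5 * ((t - 1.3) / 0.07) ** 2)
        seq = pair_bilateral_strides(peaks_na, y_aff, t, FS)
        assert len(seq.strides_aff) == 3
        assert seq.strides_aff[0].start_t == pytest.approx(1.0,
                                                           abs=1.0 / FS + 1e-9)

    def test_trailing_affected_peak_adds_one_stride(self):
        t = np.arange(int(5 * FS)) / FS
        peaks_na = np.array([0.5, 1.5, 2.5, 3.5])
        y_aff = self._aff_signal(t, [1.0, 2.0, 3.0, 4.0])
        seq = pair_bilateral_strides(peaks_na, y_aff, t, FS)
        assert len(seq.strides_nonaff) == 3
        assert len(seq.strides_aff) == 4
        diff = len(seq.strides_aff) - len(seq.strides_nonaff)
        assert abs(diff) <= 1

    def test_fewer_than_two_anchor_peaks_gives_empty_sequence(self):
        t = np.arange(100) / FS
        seq = pair_bilateral_strides(np.array([1.0]), np.zeros(100), t, FS)
        assert seq.strides_nonaff == [] and seq.strides_aff == []


class TestSegmentPipeline:
    def test_noiseless_boundaries_match_truth_within_one_sample(
            self, noiseless_bout):
        _, streams, truth = noiseless_bout
        seqs = day_stride_sequences(streams, segments_from_truth(truth))
        assert len(seqs) == 1
        for role in ("Aff", "NonAff"):
            det = np.array([s.start_t for s in seqs[0].strides(role)])
            true = truth.stride_times[role]
            for d in det:
                assert np.min(np.abs(true - d)) <= 1.0 / FS + 1e-9

    def test_default_noise_matches_95_percent_within_100ms(self):
        fracs = []
        for seed in range(5):
            streams, truth = simulate_recording_day(
                default_walker_profile(),
                DayScript([Bout("walk", 60.0), Bout("sit", 30.0)] * 3,
                          seed=seed))
            seqs = day_stride_sequences(streams, segments_from_truth(truth))
            fracs.append(stride_match_fraction(seqs, truth, tol_s=0.1))
        assert np.mean(fracs) >= 0.95

    def test_counts_differ_by_at_most_one_and_durations_bounded(
            self, walker_day):
        _, _, streams, truth = walker_day
        seqs = day_stride_sequences(streams, segments_from_truth(truth))
        assert seqs
        for seq in seqs:
            assert abs(len(seq.strides_aff) - len(seq.strides_nonaff)) <= 1
            for role in ("Aff", "NonAff"):
                for s in seq.strides(role):
                    assert 0.25 <= s.duration <= 3.0

    def test_four_stride_bout_rejected_by_min_strides_rule(self):
        profile = GaitProfile(stride_duration_mean_aff=1.2,
                              stride_duration_mean_nonaff=1.2,
                              stride_duration_sd=0.0, noise_sd=0.0)
        streams, truth = simulate_recording_day(
            profile, DayScript([Bout("walk", 5.9)]))
        assert truth.stride_times["NonAff"].size == 4
        na = stream(streams, "thigh", "NonAff")
        aff = stream(streams, "thigh", "Aff")
        seq, reason = strides_from_segment(
            WalkingSegment(0, na.n_samples, FS), na, aff)
        assert seq is None
        assert reason == "min_strides"

    def test_stride_spanning_a_pause_dropped_by_bounds(self, noiseless_bout):
        _, streams, truth = noiseless_bout
        na = stream(streams, "thigh", "NonAff")
        aff = stream(streams, "thigh", "Aff")
        # silence a 5 s hole mid-bout: the bridging interval exceeds 3 s
        for s in (na, aff):
            s.acc[1500:1750, 1] = 9.7
        seq, reason = strides_from_segment(
            WalkingSegment(0, na.n_samples, FS), na, aff)
        assert seq is not None
        for s in seq.strides_nonaff:
            assert s.duration <= 3.0

    def test_time_shift_equivariance(self, noiseless_bout):
        _, streams, _ = noiseless_bout
        na = stream(streams, "thigh", "NonAff")
        aff = stream(streams, "thigh", "Aff")
        seg = WalkingSegment(0, na.n_samples, FS)
        seq0, _ = strides_from_segment(seg, na, aff)
        shift = 17.0
        na2 = type(na)(na.patient_id, na.placement, na.body_side,
                       na.sampling_rate, na.t + shift, na.acc)
        aff2 = type(aff)(aff.patient_id, aff.placement, aff.body_side,
                         aff.sampling_rate, aff.t + shift, aff.acc)
        seq1, _ = strides_from_segment(seg, na2, aff2)
        for a, b in zip(seq0.strides_nonaff, seq1.strides_nonaff):
            assert b.start_t - a.start_t == pytest.approx(shift)
            assert b.end_t - a.end_t == pytest.approx(shift)
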