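"""Validation arithmetic on the published reference tables."""
import numpy as np
import pytest

from gaitconverge import validation as v

KEY = {"stride_duration": "dur", "cadence": "cad", "stride_count": "count"}


class TestRelativeError:
    @pytest.mark.parametrize("manual,algo,expected", [
        (2.09, 1.72, 17.70),   # largest affected-side duration error
        (1.06, 1.07, -0.94),
        (2.0, 2.0, 0.0),
    ])
    def test_signed_percentage(self, manual, algo, expected):
        assert v.relative_error(manual, algo) == pytest.approx(expected,
                                                               abs=0.005)

    def test_zero_manual_is_error(self):
        with pytest.raises(ValueError):
            v.relative_error(0.0, 1.0)

    def test_every_published_cell_reproduced(self):
        df = v.load_parameter_table()
        for param, key in KEY.items():
            for side in ("aff", "nonaff"):
                computed = np.array([
                    v.relative_error(m, a) for m, a in
                    zip(df[f"manual_{key}_{side}"], df[f"algo_{key}_{side}"])])
                printed = df[f"relerr_{key}_{side}"].to_numpy()
                assert np.max(np.abs(computed - printed)) <= 0.01


class TestAggregates:
    def test_published_group_mean_errors(self):
        agg = v.aggregate_validation()["mean_relative_error"]
        assert agg[("stride_duration", "aff")] == pytest.approx(2.26)
        assert agg[("stride_duration", "nonaff")] == pytest.approx(3.96)
        assert agg[("cadence", "aff")] == pytest.approx(-2.76)
        assert agg[("cadence", "nonaff")] == pytest.approx(-5.41)
        assert agg[("stride_count", "aff")] == pytest.approx(3.67)
        assert agg[("stride_count", "nonaff")] == pytest.approx(-0.79)

    def test_extreme_deviations_reproduced(self):
        df = v.load_parameter_table()
        r1 = df[df.patient_id == 1].iloc[0]
        r8 = df[df.patient_id == 8].iloc[0]
        assert v.relative_error(r1.manual_dur_nonaff,
                                r1.algo_dur_nonaff) == pytest.approx(28.10,
                                                                     abs=0.01)
        assert v.relative_error(r8.manual_cad_aff,
                                r8.algo_cad_aff) == pytest.approx(-20.82,
                                                                  abs=0.01)

    def test_single_record_group_is_identity(self):
        df = v.load_parameter_table().iloc[[2]]
        agg = v.aggregate_validation(df)["mean_relative_error"]
        assert agg[("stride_count", "aff")] == pytest.approx(5.66, abs=0.01)

    def test_group_means_permutation_invariant(self, rng):
        df = v.load_parameter_table()
        shuffled = df.sample(frac=1.0, random_state=11).reset_index(drop=True)
        assert v.aggregate_validation(df).equals(
            v.aggregate_validation(shuffled))

    def test_empty_group_is_error(self):
        df = v.load_parameter_table()
        with pytest.raises(ValueError):
            v.aggregate_validation(df[df.patient_id < 0])


class TestDetectionAggregates:
    def test_published_mean_sensitivities(self):
        assert v.aggregate_detection()["sensitivity"] == pytest.approx(
            69.3, abs=0.05)
        assert v.aggregate_detection(group="walker")[
            "sensitivity"] == pytest.approx(79.9, abs=0.05)
        assert v.aggregate_detection(group="wheelchair")[
            "sensitivity"] == pytest.approx(50.7, abs=0.05)

    def test_mean_specificity_above_94(self):
        for group in ("all", "walker", "wheelchair"):
            assert v.aggregate_detection(group=group)["specificity"] >= 94.0

    def test_single_patient_group(self):
        df = v.load_detection_table()
        one = df[df.patient_id == 7]
        assert v.aggregate_detection(one)["sensitivity"] == pytest.approx(
            75.88)


class TestSideGap:
    def test_published_side_gaps(self):
        assert v.side_gap(source="manual",
                          parameter="stride_count") == pytest.approx(0.18)
        assert v.side_gap(source="algorithm",
                          parameter="cadence") == pytest.approx(0.69)
        # 30 ms stride-duration gap, via rounded per-side means
        assert v.side_gap(source="algorithm",
                          parameter="stride_duration") == pytest.approx(0.03)

    def test_identical_side_columns_give_zero(self):
        df = v.load_parameter_table().copy()
        df["manual_cad_nonaff"] = df["manual_cad_aff"]
        assert v.side_gap(df, "manual", "cadence") == 0.0


class TestSyntheticApplication:
    def test_pipeline_error_magnitude_shrinks_with_noise(self):
        """The aggregation applied to synthetic truth vs. pipeline output
        yields smaller errors at lower simulator noise."""
        from gaitconverge.evaluation import (day_parameters,
                                             day_stride_sequences,
                                             segments_from_truth)
        from gaitconverge.simulate import (Bout, DayScript, GaitProfile,
                                           simulate_recording_day)

        def mean_abs_error(noise_sd, jitter):
            profile = GaitProfile(stride_duration_sd=jitter,
                                  noise_sd=noise_sd)
            script = DayScript([Bout("walk", 60.0), Bout("sit", 30.0)] * 3,
                               seed=5)
            streams, truth = simulate_recording_day(profile, script)
            seqs = day_stride_sequences(streams, segments_from_truth(truth))
            dp = day_parameters(streams, seqs)
            true_dur = profile.stride_duration_mean_nonaff
            true_sway = 2.0 * profile.sway_amp_nonaff / np.pi
            errors = [
                abs(v.relative_error(true_dur, dp.nonaff.dur_mean)),
                abs(v.relative_error(true_sway, dp.nonaff.sway_mean)),
            ]
            return float(np.mean(errors))

        clean = mean_abs_error(0.0, 0.0)
        noisy = mean_abs_error(0.1, 0.08)
        assert clean <= noisy + 1e-9
        assert clean < 0.5  # near-zero in the clean limit
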