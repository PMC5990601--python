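"""Scoring pipeline output against simulator ground truth.

Applies the same validation machinery used for the published reference
tables to synthetic recordings, where exact stride times and walking
intervals are known.
"""
from __future__ import annotations

import numpy as np

from .config import PipelineConfig
from .datatypes import SensorStream, StrideSequence, TruthTable, WalkingSegment
from .parameters import daily_summary, segment_parameters
from .preprocessing import window_features
from .simulate import GroundTruth
from .strides import strides_from_segment
from .walking import detection_truth_table, walking_indicator, windows_to_segments


def stream(streams: list[SensorStream], placement: str,
           role: str) -> SensorStream:
    """Pick one stream by placement and side role."""
    for s in streams:
        if s.placement == placement and s.role == role:
            return s
    raise ValueError(f"no {placement} stream with role {role}")


def detect_walking_day(streams: list[SensorStream], locomotion: str = "walker",
                       config: PipelineConfig | None = None) -> np.ndarray:
    """Window flags of the walking detector for one day's streams."""
    config = config or PipelineConfig()
    feats = window_features(stream(streams, "thigh", "NonAff"),
                            config.window_s)
    return walking_indicator(feats, locomotion, config.thresholds())


def day_detection_score(streams: list[SensorStream], truth: GroundTruth,
                        locomotion: str = "walker",
                        config: PipelineConfig | None = None) -> TruthTable:
    """Window-level detection truth table against simulator annotations."""
    config = config or PipelineConfig()
    flags = detect_walking_day(streams, locomotion, config)
    return detection_truth_table(flags, truth.annotations, config.window_s)


def segments_from_truth(truth: GroundTruth,
                        sampling_rate: float = 50.0) -> list[WalkingSegment]:
    """True walking intervals as segments (for isolating stride recovery)."""
    return [WalkingSegment(a, b, sampling_rate)
            for a, b in truth.walking_intervals]


def day_stride_sequences(streams: list[SensorStream],
                         segments: list[WalkingSegment],
                         config: PipelineConfig | None = None
                         ) -> list[StrideSequence]:
    """Stride segmentation of the given segments; rejected ones omitted."""
    config = config or PipelineConfig()
    na = stream(streams, "thigh", "NonAff")
    aff = stream(streams, "thigh", "Aff")
    out = []
    for seg in segments:
        seq, _ = strides_from_segment(
            seg, na, aff, median_kernel=config.median_kernel,
            ac_threshold=config.ac_threshold, min_strides=config.min_strides,
            min_separation=config.min_peak_separation,
            amp_quantile=config.peak_amp_quantile,
            amp_fraction=config.peak_amp_fraction,
            stride_min_s=config.stride_min_s,
            stride_max_s=config.stride_max_s)
        if seq is not None:
            out.append(seq)
    return out


def stride_match_fraction(sequences: list[StrideSequence], truth: GroundTruth,
                          tol_s: float = 0.1) -> float:
    """Fraction of true stride events matched by a detected stride boundary.

    Detected boundaries are the stride start times (plus the non-affected
    final stride end, which is itself a detected peak); true events are
    counted within the analyzed segments only.
    """
    total = matched = 0
    for role in ("Aff", "NonAff"):
        true_times = truth.stride_times[role]
        for seq in sequences:
            strides = seq.strides(role)
            if not strides:
                continue
            det = sorted({s.start_t for s in strides})
            if role == "NonAff":
                det.append(strides[-1].end_t)
            det = np.asarray(det)
            t0 = seq.segment.start_sample / seq.segment.sampling_rate
            t1 = seq.segment.end_sample / seq.segment.sampling_rate
            tin = true_times[(true_times >= t0) & (true_times < t1)]
            total += tin.size
            if tin.size:
                matched += int(np.sum(
                    np.min(np.abs(det[None, :] - tin[:, None]), axis=1)
                    <= tol_s))
    return matched / total if total else float("nan")


def day_parameters(streams: list[SensorStream],
                   sequences: list[StrideSequence],
                   patient_id: str = "sim", day: int = 1):
    """Daily movement-parameter summary for one simulated day."""
    arm_aff = stream(streams, "upper_arm", "Aff")
    arm_non = stream(streams, "upper_arm", "NonAff")
    params = [segment_parameters(seq, arm_aff, arm_non) for seq in sequences]
    recording_h = (streams[0].t[-1] - streams[0].t[0]) / 3600.0
    return daily_summary(params, recording_h, patient_id, day)
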