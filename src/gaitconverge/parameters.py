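"""Walking movement parameters: stride counts, duration, cadence, sway."""
from __future__ import annotations

import numpy as np

from .datatypes import (DailyParameters, SensorStream, SideDailyStats, Stride,
                        StrideSequence, WalkingSegment)


def cadence(n_strides: int, duration_s: float) -> float:
    """Strides per minute within one walking segment: C = n / t_WS[min]."""
    if duration_s <= 0:
        raise ValueError("segment duration must be positive")
    return n_strides / (duration_s / 60.0)


def sway(arm_x: np.ndarray, t: np.ndarray, stride: Stride) -> float:
    """Mean absolute mediolateral upper-arm acceleration within a stride.

    S = (sum of positive samples + |sum of negative samples|) / n over the
    stride's n raw samples, i.e. mean |x_i|; no detrending.
    """
    mask = (t >= stride.start_t) & (t < stride.end_t)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("stride spans fewer than two arm samples")
    return float(np.mean(np.abs(arm_x[mask])))


def segment_parameters(
    seq: StrideSequence,
    arm_aff: SensorStream | None = None,
    arm_nonaff: SensorStream | None = None,
) -> dict[str, dict]:
    """Per-side movement parameters of one verified walking segment.

    Sway for a side is computed from that side's upper-arm sensor; it is
    omitted when the arm stream is not given.
    """
    out: dict[str, dict] = {}
    t_ws = seq.segment.duration_s
    arms = {"Aff": arm_aff, "NonAff": arm_nonaff}
    for role in ("Aff", "NonAff"):
        strides = seq.strides(role)
        sways: list[float] = []
        arm = arms[role]
        if arm is not None:
            x = arm.axis("x")
            for s in strides:
                try:
                    sways.append(sway(x, arm.t, s))
                except ValueError:
                    continue
        out[role] = {
            "n_strides": len(strides),
            "durations": [s.duration for s in strides],
            "cadence": cadence(len(strides), t_ws),
            "sways": sways,
        }
    return out


def _mean_sd(values: list[float]) -> tuple[float, float]:
    """Mean and sample SD; absent (NaN) rather than zero when undefined."""
    if not values:
        return float("nan"), float("nan")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else float("nan")
    return mean, sd


def daily_summary(
    segment_params: list[dict[str, dict]],
    recording_h: float,
    patient_id: str = "",
    day: int = 1,
) -> DailyParameters:
    """Aggregate per-segment parameters into one day's summary.

    Stride duration and sway statistics pool all strides of the day;
    cadence statistics average over segments, unweighted.  The normalized
    stride count is the daily total divided by the recording duration in
    hours.  Days without strides report zero counts and absent means.
    """
    if recording_h <= 0:
        raise ValueError("recording span must be positive")
    sides = {}
    for role in ("Aff", "NonAff"):
        durations: list[float] = []
        sways: list[float] = []
        cadences: list[float] = []
        count = 0
        for sp in segment_params:
            p = sp[role]
            count += p["n_strides"]
            durations.extend(p["durations"])
            sways.extend(p["sways"])
            if p["n_strides"] > 0:
                cadences.append(p["cadence"])
        dur_mean, dur_sd = _mean_sd(durations)
        cad_mean, cad_sd = _mean_sd(cadences)
        sway_mean, sway_sd = _mean_sd(sways)
        sides[role] = SideDailyStats(
            stride_count=count,
            stride_count_norm=count / recording_h,
            dur_mean=dur_mean, dur_sd=dur_sd,
            cad_mean=cad_mean, cad_sd=cad_sd,
            sway_mean=sway_mean, sway_sd=sway_sd)
    return DailyParameters(patient_id=patient_id, day=day,
                           recording_h=recording_h,
                           aff=sides["Aff"], nonaff=sides["NonAff"])
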