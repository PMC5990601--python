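"""Walking-segment extraction and window-level detection scoring.

The detector is a threshold rule on the non-affected thigh's 1-s window
features: a window is walking iff

    mu_y > theta1  AND  mu_z < theta2  AND  var_y > theta3

with mu_y the vertical-axis mean (gravity-inclusive), mu_z the
anteroposterior mean and var_y the vertical-axis variance.  theta3 is
locomotion-type specific (walkers vs. wheelchair users).  The rule needs
no training data.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import TruthTable, WalkingSegment, WindowFeatures

WALKING_LABELS = ("walk", "physiotherapy_walk")


@dataclass
class Thresholds:
    theta1: float = 8.0    # m/s^2, vertical mean
    theta2: float = 4.0    # m/s^2, anteroposterior mean
    theta3_walker: float = 0.7       # (m/s^2)^2, vertical variance
    theta3_wheelchair: float = 0.25

    def __post_init__(self) -> None:
        if min(self.theta1, self.theta2,
               self.theta3_walker, self.theta3_wheelchair) <= 0:
            raise ValueError("all thresholds must be positive")

    def theta3(self, locomotion_type: str) -> float:
        if locomotion_type == "walker":
            return self.theta3_walker
        if locomotion_type == "wheelchair":
            return self.theta3_wheelchair
        raise ValueError(f"unknown locomotion type {locomotion_type!r}")


def walking_indicator(features: WindowFeatures, locomotion_type: str = "walker",
                      thresholds: Thresholds | None = None) -> np.ndarray:
    """Boolean walking flag per window (strict inequalities)."""
    if features.placement != "thigh" or features.role != "NonAff":
        raise ValueError(
            "walking indicator requires non-affected thigh features, got "
            f"placement={features.placement!r} role={features.role!r}")
    th = thresholds or Thresholds()
    th3 = th.theta3(locomotion_type)
    return ((features.mean[:, 1] > th.theta1)
            & (features.mean[:, 2] < th.theta2)
            & (features.var[:, 1] > th3))


def windows_to_segments(flags: np.ndarray, samples_per_window: int = 50,
                        sampling_rate: float = 50.0,
                        start_sample: int = 0) -> list[WalkingSegment]:
    """Merge maximal runs of walking windows into segments (no gap bridging)."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        return []
    padded = np.concatenate(([False], flags, [False]))
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [WalkingSegment(
        start_sample=start_sample + int(s) * samples_per_window,
        end_sample=start_sample + int(e) * samples_per_window,
        sampling_rate=sampling_rate) for s, e in zip(starts, ends)]


def _window_overlap(n_windows: int, window_s: float,
                    intervals: list[tuple[float, float]]) -> np.ndarray:
    """Fraction of each 1-s window covered by the given time intervals."""
    frac = np.zeros(n_windows)
    for (a, b) in intervals:
        for i in range(max(0, int(np.floor(a / window_s))),
                       min(n_windows, int(np.ceil(b / window_s)))):
            w0, w1 = i * window_s, (i + 1) * window_s
            frac[i] += max(0.0, min(b, w1) - max(a, w0))
    return frac / window_s


def annotation_window_labels(
    n_windows: int,
    annotations: list[tuple[float, float, str]],
    window_s: float = 1.0,
    walking_labels: tuple[str, ...] = WALKING_LABELS,
) -> tuple[np.ndarray, np.ndarray]:
    """Majority-overlap window labels from annotation intervals.

    Returns (is_walking, is_evaluated): a window counts as walking iff more
    than half of it overlaps a walking-labeled interval, and is evaluated
    iff more than half of it is covered by any annotation.
    """
    walk = [(a, b) for a, b, lab in annotations if lab in walking_labels]
    covered = [(a, b) for a, b, _ in annotations]
    is_walking = _window_overlap(n_windows, window_s, walk) > 0.5
    is_evaluated = _window_overlap(n_windows, window_s, covered) > 0.5
    return is_walking, is_evaluated


def detection_truth_table(
    flags: np.ndarray,
    annotations: list[tuple[float, float, str]],
    window_s: float = 1.0,
    walking_labels: tuple[str, ...] = WALKING_LABELS,
) -> TruthTable:
    """Score detected walking flags against annotations, window-level.

    TP/TN/FP/FN are percentages of evaluated windows; sensitivity =
    TP/(TP+FN), specificity = TN/(TN+FP), each NaN when undefined.
    """
    flags = np.asarray(flags, dtype=bool)
    labels, evaluated = annotation_window_labels(
        flags.size, annotations, window_s, walking_labels)
    n = int(evaluated.sum())
    if n == 0:
        raise ValueError("no annotated windows to evaluate")
    f, l = flags[evaluated], labels[evaluated]
    tp = float(np.sum(f & l)) / n * 100.0
    tn = float(np.sum(~f & ~l)) / n * 100.0
    fp = float(np.sum(f & ~l)) / n * 100.0
    fn = float(np.sum(~f & l)) / n * 100.0
    sens = tp / (tp + fn) * 100.0 if (tp + fn) > 0 else float("nan")
    spec = tn / (tn + fp) * 100.0 if (tn + fp) > 0 else float("nan")
    return TruthTable(tp=tp, tn=tn, fp=fp, fn=fn,
                      sensitivity=sens, specificity=spec, n_windows=n)


def exclude_segments(
    segments: list[WalkingSegment],
    annotations: list[tuple[float, float, str]],
    exclude_labels: tuple[str, ...] = ("physiotherapy_walk",),
    min_overlap: float = 0.5,
) -> list[WalkingSegment]:
    """Drop segments mostly overlapping excluded annotations (physiotherapy)."""
    excl = [(a, b) for a, b, lab in annotations if lab in exclude_labels]
    if not excl:
        return list(segments)
    kept = []
    for seg in segments:
        s0 = seg.start_sample / seg.sampling_rate
        s1 = seg.end_sample / seg.sampling_rate
        ov = sum(max(0.0, min(b, s1) - max(a, s0)) for a, b in excl)
        if ov <= min_overlap * (s1 - s0):
            kept.append(seg)
    return kept
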