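"""Core data containers shared across the pipeline stages.

Axis convention for all tri-axial acceleration data (m/s^2):
x = mediolateral, y = vertical (thigh/arm longitudinal when upright),
z = anteroposterior (walking direction).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

G = 9.80665
#: configured accelerometer range (+/- 4 g)
SENSOR_RANGE = 4.0 * G

PLACEMENTS = ("thigh", "upper_arm")
SIDES = ("left", "right")
ROLES = ("Aff", "NonAff")
AXES = ("x", "y", "z")


@dataclass
class SensorStream:
    """One body-worn sensor's timestamped tri-axial acceleration.

    ``t`` holds sample timestamps in seconds (strictly increasing) and
    ``acc`` the (n, 3) acceleration matrix with columns x, y, z.
    ``role`` is assigned later from the patient's affected side.
    """

    patient_id: str
    placement: str
    body_side: str
    sampling_rate: float
    t: np.ndarray
    acc: np.ndarray
    role: str | None = None

    def __post_init__(self) -> None:
        if self.placement not in PLACEMENTS:
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.body_side not in SIDES:
            raise ValueError(f"unknown body side {self.body_side!r}")
        if self.role is not None and self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if self.t.ndim != 1 or self.acc.shape != (self.t.size, 3):
            raise ValueError("t must be 1-D and acc of shape (len(t), 3)")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.acc.size and np.abs(self.acc).max() > SENSOR_RANGE + 1e-9:
            raise ValueError("acceleration exceeds the +/-4 g sensor range")

    @property
    def n_samples(self) -> int:
        return self.t.size

    def axis(self, name: str) -> np.ndarray:
        """Return one acceleration axis ('x', 'y' or 'z')."""
        return self.acc[:, AXES.index(name)]


@dataclass
class WindowFeatures:
    """Per-axis mean and variance over non-overlapping 1-s windows.

    ``mean`` and ``var`` have shape (n_windows, 3) with axis columns x, y, z.
    Variances are population variances (divide by n).
    """

    mean: np.ndarray
    var: np.ndarray
    window_s: float
    samples_per_window: int
    placement: str
    body_side: str
    role: str | None = None
    start_sample: int = 0

    @property
    def n_windows(self) -> int:
        return self.mean.shape[0]


@dataclass
class WalkingSegment:
    """A contiguous interval classified as walking.

    Sample bounds are half-open on the aligned grid.
    """

    start_sample: int
    end_sample: int
    sampling_rate: float = 50.0

    @property
    def duration_s(self) -> float:
        return (self.end_sample - self.start_sample) / self.sampling_rate


@dataclass
class TruthTable:
    """Window-level walking-detection truth table, as % of evaluated windows."""

    tp: float
    tn: float
    fp: float
    fn: float
    sensitivity: float
    specificity: float
    n_windows: int


@dataclass
class Stride:
    """One gait cycle of one leg: interval between same-side thigh peaks."""

    role: str
    start_t: float
    end_t: float

    @property
    def duration(self) -> float:
        return self.end_t - self.start_t


@dataclass
class StrideSequence:
    """Verified per-side stride sequences of one walking segment."""

    segment: WalkingSegment
    strides_aff: list[Stride] = field(default_factory=list)
    strides_nonaff: list[Stride] = field(default_factory=list)

    def strides(self, role: str) -> list[Stride]:
        return self.strides_aff if role == "Aff" else self.strides_nonaff


@dataclass
class SideDailyStats:
    """Per-side daily aggregate of the walking movement parameters.

    Means/SDs are NaN (absent), never zero, on days without strides.
    """

    stride_count: int = 0
    stride_count_norm: float = 0.0  # strides per hour of recording
    dur_mean: float = float("nan")
    dur_sd: float = float("nan")
    cad_mean: float = float("nan")
    cad_sd: float = float("nan")
    sway_mean: float = float("nan")
    sway_sd: float = float("nan")


@dataclass
class DailyParameters:
    patient_id: str
    day: int  # days since study begin (first recording day = 1)
    recording_h: float
    aff: SideDailyStats
    nonaff: SideDailyStats

    def side(self, role: str) -> SideDailyStats:
        return self.aff if role == "Aff" else self.nonaff


@dataclass
class TrendModel:
    """Per-parameter, per-side linear recovery trend y = alpha + beta * t."""

    parameter: str
    role: str
    alpha: float
    beta: float
    r_squared: float
    n_days: int


@dataclass
class ConvergencePoint:
    """Intersection day of the affected / non-affected trend lines.

    ``t_cp`` is NaN when the classification is 'parallel' or 'capped'.
    """

    parameter: str
    t_cp: float
    classification: str  # converging | diverging | parallel | capped
    t_max: float = 3650.0
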