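"""Synthetic accelerometer recordings and longitudinal parameter series.

The generator emulates the free-living recordings the pipeline expects:
four 50 Hz tri-axial sensors (both thighs, both upper arms) over a scripted
day of walking and non-walking bouts, with ground-truth walking intervals,
per-side stride event times, and per-stride sway values.

Signal model (documented in docs/methods.md):

* Thigh vertical axis (y) is gravity-dominated: ~9.4 m/s^2 upright (walking,
  standing), low (~2-2.5 m/s^2) when seated, so the walking indicator's
  mu_y > 8 m/s^2 threshold applies to raw, gravity-inclusive means.
* During walking the thigh y axis carries a stride-periodic oscillation plus
  one sharp transient pulse per stride; the pulse peak instant is the true
  stride boundary. The affected thigh's dynamic component is scaled by the
  profile's amplitude asymmetry.
* Upper-arm mediolateral axis (x) oscillates sinusoidally at the stride
  period with a per-side sway amplitude; the clean per-stride sway value of
  a sinusoid of amplitude A is 2A/pi.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import SENSOR_RANGE, SensorStream

WALK_ACTIVITIES = ("walk", "physiotherapy_walk")
NON_WALK_ACTIVITIES = ("sit", "stand", "wheelchair_propel")
ACTIVITIES = WALK_ACTIVITIES + NON_WALK_ACTIVITIES

STRIDE_MIN_S = 0.25
STRIDE_MAX_S = 3.0

# signal constants (m/s^2 unless noted)
UPRIGHT_Y = 9.7          # thigh vertical baseline when upright
SEATED_Y = 2.0           # thigh vertical baseline when seated
PROPEL_Y = 2.5           # seated, slight posture change while propelling
WALK_Z = 1.0             # anteroposterior baseline while upright
SEATED_Z = 9.3           # thigh axis rotated: gravity mostly anteroposterior
GAIT_OSC_Y = 2.0         # stride-periodic thigh oscillation amplitude
GAIT_OSC_Z = 0.5
GAIT_OSC_X = 0.3
PULSE_AMP = 4.0          # stride transient amplitude (non-affected thigh)
PULSE_WIDTH_S = 0.07     # Gaussian pulse sigma
ARM_Y = 9.0              # upper-arm longitudinal baseline (arm hanging)
PROPEL_ARM_X = 0.8       # arm oscillation while propelling a wheelchair
PROPEL_HZ = 1.1


@dataclass
class GaitProfile:
    """Per-patient gait assumptions driving the signal synthesis.

    Default stride-duration means are the study-population averages for the
    two sides; the affected thigh's dynamic signal component is attenuated
    by ``amplitude_asymmetry``; sway amplitudes are chosen so the clean
    per-stride sway (2A/pi) matches typical per-side values.
    """

    stride_duration_mean_aff: float = 1.40
    stride_duration_mean_nonaff: float = 1.38
    stride_duration_sd: float = 0.05
    amplitude_asymmetry: float = 0.75
    sway_amp_aff: float = 3.68
    sway_amp_nonaff: float = 1.82
    locomotion_type: str = "walker"
    noise_sd: float = 0.05
    phase_lag: float = 0.5    # affected-side stride phase, fraction of a stride
    start_offset: float = 0.3  # first stride event offset into the bout, ditto

    def __post_init__(self) -> None:
        for d in (self.stride_duration_mean_aff, self.stride_duration_mean_nonaff):
            if not (STRIDE_MIN_S <= d <= STRIDE_MAX_S):
                raise ValueError("stride duration mean outside [0.25, 3] s")
        if not (0.0 < self.amplitude_asymmetry <= 1.0):
            raise ValueError("amplitude_asymmetry must be in (0, 1]")
        if self.sway_amp_aff < 0 or self.sway_amp_nonaff < 0:
            raise ValueError("sway amplitudes must be >= 0")
        if self.locomotion_type not in ("walker", "wheelchair"):
            raise ValueError("locomotion_type must be 'walker' or 'wheelchair'")
        if self.stride_duration_sd < 0 or self.noise_sd < 0:
            raise ValueError("noise parameters must be >= 0")

    def stride_duration_mean(self, role: str) -> float:
        return (self.stride_duration_mean_aff if role == "Aff"
                else self.stride_duration_mean_nonaff)

    def sway_amp(self, role: str) -> float:
        return self.sway_amp_aff if role == "Aff" else self.sway_amp_nonaff


def default_walker_profile() -> GaitProfile:
    return GaitProfile()


def default_wheelchair_profile() -> GaitProfile:
    """Wheelchair-dependent patient: slower, more asymmetric, rare walking."""
    return GaitProfile(
        stride_duration_mean_aff=2.0,
        stride_duration_mean_nonaff=1.95,
        stride_duration_sd=0.08,
        amplitude_asymmetry=0.65,
        locomotion_type="wheelchair",
    )


@dataclass
class Bout:
    activity: str
    duration: float  # seconds

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise ValueError(f"unknown activity {self.activity!r}")
        if self.duration <= 0:
            raise ValueError("bout duration must be > 0")


@dataclass
class DayScript:
    """Ordered activity bouts of one simulated recording day."""

    bouts: list[Bout]
    sampling_rate: float = 50.0
    seed: int = 0
    day_index: int = 0

    @property
    def total_duration(self) -> float:
        return float(sum(b.duration for b in self.bouts))


def default_day_script(seed: int = 0, day_index: int = 0,
                       n_walks: int = 6, walk_s: float = 60.0,
                       rest_s: float = 120.0) -> DayScript:
    """Interleaved walking and rest bouts, a compressed day-care schedule."""
    bouts = [Bout("sit", rest_s)]
    rests = ("sit", "stand", "sit")
    for i in range(n_walks):
        bouts.append(Bout("walk", walk_s))
        bouts.append(Bout(rests[i % len(rests)], rest_s))
    return DayScript(bouts=bouts, seed=seed, day_index=day_index)


def default_wheelchair_day_script(seed: int = 0, day_index: int = 0,
                                  n_cycles: int = 3, walk_s: float = 60.0,
                                  propel_s: float = 90.0,
                                  rest_s: float = 120.0) -> DayScript:
    """Wheelchair-user day: propulsion and rest with occasional short walks."""
    bouts = [Bout("sit", rest_s)]
    for _ in range(n_cycles):
        bouts += [Bout("wheelchair_propel", propel_s), Bout("walk", walk_s),
                  Bout("sit", rest_s)]
    return DayScript(bouts=bouts, seed=seed, day_index=day_index)


@dataclass
class GroundTruth:
    """Reference labels of one simulated day.

    ``walking_intervals`` are half-open sample intervals; ``stride_times``
    maps role -> true stride event times (thigh pulse peaks, seconds);
    ``sway_truth`` maps role -> clean per-stride sway values (2A/pi).
    """

    walking_intervals: list[tuple[int, int]]
    stride_times: dict[str, np.ndarray]
    sway_truth: dict[str, np.ndarray]
    annotations: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        for times in self.stride_times.values():
            if times.size > 1 and not np.all(np.diff(times) > 0):
                raise ValueError("stride times must be strictly increasing")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated to the admissible stride-duration band."""
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if STRIDE_MIN_S <= v <= STRIDE_MAX_S:
            return float(v)
    return float(np.clip(mean, STRIDE_MIN_S, STRIDE_MAX_S))


def _stride_pulse_times(rng: np.random.Generator, start: float, duration: float,
                        d_mean: float, d_sd: float, lag_s: float) -> np.ndarray:
    """True stride event times within one walk bout.

    Without jitter exactly floor(duration / d_mean) events are emitted,
    uniformly spaced, the affected side shifted by its phase lag.  With
    jitter, inter-event times are truncated-normal draws and events stop
    half a mean stride before the bout end.
    """
    if d_sd == 0.0:
        n = int(np.floor(duration / d_mean + 1e-9))
        return start + lag_s + np.arange(n) * d_mean
    times = []
    t_cur = start + lag_s
    end = start + duration
    while t_cur <= end - 0.5 * d_mean:
        times.append(t_cur)
        t_cur += _truncated_normal(rng, d_mean, d_sd)
    return np.asarray(times)


def _gait_phase(tt: np.ndarray, pulses: np.ndarray, d_mean: float) -> np.ndarray:
    """Piecewise-linear gait phase: one 2*pi cycle per stride, 0 at each pulse.

    Locks the periodic signal components to the (possibly jittered) stride
    events; outside the pulse range the phase continues at the mean rate.
    """
    if pulses.size == 0:
        return 2 * np.pi * (tt - tt[0]) / d_mean
    n_pre = int(np.ceil(max(0.0, pulses[0] - tt[0]) / d_mean)) + 1
    n_post = int(np.ceil(max(0.0, tt[-1] - pulses[-1]) / d_mean)) + 1
    knots_t = np.concatenate([
        pulses[0] - d_mean * np.arange(n_pre, 0, -1),
        pulses,
        pulses[-1] + d_mean * np.arange(1, n_post + 1)])
    knots_v = 2 * np.pi * np.arange(knots_t.size, dtype=float)
    return np.interp(tt, knots_t, knots_v)


def _add_pulses(sig: np.ndarray, t: np.ndarray, pulse_times: np.ndarray,
                amp: float, width: float, fs: float) -> None:
    """Add Gaussian stride transients in place (local support only)."""
    half = int(np.ceil(5 * width * fs))
    for pt in pulse_times:
        c = int(round((pt - t[0]) * fs))
        lo, hi = max(0, c - half), min(t.size, c + half + 1)
        if lo < hi:
            sig[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - pt) / width) ** 2)


def simulate_recording_day(
    profile: GaitProfile,
    script: DayScript,
    affected_side: str = "left",
    patient_id: str = "sim",
) -> tuple[list[SensorStream], GroundTruth]:
    """Synthesize one recording day for four sensors plus its ground truth.

    Returns the streams (thigh and upper arm, both sides, roles already
    assigned from ``affected_side``) and a :class:`GroundTruth`.  Identical
    (profile, script, affected_side) inputs give bit-identical output.
    """
    if affected_side not in ("left", "right"):
        raise ValueError("affected_side must be 'left' or 'right'")
    fs = script.sampling_rate
    window_s = 1.0
    for b in script.bouts:
        if b.duration < window_s:
            raise ValueError("bout shorter than one analysis window")
        if b.activity in WALK_ACTIVITIES:
            d = profile.stride_duration_mean_nonaff
            if int(np.floor(b.duration / d + 1e-9)) < 1:
                raise ValueError("walk bout too short to contain a stride")

    rng = np.random.default_rng([int(script.seed) % 2**31, int(script.day_index)])
    n = int(round(script.total_duration * fs))
    t = np.arange(n) / fs

    sigs = {  # (placement, role) -> (n, 3) acceleration
        (p, r): np.zeros((n, 3)) for p in ("thigh", "upper_arm")
        for r in ("Aff", "NonAff")
    }

    walking_intervals: list[tuple[int, int]] = []
    stride_times: dict[str, list[np.ndarray]] = {"Aff": [], "NonAff": []}
    sway_truth: dict[str, list[np.ndarray]] = {"Aff": [], "NonAff": []}
    annotations: list[tuple[float, float, str]] = []

    start = 0.0
    for bout in script.bouts:
        end = start + bout.duration
        i0, i1 = int(round(start * fs)), int(round(end * fs))
        tt = t[i0:i1]
        annotations.append((start, end, bout.activity))

        if bout.activity in WALK_ACTIVITIES:
            walking_intervals.append((i0, i1))
            for role in ("Aff", "NonAff"):
                d_mean = profile.stride_duration_mean(role)
                scale = profile.amplitude_asymmetry if role == "Aff" else 1.0
                lag = (profile.start_offset
                       + (profile.phase_lag if role == "Aff" else 0.0)) * d_mean
                pulses = _stride_pulse_times(
                    rng, start, bout.duration, d_mean,
                    profile.stride_duration_sd, lag)
                stride_times[role].append(pulses)
                amp = profile.sway_amp(role)
                sway_truth[role].append(np.full(pulses.size, 2.0 * amp / np.pi))

                # periodic components run on the stride-locked gait phase;
                # the oscillation crest coincides with the stride pulse so
                # each stride has exactly one dominant acceleration peak
                phase = _gait_phase(tt, pulses, d_mean)
                thigh = sigs[("thigh", role)]
                thigh[i0:i1, 0] = scale * GAIT_OSC_X * np.sin(phase)
                y = UPRIGHT_Y + scale * GAIT_OSC_Y * np.cos(phase)
                _add_pulses(y, tt, pulses, scale * PULSE_AMP, PULSE_WIDTH_S, fs)
                thigh[i0:i1, 1] = y
                thigh[i0:i1, 2] = WALK_Z + scale * GAIT_OSC_Z * np.sin(phase + 0.5)

                arm = sigs[("upper_arm", role)]
                arm[i0:i1, 0] = amp * np.sin(phase)
                arm[i0:i1, 1] = ARM_Y
        else:
            for role in ("Aff", "NonAff"):
                thigh = sigs[("thigh", role)]
                arm = sigs[("upper_arm", role)]
                arm[i0:i1, 1] = ARM_Y
                if bout.activity == "sit":
                    thigh[i0:i1, 1] = SEATED_Y
                    thigh[i0:i1, 2] = SEATED_Z
                elif bout.activity == "stand":
                    thigh[i0:i1, 1] = UPRIGHT_Y
                    thigh[i0:i1, 2] = WALK_Z
                else:  # wheelchair_propel: seated, arms drive the chair
                    thigh[i0:i1, 1] = PROPEL_Y
                    thigh[i0:i1, 2] = SEATED_Z
                    arm[i0:i1, 0] = PROPEL_ARM_X * np.sin(
                        2 * np.pi * PROPEL_HZ * (tt - start))
        start = end

    side_of = {"Aff": affected_side,
               "NonAff": "right" if affected_side == "left" else "left"}
    streams = []
    for (placement, role), acc in sigs.items():
        acc = acc + rng.normal(0.0, profile.noise_sd, acc.shape)
        np.clip(acc, -SENSOR_RANGE, SENSOR_RANGE, out=acc)
        streams.append(SensorStream(
            patient_id=patient_id, placement=placement,
            body_side=side_of[role], sampling_rate=fs,
            t=t.copy(), acc=acc, role=role))

    truth = GroundTruth(
        walking_intervals=walking_intervals,
        stride_times={r: (np.concatenate(v) if v else np.empty(0))
                      for r, v in stride_times.items()},
        sway_truth={r: (np.concatenate(v) if v else np.empty(0))
                    for r, v in sway_truth.items()},
        annotations=annotations,
    )
    return streams, truth


@dataclass
class TrendSpec:
    """Ground truth of a longitudinal per-side parameter series.

    ``alpha`` are the day-1 offsets (parameter units), ``beta`` the slopes
    (units/day); daily observations get iid Normal(0, noise_sd^2) noise.
    """

    alpha_aff: float
    alpha_nonaff: float
    beta_aff: float
    beta_nonaff: float
    noise_sd: float = 0.0
    n_days: int = 30
    day_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_days < 2:
            raise ValueError("n_days must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.day_indices is None:
            self.day_indices = np.arange(1, self.n_days + 1, dtype=float)
        else:
            self.day_indices = np.asarray(self.day_indices, dtype=float)
            if self.day_indices.size != self.n_days:
                raise ValueError("day_indices length must equal n_days")

    @property
    def analytic_cp(self) -> float | None:
        """Intersection day of the two noise-free lines, None if parallel."""
        if self.beta_aff == self.beta_nonaff:
            return None
        return (self.alpha_aff - self.alpha_nonaff) / (
            self.beta_nonaff - self.beta_aff)


@dataclass
class ParameterSeries:
    days: np.ndarray
    y_aff: np.ndarray
    y_nonaff: np.ndarray
    analytic_cp: float | None
    parallel: bool


def simulate_parameter_series(spec: TrendSpec, seed: int = 0) -> ParameterSeries:
    """Draw per-side daily parameter observations around linear trends."""
    rng = np.random.default_rng(int(seed) % 2**31)
    days = spec.day_indices
    y_aff = spec.alpha_aff + spec.beta_aff * days + rng.normal(
        0.0, spec.noise_sd, days.size)
    y_nonaff = spec.alpha_nonaff + spec.beta_nonaff * days + rng.normal(
        0.0, spec.noise_sd, days.size)
    cp = spec.analytic_cp
    return ParameterSeries(days=days, y_aff=y_aff, y_nonaff=y_nonaff,
                           analytic_cp=cp, parallel=cp is None)
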