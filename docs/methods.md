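# Methods

This note documents the models, parameter choices, and numerical
conventions behind `gaitconverge`, and what the synthetic-data generator
does and does not emulate.

## Sensor model and preprocessing

All computations assume 50 Hz tri-axial accelerometers at four positions
(both thighs, both upper arms) with a fixed axis convention: x
mediolateral, y vertical / limb-longitudinal when upright, z
anteroposterior. Acceleration is raw and gravity-inclusive; the sensor
range is ±4 g and streams violating it are rejected at construction. No
orientation estimation, sensor fusion, or gravity removal is performed —
the detection thresholds are defined on gravity-inclusive means.

Streams are aligned by linear interpolation onto one uniform grid at the
nominal rate, covering only the span where all streams overlap; nominal
rates differing by more than 1 % are an error. Features are per-axis mean
and variance over non-overlapping 1-s windows (50 samples); the trailing
partial window is dropped because the detection thresholds were tuned on
full windows. Variances are population variances (divide by n): with
n = 50 the difference from sample variance is ≤ 2 %, and the convention is
fixed here once. Sensors are relabeled `Aff`/`NonAff` from the patient's
affected side; all downstream analysis is side-role-based.

## Walking extraction

A window of the non-affected thigh is walking iff all three strict
inequalities hold: vertical mean > θ1 = 8 m/s², anteroposterior mean
< θ2 = 4 m/s², vertical variance > θ3 (0.7 (m/s²)² for walkers, 0.25 for
wheelchair users, whose walking is slower and weaker). The non-affected
side is used because its signal amplitude is higher. The rule needs no
training data, which is what makes it usable for unannotated remote
monitoring. Maximal runs of walking windows become walking segments;
no gap bridging or minimum duration is applied at this stage because
spurious short segments are removed downstream by the periodicity and
five-stride filters.

Detection is scored window-level against annotation intervals: a window
counts as walking if more than half of it overlaps a walking annotation,
and enters evaluation if more than half of it is annotated at all.
TP/TN/FP/FN are percentages of evaluated windows; sensitivity and
specificity follow, reported as NaN (not zero) when their denominator is
empty. Window-level granularity is an assumption — the reference
percentages are fractions of recorded time and the window is this
pipeline's time quantum.

Segments overlapping physiotherapy annotations by more than half their
length can be excluded before parameter computation (`exclude_physio`,
default on), so that parameters describe natural walking.

## Stride segmentation

Per segment, on the vertical thigh axis:

1. **Periodicity filter.** The unbiased normalized autocorrelation of the
   mean-removed signal must reach 0.3 somewhere in the lag band
   [0.25, 3] s (the admissible stride-duration band). Segments shorter
   than 2 s or numerically constant are rejected. The 0.3 threshold
   separates periodic from aperiodic signals cleanly in simulation (white
   noise exceeds it in < 5 % of seeds at these segment lengths) and is a
   config key.
2. **Hill-climb peak detection.** The signal is median-smoothed (5
   samples = 0.1 s: removes sample noise without merging peaks ≥ 0.25 s
   apart) and differentiated by central differences. Local maxima of the
   derivative above 0.3 × its 95th-percentile amplitude seed an iterative
   ascent on the smoothed *acceleration* to the nearest local maximum, so
   emitted stride events are acceleration peaks — the feature a human
   annotator marks. Peaks closer than 0.25 s are thinned, keeping the
   higher peak (ties: the earlier). A flat signal yields no peaks.
3. **Bilateral verification.** The non-affected side anchors: its strides
   are the intervals between consecutive peaks. For each interval exactly
   one affected peak is kept — the detected candidate with the highest
   affected acceleration amplitude, or, if no candidate falls inside, the
   interval's affected acceleration maximum (so one peak per stride is
   ensured); surplus lower-amplitude candidates are removed, and a
   fallback pick closer than 0.25 s to an already-kept peak is skipped as
   a boundary artifact. One trailing affected candidate after the last
   non-affected peak may add one extra affected stride, since either side
   may close out a walking segment. Each affected peak marks one stride;
   the final affected stride's end is imputed from the last non-affected
   inter-peak interval, a documented convention needed because its closing
   peak is unobserved. Counts therefore differ by at most one per
   segment, and the count constraint is re-enforced after duration
   filtering by trimming the longer side's tail.
4. **Bounds and minimum run.** Strides outside [0.25, 3] s are discarded
   individually; the whole segment is rejected unless at least five
   consecutive in-bounds strides remain on the non-affected side (the
   anchor side — the reference leaves the side unstated).

Rejected segments carry a reason code (`too_short`, `aperiodic`,
`too_few_peaks`, `min_strides`, `excluded_annotation`) in the pipeline's
rejection log.

## Movement parameters

Per walking segment and side: cadence C = n_strides / t_WS in strides per
minute (note: strides, i.e. half the steps-per-minute figure common
elsewhere). Sway per stride is the mean absolute mediolateral upper-arm
acceleration over the stride's raw samples — positive and negative
excursions both count — taken from the side-matched arm sensor. Raw
samples are used (no detrending); an offset-corrected variant would be a
config-level change. Daily aggregates per side: total stride count;
normalized stride count in strides per recording hour (the unit under
which published totals and normalized values are mutually consistent);
mean/SD of stride duration and sway pooled over the day's strides; mean/SD
of cadence across segments, unweighted. SDs use the sample convention
(ddof = 1) and are absent (NaN) with fewer than two values; days without
strides report zero counts and absent, never zero, means.

## Trend analysis and convergence points

Each parameter's daily series is fitted per side by ordinary least
squares, y = α + βt, with t in days since study begin (day 1 = first
recording day); days without walking data are omitted, not zero-filled.
R² is reported, defined as 0 for a zero-variance response. The
convergence point CP = (α_Aff − α_NonAff)/(β_NonAff − β_Aff) is evaluated
on t ∈ [1, 3650] days; equal slopes are "parallel" and intersections
outside the horizon are "capped". A CP earlier than the last observed day
is reported as-is with classification "converging" — convergence already
achieved.

Trend classification: "parallel" iff the Pearson correlation between the
sides' daily values (raw values, not residuals) is positive with
p < 0.05; otherwise "converging" iff the fitted lines intersect within
[1, t_max], else "diverging". Side differences are tested with a paired
two-sided t-test (sides are measured on the same days); identical series
give t = 0, p = 1, while a zero-variance nonzero difference leaves p
undefined. Continuous convergence uses a growing window: for k = 2..K
days, both trends are refitted on days 1..k and the CP recorded,
supporting box-plot summaries of estimate stability. No multiple-testing
correction is applied across parameters.

## Synthetic-data generator

The generator produces what the pipeline needs to be testable without the
(unreleased) clinical recordings: four 50 Hz streams over a scripted day
of bouts (walk, physiotherapy walk, sit, stand, wheelchair propulsion)
with exact ground truth — walking intervals, per-side stride event times,
per-stride clean sway values.

Signal model and the reasoning behind it:

* **Thigh vertical axis**: baseline 9.7 m/s² upright (walking/standing),
  2–2.5 m/s² seated, so the μ_y > 8 m/s² rule discriminates posture
  exactly as it does on raw gravity-inclusive data. During walking a
  2.0 m/s² single-period oscillation plus one Gaussian transient pulse
  (amplitude 4 m/s², σ = 0.07 s) per stride are added, with the
  oscillation crest aligned to the pulse: each stride has exactly one
  dominant acceleration peak and monotone flanks, which is what the peak
  detector assumes about real gait. All periodic components run on a
  piecewise-linear "gait phase" locked to the jittered stride events, so
  jitter cannot drift the oscillation away from the pulses.
* **Stride events** are the pulse-peak instants; the first event sits 0.3
  strides into the bout (an event on the bout edge would be unobservable
  in principle) and the affected side lags by half a stride. Without
  jitter each side emits exactly floor(bout/stride-duration) events;
  stride-time jitter is normal, truncated to [0.25, 3] s.
* **Affected-side asymmetry**: the affected thigh's dynamic components are
  scaled by `amplitude_asymmetry` (default 0.75 walker, 0.65 wheelchair).
* **Arm sway**: the upper-arm mediolateral axis is a stride-period
  sinusoid with per-side amplitude; the clean per-stride sway of a
  sinusoid of amplitude A is 2A/π, which is the stored ground truth.
  Defaults (3.68 / 1.82 m/s²) put per-stride sway near 2.34 / 1.16 m/s²,
  typical affected/non-affected values.
* **Non-walking bouts**: sitting and propulsion rotate gravity onto the
  anteroposterior axis (μ_y ≈ 2–2.5 m/s², failing θ1); standing keeps the
  upright baseline but near-zero variance (failing θ3); propulsion adds
  arm oscillation at 1.1 Hz. The propulsion model is a stipulation — no
  quantitative description of propulsion accelerations was available.
* **Noise**: white Gaussian, σ = 0.05 m/s² per axis, a typical
  consumer-accelerometer noise level at 50 Hz bandwidth.
* **Defaults**: stride-duration means 1.40/1.38 s (walker Aff/NonAff,
  the study-population averages) and 2.00/1.95 s (wheelchair), jitter SD
  0.05/0.08 s.
* **Reproducibility**: one RNG stream per recording day, derived from
  (seed, day index); identical inputs give bit-identical output.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: soft-tissue and sensor-mounting artifacts,
orientation drift, turning, stairs, walking aids, within-bout speed
changes, non-scripted activity transitions, and the full diversity of
pathological gait (scuffing, spasticity, freezing). Synthetic results
bound algorithmic correctness, not clinical performance; the published
per-patient validation tables are packaged as fixtures precisely because
they are the only bit-reproducible link to real recordings.

The longitudinal generator draws per-side daily values around specified
linear trends with iid normal noise and returns the analytic intersection
day, giving trend/CP estimation an exact oracle.

## Validation fixtures

Two packaged CSVs hold the published per-patient validation results: the
walking-detection truth tables (11 patients; TP/TN/FP/FN, sensitivity,
specificity in %) and the manual vs. algorithm movement parameters
(stride duration, cadence, stride count, per side, plus the printed
relative-error cells). The relative error is (manual − algorithm)/manual
× 100 — positive when the algorithm underestimates — verified cell by
cell against the printed values. Group means are unweighted. Side gaps
reproduce means computed from rounded published columns by rounding the
per-side means to two decimals before differencing. The one printed gap
that requires this emulation is the 30 ms stride-duration gap. The same
aggregation code path applies to synthetic ground truth vs. pipeline
output; cohort-level statistics (age etc.) are deliberately excluded from
fixtures because the printed summary row is internally inconsistent.

## Problem sizes

Simulated test days are compressed day-care schedules (typically 15–25
minutes of signal containing 3–6 walk bouts of 45–60 s) rather than 8-h
recordings: every algorithmic code path (bout transitions, segment
filtering, bilateral pairing, daily aggregation) is exercised while the
suite stays fast. Property suites use 5–20 simulated days; convergence
recovery uses 200 replicates of 30-day series; the continuous-CP
variance check uses 120 replicates.

## Known limitations

* The hill-climber's seeding (derivative maxima above a quantile
  threshold) and ascent target (acceleration maxima) are one concrete
  reading of an underspecified procedure; alternatives (ascent on the
  derivative itself) would shift stride boundaries by a fixed fraction of
  the pulse width.
* When the two sides' stride phases collide (legs nearly in phase), the
  bilateral verifier can lose a few strides around the collision; the
  duration bounds keep the parameter statistics clean but stride counts
  dip locally.
* Stride counts per segment are interval counts (peaks − 1 on the anchor
  side), so a segment's count is one less than its event count — visible
  when comparing against event-based ground truth.
* Linear trends are a deliberate simplification of recovery dynamics;
  convergence points extrapolate them far beyond the observed span and
  should be read as a screening metric, not a forecast.
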