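"""Stream alignment, affected-side relabeling, and 1-s window features."""
from __future__ import annotations

import numpy as np

from .datatypes import SensorStream, WindowFeatures


def align_streams(streams: list[SensorStream],
                  rate_tolerance: float = 0.01) -> list[SensorStream]:
    """Resample all streams onto one shared uniform grid.

    The grid runs at the first stream's nominal rate over the time span
    where all streams overlap; values are linearly interpolated.  Raises
    ``ValueError`` on empty overlap or nominal-rate mismatch > 1 %.
    """
    if not streams:
        raise ValueError("need at least one stream")
    rates = np.array([s.sampling_rate for s in streams], dtype=float)
    if rates.max() / rates.min() - 1.0 > rate_tolerance:
        raise ValueError("sampling-rate mismatch exceeds 1 %")
    fs = float(rates[0])
    start = max(s.t[0] for s in streams)
    end = min(s.t[-1] for s in streams)
    if end <= start:
        raise ValueError("streams have no overlapping time span")
    n = int(np.floor((end - start) * fs + 1e-9)) + 1
    grid = start + np.arange(n) / fs
    out = []
    for s in streams:
        acc = np.column_stack([np.interp(grid, s.t, s.acc[:, k])
                               for k in range(3)])
        out.append(SensorStream(
            patient_id=s.patient_id, placement=s.placement,
            body_side=s.body_side, sampling_rate=fs,
            t=grid.copy(), acc=acc, role=s.role))
    return out


def assign_sides(streams: list[SensorStream],
                 affected_side: str) -> list[SensorStream]:
    """Label each stream Aff/NonAff from the patient's affected side."""
    if affected_side not in ("left", "right"):
        raise ValueError("affected_side must be 'left' or 'right'")
    for s in streams:
        s.role = "Aff" if s.body_side == affected_side else "NonAff"
    return streams


def window_features(stream: SensorStream, window_s: float = 1.0) -> WindowFeatures:
    """Per-axis mean and population variance over non-overlapping windows.

    The trailing partial window is dropped.  A stream shorter than one
    window yields zero windows (not an error).
    """
    spw = int(round(window_s * stream.sampling_rate))
    n_win = stream.n_samples // spw
    if n_win == 0:
        shape = (0, 3)
        return WindowFeatures(np.empty(shape), np.empty(shape), window_s, spw,
                              stream.placement, stream.body_side, stream.role)
    blocks = stream.acc[: n_win * spw].reshape(n_win, spw, 3)
    return WindowFeatures(
        mean=blocks.mean(axis=1), var=blocks.var(axis=1),
        window_s=window_s, samples_per_window=spw,
        placement=stream.placement, body_side=stream.body_side,
        role=stream.role)
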