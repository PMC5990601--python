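"""End-to-end orchestration of the four analysis stages.

Each stage reads its inputs from files and writes its outputs to files, so
running the stages individually (chained via their outputs) is identical
to one end-to-end run.  All stages are deterministic: identical inputs and
configuration give byte-identical outputs.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .config import PipelineConfig
from .datatypes import DailyParameters, Stride, StrideSequence, WalkingSegment
from .parameters import daily_summary, segment_parameters
from .preprocessing import align_streams, assign_sides, window_features
from .strides import strides_from_segment
from .trends import (classify_trend, continuous_convergence, convergence_point,
                     fit_linear_trend, side_difference_test)
from .walking import (detection_truth_table, exclude_segments,
                      walking_indicator, windows_to_segments)

log = logging.getLogger(__name__)

#: daily-parameter columns analyzed for recovery trends
TREND_PARAMETERS = ("stride_count_norm", "dur_mean", "dur_sd",
                    "cad_mean", "cad_sd", "sway_mean", "sway_sd")

DAILY_COLUMNS = ["patient_id", "day", "side", "stride_count",
                 "stride_count_norm", "dur_mean", "dur_sd", "cad_mean",
                 "cad_sd", "sway_mean", "sway_sd", "recording_h"]


def _prepared_day(root: Path, patient: dict, day_dir: Path,
                  config: PipelineConfig):
    """Aligned, role-labeled streams of one recording day, plus annotations."""
    streams = gio.read_day_streams(day_dir, patient["patient_id"])
    streams = align_streams(streams)
    assign_sides(streams, patient["affected_side"])
    ann_path = day_dir / "annotations.csv"
    annotations = gio.read_annotations(ann_path) if ann_path.exists() else []
    return streams, annotations


def _stream(streams, placement: str, role: str):
    for s in streams:
        if s.placement == placement and s.role == role:
            return s
    raise ValueError(f"missing {placement} stream for role {role}")


def stage_detect(input_dir: str | Path, out_dir: str | Path,
                 config: PipelineConfig | None = None) -> pd.DataFrame:
    """Stage 1+2: features and walking-segment extraction for every day."""
    config = config or PipelineConfig()
    root, out = Path(input_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seg_rows, det_rows = [], []
    for patient in gio.read_patients(root).to_dict("records"):
        pid = patient["patient_id"]
        for day, day_dir in gio.day_dirs(root, pid):
            streams, annotations = _prepared_day(root, patient, day_dir, config)
            feats = window_features(_stream(streams, "thigh", "NonAff"),
                                    config.window_s)
            flags = walking_indicator(feats, patient["locomotion_type"],
                                      config.thresholds())
            segments = windows_to_segments(
                flags, feats.samples_per_window, config.sampling_rate)
            for i, seg in enumerate(segments):
                seg_rows.append({
                    "patient_id": pid, "day": day, "segment_id": i,
                    "start_sample": seg.start_sample,
                    "end_sample": seg.end_sample,
                    "duration_s": seg.duration_s})
            if annotations:
                tt = detection_truth_table(flags, annotations, config.window_s)
                det_rows.append({"patient_id": pid, "day": day,
                                 "tp": tt.tp, "tn": tt.tn, "fp": tt.fp,
                                 "fn": tt.fn, "sensitivity": tt.sensitivity,
                                 "specificity": tt.specificity})
    seg_df = pd.DataFrame(seg_rows, columns=[
        "patient_id", "day", "segment_id", "start_sample", "end_sample",
        "duration_s"])
    seg_df.to_csv(out / "segments.csv", index=False, float_format="%.3f")
    pd.DataFrame(det_rows, columns=[
        "patient_id", "day", "tp", "tn", "fp", "fn", "sensitivity",
        "specificity"]).to_csv(out / "detection.csv", index=False,
                               float_format="%.4f")
    return seg_df


def stage_strides(input_dir: str | Path, out_dir: str | Path,
                  config: PipelineConfig | None = None) -> pd.DataFrame:
    """Stage 3a: stride segmentation of every detected walking segment."""
    config = config or PipelineConfig()
    root, out = Path(input_dir), Path(out_dir)
    seg_df = pd.read_csv(out / "segments.csv", dtype={"patient_id": str})
    stride_rows, reject_rows = [], []
    for patient in gio.read_patients(root).to_dict("records"):
        pid = patient["patient_id"]
        for day, day_dir in gio.day_dirs(root, pid):
            sel = seg_df[(seg_df.patient_id == pid) & (seg_df.day == day)]
            if sel.empty:
                continue
            streams, annotations = _prepared_day(root, patient, day_dir, config)
            segments = [WalkingSegment(int(r.start_sample), int(r.end_sample),
                                       config.sampling_rate)
                        for r in sel.itertuples()]
            seg_ids = list(sel.segment_id)
            if config.exclude_physio and annotations:
                kept = exclude_segments(segments, annotations,
                                        config.exclude_labels)
                kept_keys = {(s.start_sample, s.end_sample) for s in kept}
                for sid, seg in zip(seg_ids, segments):
                    if (seg.start_sample, seg.end_sample) not in kept_keys:
                        reject_rows.append({"patient_id": pid, "day": day,
                                            "segment_id": sid,
                                            "reason": "excluded_annotation"})
                pairs = [(sid, s) for sid, s in zip(seg_ids, segments)
                         if (s.start_sample, s.end_sample) in kept_keys]
            else:
                pairs = list(zip(seg_ids, segments))
            thigh_na = _stream(streams, "thigh", "NonAff")
            thigh_aff = _stream(streams, "thigh", "Aff")
            for sid, seg in pairs:
                seq, reason = strides_from_segment(
                    seg, thigh_na, thigh_aff,
                    median_kernel=config.median_kernel,
                    ac_threshold=config.ac_threshold,
                    min_strides=config.min_strides,
                    min_separation=config.min_peak_separation,
                    amp_quantile=config.peak_amp_quantile,
                    amp_fraction=config.peak_amp_fraction,
                    stride_min_s=config.stride_min_s,
                    stride_max_s=config.stride_max_s)
                if seq is None:
                    log.info("segment rejected: patient=%s day=%s id=%s "
                             "reason=%s", pid, day, sid, reason)
                    reject_rows.append({"patient_id": pid, "day": day,
                                        "segment_id": sid, "reason": reason})
                    continue
                for role in ("Aff", "NonAff"):
                    for s in seq.strides(role):
                        stride_rows.append({
                            "patient_id": pid, "day": day, "segment_id": sid,
                            "side": role, "start_s": s.start_t,
                            "end_s": s.end_t, "duration_s": s.duration})
    pd.DataFrame(stride_rows, columns=[
        "patient_id", "day", "segment_id", "side", "start_s", "end_s",
        "duration_s"]).to_csv(out / "strides.csv", index=False,
                              float_format="%.4f")
    pd.DataFrame(reject_rows, columns=[
        "patient_id", "day", "segment_id", "reason"]).to_csv(
        out / "rejected_segments.csv", index=False)
    return pd.read_csv(out / "strides.csv", dtype={"patient_id": str})


def stage_parameters(input_dir: str | Path, out_dir: str | Path,
                     config: PipelineConfig | None = None) -> pd.DataFrame:
    """Stage 3b: per-day, per-side movement-parameter aggregation."""
    config = config or PipelineConfig()
    root, out = Path(input_dir), Path(out_dir)
    seg_df = pd.read_csv(out / "segments.csv", dtype={"patient_id": str})
    str_df = pd.read_csv(out / "strides.csv", dtype={"patient_id": str})
    rows = []
    for patient in gio.read_patients(root).to_dict("records"):
        pid = patient["patient_id"]
        for day, day_dir in gio.day_dirs(root, pid):
            streams, _ = _prepared_day(root, patient, day_dir, config)
            recording_h = ((streams[0].t[-1] - streams[0].t[0]) / 3600.0
                           if streams[0].n_samples else 0.0)
            segs = seg_df[(seg_df.patient_id == pid) & (seg_df.day == day)]
            strs = str_df[(str_df.patient_id == pid) & (str_df.day == day)]
            seg_params = []
            for r in segs.itertuples():
                ss = strs[strs.segment_id == r.segment_id]
                if ss.empty:
                    continue
                seq = StrideSequence(
                    segment=WalkingSegment(int(r.start_sample),
                                           int(r.end_sample),
                                           config.sampling_rate))
                for srow in ss.itertuples():
                    seq.strides(srow.side).append(
                        Stride(srow.side, float(srow.start_s),
                               float(srow.end_s)))
                seg_params.append(segment_parameters(
                    seq, arm_aff=_stream(streams, "upper_arm", "Aff"),
                    arm_nonaff=_stream(streams, "upper_arm", "NonAff")))
            dp = daily_summary(seg_params, recording_h, pid, day)
            for role, stats in (("Aff", dp.aff), ("NonAff", dp.nonaff)):
                rows.append({"patient_id": pid, "day": day, "side": role,
                             "stride_count": stats.stride_count,
                             "stride_count_norm": stats.stride_count_norm,
                             "dur_mean": stats.dur_mean,
                             "dur_sd": stats.dur_sd,
                             "cad_mean": stats.cad_mean,
                             "cad_sd": stats.cad_sd,
                             "sway_mean": stats.sway_mean,
                             "sway_sd": stats.sway_sd,
                             "recording_h": recording_h})
    df = pd.DataFrame(rows, columns=DAILY_COLUMNS)
    df.to_csv(out / "daily_parameters.csv", index=False, float_format="%.5f")
    return df


def stage_trends(out_dir: str | Path,
                 config: PipelineConfig | None = None) -> dict:
    """Stage 4: per-patient recovery trends, classification and CPs."""
    config = config or PipelineConfig()
    out = Path(out_dir)
    df = pd.read_csv(out / "daily_parameters.csv", dtype={"patient_id": str})
    report: dict = {}
    cp_rows = []
    for pid, pdf in df.groupby("patient_id", sort=True):
        report[pid] = {}
        wide = pdf.pivot_table(index="day", columns="side",
                               values=list(TREND_PARAMETERS), sort=True)
        for param in TREND_PARAMETERS:
            entry: dict = {"parameter": param}
            try:
                y_aff = wide[(param, "Aff")].to_numpy(dtype=float)
                y_non = wide[(param, "NonAff")].to_numpy(dtype=float)
            except KeyError:
                y_aff = y_non = np.array([])
            days = wide.index.to_numpy(dtype=float) if len(wide) else np.array([])
            ok = (days.size >= 2 and np.sum(~np.isnan(y_aff)) >= 2
                  and np.sum(~np.isnan(y_non)) >= 2)
            if not ok:
                log.warning("patient %s: too little walking data for a %s "
                            "trend", pid, param)
                entry["trend"] = None
                report[pid][param] = entry
                continue
            ma = fit_linear_trend(days, y_aff, param, "Aff")
            mn = fit_linear_trend(days, y_non, param, "NonAff")
            cp = convergence_point(ma, mn, t_max=config.t_max)
            cls = classify_trend(days, y_aff, y_non, ma, mn)
            try:
                p_value = side_difference_test(y_aff, y_non)
            except ValueError:
                p_value = float("nan")
            both = ~np.isnan(y_aff) & ~np.isnan(y_non)
            cps = continuous_convergence(days[both], y_aff[both], y_non[both],
                                         param, t_max=config.t_max) \
                if both.sum() >= 2 else []
            entry.update({
                "trend": {
                    "Aff": {"alpha": ma.alpha, "beta": ma.beta,
                            "r_squared": ma.r_squared, "n_days": ma.n_days},
                    "NonAff": {"alpha": mn.alpha, "beta": mn.beta,
                               "r_squared": mn.r_squared, "n_days": mn.n_days},
                },
                "classification": cls,
                "convergence_point": {
                    "t_cp": None if np.isnan(cp.t_cp) else cp.t_cp,
                    "classification": cp.classification,
                    "t_max": cp.t_max},
                "p_value": None if np.isnan(p_value) else p_value,
                "continuous_cp": [
                    {"window_days": k + 2,
                     "t_cp": None if np.isnan(c.t_cp) else c.t_cp,
                     "classification": c.classification}
                    for k, c in enumerate(cps)],
            })
            for k, c in enumerate(cps):
                cp_rows.append({"patient_id": pid, "parameter": param,
                                "window_days": k + 2, "t_cp": c.t_cp,
                                "classification": c.classification})
            report[pid][param] = entry
    (out / "trend_report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True))
    pd.DataFrame(cp_rows, columns=[
        "patient_id", "parameter", "window_days", "t_cp",
        "classification"]).to_csv(out / "cp_summary.csv", index=False,
                                  float_format="%.4f")
    return report


def run_pipeline(input_dir: str | Path, out_dir: str | Path,
                 config: PipelineConfig | None = None
                 ) -> tuple[pd.DataFrame, dict]:
    """Run all four stages in order; returns the daily table and report."""
    config = config or PipelineConfig()
    stage_detect(input_dir, out_dir, config)
    stage_strides(input_dir, out_dir, config)
    daily = stage_parameters(input_dir, out_dir, config)
    report = stage_trends(out_dir, config)
    return daily, report
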