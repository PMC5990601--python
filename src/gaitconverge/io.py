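"""Dataset reading and writing.

On-disk layout of a recording dataset (real or simulated)::

    <root>/patients.csv              patient_id,affected_side,locomotion_type
    <root>/manifest.csv              patient_id,sensor_id,placement,body_side
    <root>/<patient>/day_<k>/<placement>_<side>.csv   time_s,ax,ay,az
    <root>/<patient>/day_<k>/annotations.csv          start_s,end_s,label
    <root>/<patient>/day_<k>/truth.json               optional ground truth

Sensor CSVs hold one header row and columns time_s, ax, ay, az in m/s^2
(x mediolateral, y vertical, z anteroposterior).  All writers use fixed
float formats so identical inputs give byte-identical files.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import SensorStream
from .simulate import GroundTruth

TIME_FMT = "%.3f"
ACC_FMT = "%.5f"


def write_sensor_csv(path: str | Path, stream: SensorStream) -> None:
    df = pd.DataFrame({"time_s": stream.t, "ax": stream.acc[:, 0],
                       "ay": stream.acc[:, 1], "az": stream.acc[:, 2]})
    df.to_csv(path, index=False,
              float_format=ACC_FMT)


def read_sensor_csv(path: str | Path, patient_id: str, placement: str,
                    body_side: str) -> SensorStream:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    acc = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"sensor file {path} too short")
    fs = float(round(1.0 / np.median(np.diff(t))))
    return SensorStream(patient_id=patient_id, placement=placement,
                        body_side=body_side, sampling_rate=fs, t=t, acc=acc)


def write_annotations(path: str | Path,
                      annotations: list[tuple[float, float, str]]) -> None:
    df = pd.DataFrame(annotations, columns=["start_s", "end_s", "label"])
    df.to_csv(path, index=False, float_format=TIME_FMT)


def read_annotations(path: str | Path) -> list[tuple[float, float, str]]:
    df = pd.read_csv(path)
    return [(float(a), float(b), str(lab))
            for a, b, lab in zip(df["start_s"], df["end_s"], df["label"])]


def write_truth_json(path: str | Path, truth: GroundTruth) -> None:
    payload = {
        "walking_intervals": [[int(a), int(b)]
                              for a, b in truth.walking_intervals],
        "stride_times": {r: [round(float(v), 4) for v in times]
                         for r, times in truth.stride_times.items()},
        "sway_truth": {r: [round(float(v), 5) for v in vals]
                       for r, vals in truth.sway_truth.items()},
        "annotations": [[round(float(a), 3), round(float(b), 3), lab]
                        for a, b, lab in truth.annotations],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth_json(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        walking_intervals=[(int(a), int(b))
                           for a, b in payload["walking_intervals"]],
        stride_times={r: np.asarray(v, dtype=float)
                      for r, v in payload["stride_times"].items()},
        sway_truth={r: np.asarray(v, dtype=float)
                    for r, v in payload["sway_truth"].items()},
        annotations=[(float(a), float(b), str(lab))
                     for a, b, lab in payload["annotations"]],
    )


def write_day(day_dir: str | Path, streams: list[SensorStream],
              truth: GroundTruth | None = None) -> None:
    day_dir = Path(day_dir)
    day_dir.mkdir(parents=True, exist_ok=True)
    for s in streams:
        write_sensor_csv(day_dir / f"{s.placement}_{s.body_side}.csv", s)
    if truth is not None:
        write_annotations(day_dir / "annotations.csv", truth.annotations)
        write_truth_json(day_dir / "truth.json", truth)


def write_patient_tables(root: str | Path,
                         patients: list[dict]) -> None:
    """Write patients.csv and manifest.csv for the given patient dicts
    (keys: patient_id, affected_side, locomotion_type)."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(patients).to_csv(root / "patients.csv", index=False)
    manifest = [{"patient_id": p["patient_id"],
                 "sensor_id": f"S{i + 1}",
                 "placement": placement, "body_side": side}
                for p in patients
                for i, (placement, side) in enumerate(
                    [("thigh", "left"), ("thigh", "right"),
                     ("upper_arm", "left"), ("upper_arm", "right")])]
    pd.DataFrame(manifest).to_csv(root / "manifest.csv", index=False)


def read_patients(root: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(root) / "patients.csv", dtype={"patient_id": str})


def day_dirs(root: str | Path, patient_id: str) -> list[tuple[int, Path]]:
    """Sorted (day_index, path) pairs for one patient's recording days."""
    pdir = Path(root) / str(patient_id)
    out = []
    for d in sorted(pdir.glob("day_*")):
        try:
            out.append((int(d.name.split("_", 1)[1]), d))
        except ValueError:
            continue
    return sorted(out)


def read_day_streams(day_dir: str | Path, patient_id: str,
                     manifest: pd.DataFrame | None = None) -> list[SensorStream]:
    day_dir = Path(day_dir)
    streams = []
    for placement in ("thigh", "upper_arm"):
        for side in ("left", "right"):
            path = day_dir / f"{placement}_{side}.csv"
            if not path.exists():
                raise FileNotFoundError(
                    f"missing sensor file for placement={placement} "
                    f"side={side} in {day_dir}")
            streams.append(read_sensor_csv(path, patient_id, placement, side))
    return streams
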