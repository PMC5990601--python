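"""Validation arithmetic against the manual stride reference.

Ships the published per-patient validation tables as machine-readable
fixtures (walking-detection truth tables; manual vs. algorithm movement
parameters) and implements the relative-error and group-average
computations used to validate the pipeline.  The same aggregation code
path applies to synthetic ground truth vs. pipeline output.
"""
from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

PARAMETERS = ("stride_duration", "cadence", "stride_count")
_PARAM_KEY = {"stride_duration": "dur", "cadence": "cad", "stride_count": "count"}
SIDES = ("aff", "nonaff")
GROUPS = ("all", "walker", "wheelchair")


def _fixture(name: str) -> pd.DataFrame:
    with resources.files("gaitconverge").joinpath("data", name).open() as fh:
        return pd.read_csv(fh)


def load_detection_table() -> pd.DataFrame:
    """Per-patient walking-detection truth-table percentages."""
    return _fixture("table2_detection.csv")


def load_parameter_table() -> pd.DataFrame:
    """Per-patient manual vs. algorithm movement parameters."""
    return _fixture("table3_parameters.csv")


def relative_error(manual: float, algorithm: float) -> float:
    """Signed relative error in %: (manual - algorithm) / manual * 100.

    Positive when the algorithm underestimates the manual reference.
    """
    if manual == 0:
        raise ValueError("manual reference value must be nonzero")
    return (manual - algorithm) / manual * 100.0


def _select_group(df: pd.DataFrame, group: str) -> pd.DataFrame:
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if group != "all":
        df = df[df["locomotion_type"] == group]
    if df.empty:
        raise ValueError(f"no records in group {group!r}")
    return df


def make_record(patient_id, locomotion_type: str, manual: dict,
                algorithm: dict) -> dict:
    """Build one validation record row from two parameter dicts.

    ``manual`` and ``algorithm`` map (parameter, side) — e.g.
    ``("cadence", "aff")`` — to values; sides are 'aff'/'nonaff'.
    """
    row = {"patient_id": patient_id, "locomotion_type": locomotion_type}
    for param in PARAMETERS:
        key = _PARAM_KEY[param]
        for side in SIDES:
            row[f"manual_{key}_{side}"] = manual[(param, side)]
            row[f"algo_{key}_{side}"] = algorithm[(param, side)]
    return row


def aggregate_validation(df: pd.DataFrame | None = None, group: str = "all",
                         ndigits: int = 2) -> pd.DataFrame:
    """Unweighted mean relative error per parameter and side, in %.

    Per-patient errors are recomputed from the manual/algorithm value pairs
    with :func:`relative_error` and reported to ``ndigits`` decimals.
    """
    if df is None:
        df = load_parameter_table()
    df = _select_group(df, group)
    rows = []
    for param in PARAMETERS:
        key = _PARAM_KEY[param]
        for side in SIDES:
            errors = [relative_error(m, a) for m, a in
                      zip(df[f"manual_{key}_{side}"], df[f"algo_{key}_{side}"])]
            rows.append({"parameter": param, "side": side,
                         "mean_relative_error": round(float(np.mean(errors)),
                                                      ndigits)})
    return pd.DataFrame(rows).set_index(["parameter", "side"])


def aggregate_detection(df: pd.DataFrame | None = None,
                        group: str = "all") -> dict[str, float]:
    """Unweighted group means of the per-patient detection percentages."""
    if df is None:
        df = load_detection_table()
    df = _select_group(df, group)
    return {k: float(df[k].mean())
            for k in ("tp", "tn", "fp", "fn", "sensitivity", "specificity")}


def side_gap(df: pd.DataFrame | None = None, source: str = "manual",
             parameter: str = "stride_count",
             emulate_paper_rounding: bool = True) -> float:
    """Absolute difference of the two sides' patient means.

    With ``emulate_paper_rounding`` the per-side means are rounded to two
    decimals before differencing, reproducing means computed from rounded
    published columns.
    """
    if source not in ("manual", "algo", "algorithm"):
        raise ValueError("source must be 'manual' or 'algorithm'")
    src = "algo" if source.startswith("algo") else "manual"
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}")
    if df is None:
        df = load_parameter_table()
    if df[["patient_id"]].isna().any().any():
        raise ValueError("missing records")
    key = _PARAM_KEY[parameter]
    m_aff = float(df[f"{src}_{key}_aff"].mean())
    m_non = float(df[f"{src}_{key}_nonaff"].mean())
    if emulate_paper_rounding:
        m_aff, m_non = round(m_aff, 2), round(m_non, 2)
    return abs(m_non - m_aff)
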