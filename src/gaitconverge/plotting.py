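"""Trend-line and convergence-point plots for one pipeline run."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def plot_trend_report(out_dir: str | Path) -> list[Path]:
    """Plot per-patient side trends with CP markers from a pipeline run.

    Reads daily_parameters.csv and trend_report.json from ``out_dir`` and
    writes one PNG per patient.  Returns the written paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    daily = pd.read_csv(out_dir / "daily_parameters.csv",
                        dtype={"patient_id": str})
    report = json.loads((out_dir / "trend_report.json").read_text())
    written = []
    for pid, params in report.items():
        pdf = daily[daily.patient_id == pid]
        names = [p for p, e in params.items() if e.get("trend")]
        if not names:
            continue
        fig, axes = plt.subplots(len(names), 1,
                                 figsize=(7, 2.2 * len(names)), sharex=True)
        axes = np.atleast_1d(axes)
        for ax, name in zip(axes, names):
            entry = params[name]
            for role, color in (("Aff", "tab:red"), ("NonAff", "tab:blue")):
                side = pdf[pdf.side == role]
                ax.plot(side.day, side[name], "o", ms=3, color=color,
                        label=role)
                tr = entry["trend"][role]
                xs = np.array([side.day.min(), side.day.max()], dtype=float)
                ax.plot(xs, tr["alpha"] + tr["beta"] * xs, "--", color=color)
            cp = entry["convergence_point"]
            if cp["t_cp"] is not None:
                ax.axvline(cp["t_cp"], color="k", ls=":", lw=1)
            ax.set_ylabel(name, fontsize=8)
            ax.legend(fontsize=7)
        axes[-1].set_xlabel("day since study begin")
        fig.suptitle(f"patient {pid}")
        fig.tight_layout()
        path = out_dir / f"trends_{pid}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    return written
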