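"""Plain-CSV readers and writers for tachograms, ECG traces and cohort tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import EctopyReport
from .series import ECGRecord, RRISeries

__all__ = [
    "write_rri_csv",
    "read_rri_csv",
    "write_ecg_csv",
    "read_ecg_csv",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_edit_report",
]


def write_rri_csv(rri: RRISeries, path) -> None:
    """Two-column tachogram CSV (beat_time_s, nn_ms) plus per-interval label.

    The final beat closes the last interval and has no label of its own.
    """
    df = pd.DataFrame({
        "beat_time_s": rri.beat_times,
        "nn_ms": np.append(rri.nn_ms, np.nan),
        "label": np.append(rri.labels, None),
    })
    df.to_csv(path, index=False)


def read_rri_csv(path) -> RRISeries:
    df = pd.read_csv(path)
    times = df["beat_time_s"].to_numpy(dtype=float)
    labels = df["label"].iloc[:-1].to_numpy() if "label" in df.columns else None
    return RRISeries.from_beat_times(times, labels=labels)


def write_ecg_csv(ecg: ECGRecord, path) -> None:
    pd.DataFrame({"time_s": ecg.times, "amplitude": ecg.samples}).to_csv(path, index=False)


def read_ecg_csv(path) -> ECGRecord:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("ECG CSV must be uniformly sampled")
    return ECGRecord(1.0 / dt[0], df["amplitude"].to_numpy(dtype=float), start_time=t[0])


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    from .series import TIMEPOINT_LABELS

    df = pd.read_csv(path)
    df["timepoint"] = pd.Categorical(df["timepoint"], categories=TIMEPOINT_LABELS,
                                     ordered=True)
    return df


def write_edit_report(report: EctopyReport, path) -> None:
    Path(path).write_text(json.dumps({
        "flagged_indices": report.flagged_indices.tolist(),
        "edit_fraction": report.edit_fraction,
        "n_intervals": report.n_intervals,
        "repair": report.repair,
        "rejected": report.rejected,
    }, indent=2))
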