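"""CSV readers/writers for the pipeline's intermediate products.

ECG: two-column CSV (time_s, mv).  Beats: (time_s, rr_ms, flag).
Tachogram: (t_s, rr_ms).  Cohort/echo/survival tables are plain pandas
CSV with a header row.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import BeatSeries, ECGRecord, Tachogram

__all__ = [
    "read_ecg_csv",
    "write_ecg_csv",
    "read_beats_csv",
    "write_beats_csv",
    "read_tachogram_csv",
    "write_tachogram_csv",
]


def write_ecg_csv(ecg: ECGRecord, path: str | Path) -> None:
    pd.DataFrame({"time_s": ecg.times, "mv": ecg.samples}).to_csv(
        path, index=False
    )


def read_ecg_csv(path: str | Path) -> ECGRecord:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    if t.size < 2 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("ECG CSV must be uniformly sampled")
    return ECGRecord(
        samples=df["mv"].to_numpy(),
        sampling_rate=1.0 / float(dt[0]),
        start_time=float(t[0]),
    )


def write_beats_csv(beats: BeatSeries, path: str | Path) -> None:
    rr = np.concatenate([[np.nan], beats.rr])
    pd.DataFrame(
        {"time_s": beats.r_times, "rr_ms": rr, "flag": beats.quality_flags}
    ).to_csv(path, index=False)


def read_beats_csv(path: str | Path) -> BeatSeries:
    df = pd.read_csv(path)
    return BeatSeries(
        r_times=df["time_s"].to_numpy(),
        quality_flags=[str(f) for f in df["flag"]],
    )


def write_tachogram_csv(t: Tachogram, path: str | Path) -> None:
    pd.DataFrame({"t_s": t.times, "rr_ms": t.values}).to_csv(path, index=False)


def read_tachogram_csv(path: str | Path, detrended: bool = False) -> Tachogram:
    df = pd.read_csv(path)
    ts = df["t_s"].to_numpy()
    dt = np.diff(ts)
    if ts.size < 2 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("tachogram CSV must be uniformly sampled")
    return Tachogram(
        values=df["rr_ms"].to_numpy(),
        sampling_rate=1.0 / float(dt[0]),
        detrended=detrended,
        origin_time=float(ts[0]),
    )
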