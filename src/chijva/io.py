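"""File round-trips: multi-page TIFF stacks, signal sidecars, cohort tables."""

from __future__ import annotations

from dataclasses import fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .cohort import ParticipantModel
from .optics import FrameStack, ReferenceSignals

__all__ = [
    "write_stack",
    "read_stack",
    "write_signals",
    "read_signals",
    "cohort_to_frame",
    "cohort_to_csv",
    "cohort_from_csv",
]


def write_stack(path, stack: FrameStack) -> None:
    """One TIFF page per frame, float64 so the round-trip is lossless."""
    tifffile.imwrite(
        path,
        stack.data.astype(np.float64),
        metadata={"fs": stack.fs, "illum_intensity": stack.illum_intensity},
    )


def read_stack(path, fs: float | None = None) -> FrameStack:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if fs is None:
        fs = float(meta.get("fs", 0.0))
    return FrameStack(data=data, fs=fs, illum_intensity=float(meta.get("illum_intensity", 1.0)))


def write_signals(path, signals: ReferenceSignals) -> None:
    """PPG samples and R-spike times in one CSV sidecar."""
    n = len(signals.ppg)
    t = np.arange(n) / signals.fs
    spikes = np.full(n, np.nan)
    spikes[: len(signals.r_spike_times)] = signals.r_spike_times
    pd.DataFrame({"time_s": t, "ppg": signals.ppg, "r_spike_time_s": spikes}).to_csv(path, index=False)


def read_signals(path) -> ReferenceSignals:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(float)
    fs = 1.0 / (t[1] - t[0]) if len(t) > 1 else 1.0
    return ReferenceSignals(
        ppg=df["ppg"].to_numpy(float),
        r_spike_times=df["r_spike_time_s"].dropna().to_numpy(float),
        fs=float(round(fs, 6)),
    )


def cohort_to_frame(cohort: list[ParticipantModel]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in cohort])


def cohort_to_csv(path, cohort: list[ParticipantModel]) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def cohort_from_csv(path) -> list[ParticipantModel]:
    df = pd.read_csv(path)
    names = [f.name for f in dc_fields(ParticipantModel)]
    return [
        ParticipantModel(**{n: (str(row[n]) if n in ("id", "sex") else float(row[n])) for n in names})
        for _, row in df.iterrows()
    ]
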