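"""Readers and writers for sample logs, trial tables and run reports.

Sample logs are tab-separated text files with columns
``time_ms  pupil_area  gaze_x  gaze_y  validity`` — the layout of a plain
eye-tracker sample report export — one file per participant-block, trials
concatenated on a common block clock. The trial-metadata CSV carries one row
per trial including ``onset_ms``, the stimulus-onset time of that trial on
the block clock (missing for trials without recorded samples).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .series import SampleSeries

__all__ = [
    "SAMPLE_COLUMNS",
    "write_samples",
    "read_samples",
    "write_trials",
    "read_trials",
    "sample_log_name",
    "write_manifest",
]

SAMPLE_COLUMNS = ["time_ms", "pupil_area", "gaze_x", "gaze_y", "validity"]

TRIAL_COLUMNS = [
    "participant_id",
    "block_index",
    "task",
    "trial_index",
    "stimulus_id",
    "normative_category",
    "target_present",
    "response",
    "detected",
    "onset_ms",
]


def sample_log_name(participant_id: int, block_index: int) -> str:
    return f"samples_p{participant_id:03d}_b{block_index}.tsv"


def write_samples(path, series: SampleSeries) -> None:
    """Write one series as a TSV sample log (6-decimal fixed point)."""
    n = len(series)
    df = pd.DataFrame(
        {
            "time_ms": series.time_ms,
            "pupil_area": series.pupil,
            "gaze_x": series.gaze_x if series.gaze_x is not None else np.zeros(n),
            "gaze_y": series.gaze_y if series.gaze_y is not None else np.zeros(n),
            "validity": series.validity.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_samples(path) -> SampleSeries:
    """Read a TSV sample log, validating schema and time monotonicity."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sample log not found: {path}")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    t = df["time_ms"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 2  # 1-based data row
        raise SchemaError(f"{path}: time_ms not strictly increasing at line {bad}")
    return SampleSeries(
        time_ms=t,
        pupil=df["pupil_area"].to_numpy(dtype=float),
        validity=df["validity"].to_numpy().astype(bool),
        gaze_x=df["gaze_x"].to_numpy(dtype=float),
        gaze_y=df["gaze_y"].to_numpy(dtype=float),
        units="area",
    )


def write_trials(path, trials: pd.DataFrame) -> None:
    df = trials.copy()
    for c in TRIAL_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    df[TRIAL_COLUMNS].to_csv(path, index=False, float_format="%.6f")


def read_trials(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trial table not found: {path}")
    df = pd.read_csv(path)
    required = [c for c in TRIAL_COLUMNS if c not in ("response", "detected", "onset_ms")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if "response" not in df.columns:
        df["response"] = None
    if "detected" not in df.columns:
        df["detected"] = np.nan
    if "onset_ms" not in df.columns:
        df["onset_ms"] = np.nan
    df["target_present"] = df["target_present"].astype(bool)
    return df


def write_manifest(path, payload: dict) -> None:
    """Deterministic JSON manifest (sorted keys, stable float formatting)."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        return str(o)

    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=default))
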