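"""Outcome measures: the pupil-dilation gradient, time courses, behavioural rates.

The primary physiological index is the *dilation gradient* — the slope of the
baseline-corrected pupil diameter between an early-window extremum and the
1–2 s maximum:

* picture (visual) mode: from the **minimum** in 0–1,000 ms (light-reflex
  trough) to the **maximum** in 1,000–2,000 ms;
* sound (auditory) mode: from the **maximum** in 0–1,000 ms to the maximum in
  1,000–2,000 ms (no light reflex, the pupil dilates from onset).

The gradient is reported as diameter units per second; a raw-difference
variant (no time denominator) is available since the two differ only by the
extremum-time span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import Epoch

__all__ = [
    "GradientValue",
    "gradient",
    "condition_table",
    "grand_average_timecourse",
    "match_rate",
    "detection_rate",
]

MODES = ("visual_minmax", "auditory_maxmax")


@dataclass
class GradientValue:
    """Dilation-gradient summary of one epoch."""

    value: float  # diameter units / s (or raw difference, see ``per_second``)
    t_start_ms: float
    t_end_ms: float
    d_start: float
    d_end: float
    mode: str
    per_second: bool = True


def _extremum(t: np.ndarray, x: np.ndarray, kind: str) -> tuple[float, float]:
    """Earliest-time extremum of x over the (already masked) window."""
    if kind == "min":
        i = int(np.nanargmin(x))
    else:
        i = int(np.nanargmax(x))
    return float(t[i]), float(x[i])


def gradient(
    epoch: Epoch,
    mode: str,
    early_window: tuple = (0.0, 1000.0),
    late_window: tuple = (1000.0, 2000.0),
    per_second: bool = True,
) -> GradientValue:
    """Dilation gradient of a corrected epoch.

    Both search windows are closed intervals (the 1,000 ms boundary sample
    belongs to both); extremum ties break toward the earliest time. A
    degenerate same-sample pair yields value 0 with a warning rather than a
    division by zero.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    t, x = epoch.rel_time_ms, epoch.corrected
    m1 = epoch.window(*early_window)
    m2 = epoch.window(*late_window)
    if not m1.any() or not m2.any():
        raise ValueError("epoch does not cover the gradient windows")
    kind1 = "min" if mode == "visual_minmax" else "max"
    t1, d1 = _extremum(t[m1], x[m1], kind1)
    t2, d2 = _extremum(t[m2], x[m2], "max")
    if t2 == t1:
        warnings.warn("gradient extrema coincide at the window boundary; value set to 0")
        value = 0.0
    elif per_second:
        value = (d2 - d1) / ((t2 - t1) / 1000.0)
    else:
        value = d2 - d1
    return GradientValue(value, t1, t2, d1, d2, mode, per_second)


def condition_table(trial_results: pd.DataFrame) -> pd.DataFrame:
    """Participant × condition × task mean gradients, the ANOVA input.

    ``trial_results`` needs columns participant_id, assigned_condition, task,
    gradient — one row per analyzable trial. Returns a tidy frame with one
    row per (participant, condition, task) cell mean; empty input yields an
    empty frame, empty cells are simply absent (participants with missing
    cells are flagged by the inference layer).
    """
    cols = ["participant_id", "assigned_condition", "task", "gradient"]
    if trial_results.empty:
        return pd.DataFrame(columns=cols)
    table = (
        trial_results.groupby(
            ["participant_id", "assigned_condition", "task"], observed=True
        )["gradient"]
        .mean()
        .reset_index()
    )
    return table[cols]


def grand_average_timecourse(
    epochs: list[Epoch],
    labels: list[str],
    participants: list,
    t_max_ms: float = 5800.0,
) -> pd.DataFrame:
    """Grand-average corrected time course per condition over 0..``t_max_ms``.

    Averages within participant first, then across participants, on the
    common 20 ms grid (291 points for 0–5,800 ms). All epochs must share the
    grid; returns a tidy frame (condition, rel_time_ms, mean).
    """
    if not epochs:
        return pd.DataFrame(columns=["condition", "rel_time_ms", "mean"])
    ref = epochs[0].rel_time_ms
    for e in epochs[1:]:
        if len(e.rel_time_ms) != len(ref) or np.any(np.abs(e.rel_time_ms - ref) > 1e-6):
            raise ValueError("epochs are not aligned on a common time grid")
    keep = (ref >= -1e-9) & (ref <= t_max_ms + 1e-9)
    grid = ref[keep]
    df = pd.DataFrame(
        {
            "condition": labels,
            "participant": participants,
            "trace": [e.corrected[keep] for e in epochs],
        }
    )
    rows = []
    for cond, sub in df.groupby("condition", observed=True):
        per_subject = sub.groupby("participant", observed=True)["trace"].apply(
            lambda s: np.mean(np.stack(s.to_numpy()), axis=0)
        )
        mean = np.mean(np.stack(per_subject.to_numpy()), axis=0)
        rows.append(pd.DataFrame({"condition": cond, "rel_time_ms": grid, "mean": mean}))
    return pd.concat(rows, ignore_index=True)


def match_rate(responses: pd.DataFrame) -> pd.DataFrame:
    """Emotional-task agreement with normative valence, per participant ×
    category: (# responses equal to the normative category) / (# stimuli of
    that category). Categories with no stimuli are reported as missing."""
    emo = responses.loc[responses["task"] == "emotional"]
    rows = []
    for (pid, cat), sub in emo.groupby(
        ["participant_id", "normative_category"], observed=True
    ):
        n = len(sub)
        rate = float((sub["response"] == cat).sum()) / n if n else np.nan
        rows.append((pid, cat, rate, n))
    return pd.DataFrame(rows, columns=["participant_id", "category", "rate", "n_stimuli"])


def detection_rate(responses: pd.DataFrame) -> pd.DataFrame:
    """Target hit rate per participant × detection task: hits / target trials."""
    det = responses.loc[
        responses["task"].isin(["visual_detect", "auditory_detect"])
        & responses["target_present"].astype(bool)
    ]
    rows = []
    for (pid, task), sub in det.groupby(["participant_id", "task"], observed=True):
        n = len(sub)
        rate = float(np.nansum(sub["detected"].to_numpy())) / n if n else np.nan
        rows.append((pid, task, rate, n))
    return pd.DataFrame(rows, columns=["participant_id", "task", "rate", "n_targets"])
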