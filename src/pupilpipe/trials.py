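"""Trial bookkeeping between preprocessing and statistics.

Covers the design-specific accounting rules of the four-block paradigm:
target-containing detection trials never enter pupillary analyses; every
trial of a stimulus is assigned the emotion condition the participant
*reported* for that stimulus in the emotional block (subjective rather than
normative valence); participants lose their data when artifact rejection
wipes out a whole emotion condition or more than 75% of a task's analyzable
trials.

All operations act on tidy pandas DataFrames with one row per trial
(columns as produced by :mod:`pupilpipe.synthetic` / the sample-log readers).
"""

from __future__ import annotations

import warnings

import pandas as pd

from .exceptions import ConfigurationError

__all__ = [
    "drop_target_trials",
    "classify_by_response",
    "condition_counts",
    "exclude_participants",
    "check_count_range",
]

CONDITIONS = ("positive", "negative", "neutral")


def drop_target_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Remove detection-target trials (idempotent). Under the standard
    schedule each 75-trial detection block retains 60 analyzable trials."""
    if "target_present" not in trials.columns or trials.empty:
        return trials.copy()
    return trials.loc[~trials["target_present"].astype(bool)].copy()


def classify_by_response(trials: pd.DataFrame) -> pd.DataFrame:
    """Label every trial with the emotion condition its participant reported
    for that stimulus in the emotional block.

    Adds an ``assigned_condition`` column: the emotional-block ``response``
    of the same (participant, stimulus) pair, for all four blocks. Stimuli
    with no usable emotional response (timeout / missing) are labelled
    ``"unclassified"`` and must be dropped from pupillary analyses.
    """
    out = trials.copy()
    if out.empty:
        out["assigned_condition"] = pd.Series(dtype=object)
        return out
    emo = out.loc[out["task"] == "emotional"]
    missing = set(out["participant_id"].unique()) - set(emo["participant_id"].unique())
    if missing:
        raise ConfigurationError(
            f"participants without an emotional block: {sorted(missing)}"
        )
    key = pd.MultiIndex.from_frame(emo[["participant_id", "stimulus_id"]])
    mapping = pd.Series(emo["response"].to_numpy(), index=key)
    # one emotional presentation per stimulus; keep the first if duplicated
    mapping = mapping[~mapping.index.duplicated()]
    lookup = pd.MultiIndex.from_frame(out[["participant_id", "stimulus_id"]])
    assigned = mapping.reindex(lookup).to_numpy(dtype=object)
    assigned = [
        a if a in CONDITIONS else "unclassified" for a in assigned
    ]
    out["assigned_condition"] = assigned
    return out


def condition_counts(trials: pd.DataFrame, analyzable: pd.Series | None = None) -> pd.DataFrame:
    """Per-participant analyzable trial counts by assigned condition and task.

    ``analyzable`` is an optional boolean mask (aligned with ``trials``);
    by default every non-target, classified trial counts.
    """
    df = trials
    mask = ~df["target_present"].astype(bool) & df["assigned_condition"].isin(CONDITIONS)
    if analyzable is not None:
        mask &= analyzable.astype(bool)
    kept = df.loc[mask]
    counts = (
        kept.groupby(["participant_id", "assigned_condition", "task"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    return counts


def check_count_range(
    counts: pd.DataFrame, low: int = 10, high: int = 40
) -> pd.DataFrame:
    """Soft sanity check on per-condition trial counts within each task block.

    Under subjective-response classification each emotion condition is
    expected to hold a moderate share of a block's ≤ 60 analyzable trials
    (10–40 before artifact removal, 9–39 after, under the standard design);
    cells outside [low, high] get a warning, never an error — skewed
    responders legitimately break the band. Returns the per-participant ×
    condition × task counts it examined.
    """
    bad = counts.loc[(counts["n"] < low) | (counts["n"] > high)]
    if len(bad):
        warnings.warn(
            f"{len(bad)} participant × condition × task counts outside [{low}, {high}]"
        )
    return counts.copy()


def exclude_participants(
    counts_after: pd.DataFrame,
    rejected_per_task: pd.DataFrame | None = None,
    task_total: int = 60,
    task_reject_fraction: float = 0.75,
) -> pd.DataFrame:
    """Participant-level exclusion after artifact rejection.

    A participant is excluded iff

    a. some assigned emotion condition retains 0 analyzable trials, or
    b. some task condition lost strictly more than ``task_reject_fraction``
       of its ``task_total`` analyzable trials (i.e. > 45 of 60 by default).

    ``counts_after`` is the output of :func:`condition_counts` on
    artifact-surviving trials; ``rejected_per_task`` has columns
    participant_id, task, n_rejected.

    Returns one row per participant: participant_id, excluded, reason.
    """
    rows = []
    participants = sorted(counts_after["participant_id"].unique())
    cutoff = task_reject_fraction * task_total
    for pid in participants:
        sub = counts_after.loc[counts_after["participant_id"] == pid]
        by_cond = sub.groupby("assigned_condition", observed=True)["n"].sum()
        reason = ""
        empty = [c for c in CONDITIONS if by_cond.get(c, 0) == 0]
        if empty:
            reason = f"no analyzable trials in condition(s): {', '.join(empty)}"
        elif rejected_per_task is not None:
            rej = rejected_per_task.loc[rejected_per_task["participant_id"] == pid]
            over = rej.loc[rej["n_rejected"] > cutoff, "task"]
            if len(over):
                reason = (
                    f"more than {task_reject_fraction:.0%} of task(s) rejected: "
                    f"{', '.join(over)}"
                )
        rows.append((pid, bool(reason), reason))
    return pd.DataFrame(rows, columns=["participant_id", "excluded", "reason"])
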