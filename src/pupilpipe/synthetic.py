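"""Synthetic event-related pupillometry sessions with known ground truth.

Emulates a four-block within-subject design: on each trial a fixation point
(1,000 ms) precedes an emotional stimulus (6,000 ms) while pupil area is
recorded at 500 Hz. Blocks differ only in task — explicit emotional evaluation,
passive viewing ("no task"), visual target detection, or auditory target
detection. Stimuli come in three normative valence categories (positive /
negative / neutral, 20 each of 60). Detection blocks carry 75 trials of which
20% contain a target, so the 60 analyzable non-target trials match the other
blocks.

The generated pupil signal is a sum of interpretable components on a device
area scale (diameter²-proportional units):

``area(t) = baseline + subject offset + light-reflex kernel (visual mode)
            + gain · dilation kernel + Gaussian noise``

where the dilation gain is ``arousal_gain[valence] × task_attention_gain[task]``
modulated by subject- and trial-level lognormal variability. Visual-mode traces
therefore constrict after onset (pupillary light reflex) and re-dilate;
auditory-mode traces dilate from onset. Blinks are injected as zero-valued,
invalid stretches. Every random quantity is drawn from deterministic
substreams of one master seed, so any single trial is reproducible in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, GenerationError
from .series import SampleSeries

__all__ = [
    "TASKS",
    "CATEGORIES",
    "SimConfig",
    "visual_study_config",
    "auditory_study_config",
    "make_schedule",
    "simulate_trace",
    "inject_blinks",
    "simulate_responses",
    "simulate_session",
]

#: Task conditions, one per block.
TASKS = ("emotional", "none", "visual_detect", "auditory_detect")
#: Normative valence categories.
CATEGORIES = ("positive", "negative", "neutral")
#: Tasks whose blocks contain detection targets.
DETECTION_TASKS = ("visual_detect", "auditory_detect")

# Balanced 4x4 Latin square used to counterbalance task order across subjects.
_LATIN_SQUARE = ((0, 1, 2, 3), (1, 0, 3, 2), (2, 3, 0, 1), (3, 2, 1, 0))

# Substream tags keeping schedule / subject / trial / blink draws independent.
_TAG_SCHEDULE, _TAG_SUBJECT, _TAG_TRACE, _TAG_BLINK, _TAG_RESPONSE = range(5)


def _default_arousal_gain() -> dict:
    # Emotional (positive/negative) stimuli drive a stronger dilation than
    # neutral ones; magnitudes are on the EyeLink arbitrary-area scale.
    return {"positive": 120.0, "negative": 120.0, "neutral": 50.0}


def _default_task_gain() -> dict:
    return {t: 1.0 for t in TASKS}


def _default_confusion() -> np.ndarray:
    # Mostly-veridical emotional judgments with some cross-category confusion.
    return np.array(
        [
            [0.80, 0.10, 0.10],
            [0.10, 0.80, 0.10],
            [0.10, 0.10, 0.80],
        ]
    )


@dataclass(frozen=True)
class SimConfig:
    """All generative parameters of a synthetic session.

    Durations are milliseconds, pupil amplitudes are device area units
    (diameter²-proportional), rates are events/minute or Hz as named.
    """

    n_participants: int = 24
    modality: str = "visual"  # "visual" (pictures) or "auditory" (sounds)
    sampling_rate: float = 500.0
    fixation_ms: float = 1000.0
    stimulus_ms: float = 6000.0
    n_stimuli: int = 60
    detection_trials: int = 75
    target_fraction: float = 0.20
    # signal model
    baseline_level: float = 1500.0
    reflex_amplitude: float = 300.0
    reflex_latency_ms: float = 250.0
    reflex_constriction_ms: float = 350.0
    reflex_recovery_tau_ms: float = 1200.0
    arousal_gain: Mapping[str, float] = field(default_factory=_default_arousal_gain)
    task_attention_gain: Mapping[str, float] = field(default_factory=_default_task_gain)
    dilation_peak_ms: float = 1300.0
    dilation_tau_ms: float = 800.0
    # variability
    noise_sd: float = 15.0
    participant_sd: float = 100.0
    participant_gain_sd: float = 0.20  # lognormal sigma on the dilation gain
    trial_gain_sd: float = 0.30  # lognormal sigma, trial-to-trial
    # artifacts
    blink_rate: float = 15.0  # events per minute
    blink_duration_ms_range: tuple = (100.0, 300.0)
    # behaviour
    response_confusion: np.ndarray = field(default_factory=_default_confusion)
    timeout_rate: float = 0.0
    detection_hit_rate: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality not in ("visual", "auditory"):
            raise ConfigurationError(f"unknown modality {self.modality!r}")
        if self.n_participants < 0:
            raise ConfigurationError("n_participants must be >= 0")
        for name in (
            "sampling_rate",
            "fixation_ms",
            "stimulus_ms",
            "reflex_latency_ms",
            "reflex_constriction_ms",
            "reflex_recovery_tau_ms",
            "dilation_peak_ms",
            "dilation_tau_ms",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.n_stimuli % len(CATEGORIES):
            raise ConfigurationError(
                f"n_stimuli={self.n_stimuli} cannot split evenly over "
                f"{len(CATEGORIES)} valence categories"
            )
        n_targets = self.detection_trials * self.target_fraction
        if abs(n_targets - round(n_targets)) > 1e-9:
            raise ConfigurationError(
                "detection_trials × target_fraction must be an integer"
            )
        for mapping, name in (
            (self.arousal_gain, "arousal_gain"),
            (self.task_attention_gain, "task_attention_gain"),
        ):
            if any(v < 0 for v in mapping.values()):
                raise ConfigurationError(f"{name} entries must be non-negative")
        conf = np.asarray(self.response_confusion, dtype=float)
        if conf.shape != (3, 3) or np.any(conf < 0):
            raise ConfigurationError("response_confusion must be a non-negative 3×3 matrix")
        if np.any(np.abs(conf.sum(axis=1) - 1.0) > 1e-12):
            raise ConfigurationError("response_confusion rows must sum to 1")
        n_samp = self.sampling_rate * self.stimulus_ms / 1000.0
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ConfigurationError(
                "sampling_rate × stimulus_ms must give an integer sample count"
            )

    # -- deterministic substreams ------------------------------------------
    def _rng(self, *key: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=key))

    def schedule_rng(self) -> np.random.Generator:
        return self._rng(_TAG_SCHEDULE)

    def participant_rng(self, participant_id: int) -> np.random.Generator:
        return self._rng(_TAG_SUBJECT, participant_id)

    def trial_rng(self, participant_id: int, block_index: int, trial_index: int) -> np.random.Generator:
        return self._rng(_TAG_TRACE, participant_id, block_index, trial_index)

    def blink_rng(self, participant_id: int, block_index: int, trial_index: int) -> np.random.Generator:
        return self._rng(_TAG_BLINK, participant_id, block_index, trial_index)

    def response_rng(self) -> np.random.Generator:
        return self._rng(_TAG_RESPONSE)

    @property
    def n_targets(self) -> int:
        return int(round(self.detection_trials * self.target_fraction))

    @property
    def trial_span_ms(self) -> float:
        return self.fixation_ms + self.stimulus_ms

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def visual_study_config(seed: int = 0, **overrides) -> SimConfig:
    """Picture-modality session: light reflex present, arousal effect in every task."""
    return SimConfig(modality="visual", seed=seed, **overrides)


def auditory_study_config(seed: int = 0, **overrides) -> SimConfig:
    """Sound-modality session: no light reflex; the arousal effect is gated by
    attention to the auditory stream (present only under the emotional and
    auditory-detection tasks), which injects a valence × task interaction."""
    overrides.setdefault(
        "task_attention_gain",
        {"emotional": 1.0, "none": 0.0, "visual_detect": 0.0, "auditory_detect": 1.0},
    )
    return SimConfig(modality="auditory", seed=seed, **overrides)


def stimulus_category(stimulus_id: int, n_stimuli: int = 60) -> str:
    """Normative valence of a stimulus id (1-based; contiguous 20/20/20 split)."""
    per = n_stimuli // len(CATEGORIES)
    return CATEGORIES[(stimulus_id - 1) // per]


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

def make_schedule(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Build the per-trial plan for all participants.

    Each participant runs 4 blocks (task order counterbalanced via a balanced
    Latin square). Emotional and no-task blocks present each of the 60 stimuli
    exactly once in random order. Detection blocks hold 75 trials — the 60
    stimuli once each plus 15 repeats — with targets assigned to 15 uniformly
    random trials.

    Returns a DataFrame with columns participant_id, block_index, task,
    trial_index, stimulus_id, normative_category, target_present.
    """
    if rng is None:
        rng = config.schedule_rng()
    rows: list[tuple] = []
    stim_ids = np.arange(1, config.n_stimuli + 1)
    for pid in range(1, config.n_participants + 1):
        order = _LATIN_SQUARE[(pid - 1) % 4]
        for block_index, task_i in enumerate(order, start=1):
            task = TASKS[task_i]
            if task in DETECTION_TASKS:
                extra = rng.choice(
                    stim_ids, size=config.detection_trials - config.n_stimuli, replace=False
                )
                stims = np.concatenate([stim_ids, extra])
                rng.shuffle(stims)
                targets = np.zeros(config.detection_trials, dtype=bool)
                targets[rng.choice(config.detection_trials, size=config.n_targets, replace=False)] = True
            else:
                stims = rng.permutation(stim_ids)
                targets = np.zeros(config.n_stimuli, dtype=bool)
            for trial_index, (sid, tgt) in enumerate(zip(stims, targets), start=1):
                rows.append(
                    (
                        pid,
                        block_index,
                        task,
                        trial_index,
                        int(sid),
                        stimulus_category(int(sid), config.n_stimuli),
                        bool(tgt),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "block_index",
            "task",
            "trial_index",
            "stimulus_id",
            "normative_category",
            "target_present",
        ],
    )


# ---------------------------------------------------------------------------
# signal kernels
# ---------------------------------------------------------------------------

def _gamma_bump(t_ms: np.ndarray, peak_ms: float, tau_ms: float) -> np.ndarray:
    """Gamma-shaped unit bump: 0 for t<=0, peak 1 at ``peak_ms``, late decay
    time-constant ``tau_ms`` (shape exponent k = peak/tau)."""
    k = peak_ms / tau_ms
    out = np.zeros_like(t_ms, dtype=float)
    pos = t_ms > 0
    x = t_ms[pos] / peak_ms
    out[pos] = x**k * np.exp(k * (1.0 - x))
    return out


def dilation_kernel(t_ms: np.ndarray, config: SimConfig) -> np.ndarray:
    """Event-related dilation kernel (unit peak, peak near ``dilation_peak_ms``)."""
    return _gamma_bump(t_ms, config.dilation_peak_ms, config.dilation_tau_ms)


def reflex_kernel(t_ms: np.ndarray, config: SimConfig) -> np.ndarray:
    """Pupillary light reflex: onset-latency constriction reaching
    ``-reflex_amplitude`` at latency + constriction time, recovering with
    ``reflex_recovery_tau_ms``. Zero in auditory mode (no luminance change)."""
    return -config.reflex_amplitude * _gamma_bump(
        t_ms - config.reflex_latency_ms,
        config.reflex_constriction_ms,
        config.reflex_recovery_tau_ms,
    )


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def _participant_effects(config: SimConfig, participant_id: int) -> tuple[float, float]:
    rng = config.participant_rng(participant_id)
    offset = rng.normal(0.0, config.participant_sd)
    gain = float(np.exp(rng.normal(0.0, config.participant_gain_sd)))
    return offset, gain


def simulate_trace(
    plan: Mapping,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> SampleSeries:
    """Generate the raw 500 Hz pupil-area series for one trial.

    ``plan`` is one schedule row (mapping with participant_id, block_index,
    task, trial_index, normative_category). The series spans fixation onset
    (−fixation_ms) to stimulus offset (+stimulus_ms), stimulus onset at 0 ms.
    """
    task = plan["task"]
    category = plan["normative_category"]
    if task not in TASKS:
        raise ConfigurationError(f"unknown task {task!r}")
    if category not in CATEGORIES:
        raise ConfigurationError(f"unknown category {category!r}")
    if rng is None:
        rng = config.trial_rng(
            plan["participant_id"], plan["block_index"], plan["trial_index"]
        )

    step = 1000.0 / config.sampling_rate
    n = int(round(config.trial_span_ms / step))
    t = -config.fixation_ms + np.arange(n) * step

    offset, subj_gain = _participant_effects(config, plan["participant_id"])
    trial_gain = float(np.exp(rng.normal(0.0, config.trial_gain_sd))) if config.trial_gain_sd else 1.0
    gain = (
        config.arousal_gain[category]
        * config.task_attention_gain[task]
        * subj_gain
        * trial_gain
    )

    area = np.full(n, config.baseline_level + offset)
    if config.modality == "visual":
        area += reflex_kernel(t, config)
    area += gain * dilation_kernel(t, config)
    if config.noise_sd:
        area += rng.normal(0.0, config.noise_sd, size=n)
    if np.min(area) <= 0:
        raise GenerationError(
            "generated pupil area is non-positive; baseline_level too small "
            "relative to reflex amplitude / offsets / noise"
        )

    gaze_x = 512.0 + rng.normal(0.0, 5.0, size=n)
    gaze_y = 384.0 + rng.normal(0.0, 5.0, size=n)
    return SampleSeries(
        time_ms=t,
        pupil=area,
        gaze_x=gaze_x,
        gaze_y=gaze_y,
        units="area",
        meta={
            "participant_id": plan["participant_id"],
            "block_index": plan["block_index"],
            "trial_index": plan["trial_index"],
            "task": task,
            "normative_category": category,
        },
    )


def inject_blinks(
    series: SampleSeries, config: SimConfig, rng: np.random.Generator
) -> SampleSeries:
    """Overlay blink data loss: a Poisson process at ``blink_rate`` events/min,
    each event zeroing the pupil and clearing validity for a duration uniform
    in ``blink_duration_ms_range``. Overlapping events are merged."""
    out = series.copy()
    out.meta["blink_events"] = 0
    if config.blink_rate <= 0:
        return out
    span_min = (series.time_ms[-1] - series.time_ms[0]) / 60000.0
    n_events = int(rng.poisson(config.blink_rate * span_min))
    out.meta["blink_events"] = n_events
    if n_events == 0:
        return out
    t0, t1 = series.time_ms[0], series.time_ms[-1]
    starts = np.sort(rng.uniform(t0, t1, size=n_events))
    durs = rng.uniform(*config.blink_duration_ms_range, size=n_events)
    for s, d in zip(starts, durs):
        mask = (out.time_ms >= s) & (out.time_ms < s + d)
        out.pupil[mask] = 0.0
        out.validity[mask] = False
    return out


# ---------------------------------------------------------------------------
# responses
# ---------------------------------------------------------------------------

def simulate_responses(
    schedule: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Attach behavioural responses to a schedule.

    Emotional-block trials get a reported valence drawn from the row of
    ``response_confusion`` for the stimulus' normative category (or ``"none"``
    with probability ``timeout_rate``). Detection-block target trials get a
    hit with probability ``detection_hit_rate``. Other cells are missing.
    """
    if not (schedule["task"] == "emotional").any() and len(schedule):
        raise ConfigurationError("schedule contains no emotional block")
    if rng is None:
        rng = config.response_rng()
    conf = np.asarray(config.response_confusion, dtype=float)

    out = schedule.copy()
    response = np.full(len(out), None, dtype=object)
    detected = np.full(len(out), np.nan)

    cat_index = {c: i for i, c in enumerate(CATEGORIES)}
    emo = out["task"] == "emotional"
    for i in np.flatnonzero(emo.to_numpy()):
        if config.timeout_rate and rng.random() < config.timeout_rate:
            response[i] = "none"
        else:
            row = conf[cat_index[out["normative_category"].iat[i]]]
            response[i] = CATEGORIES[rng.choice(3, p=row)]

    tgt = out["target_present"].to_numpy() & out["task"].isin(DETECTION_TASKS).to_numpy()
    detected[tgt] = (rng.random(int(tgt.sum())) < config.detection_hit_rate).astype(float)

    out["response"] = response
    out["detected"] = detected
    return out


def simulate_session(config: SimConfig) -> pd.DataFrame:
    """Convenience: schedule + responses for a full multi-participant session."""
    schedule = make_schedule(config)
    return simulate_responses(schedule, config)
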