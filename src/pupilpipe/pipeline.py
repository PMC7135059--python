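"""End-to-end orchestration: samples → epochs → trials → gradients → inference.

`run_pipeline` executes the full analysis in the documented order —

    blink repair → artifact flagging (velocity peak, PCA outliers) →
    50 Hz downsampling + smoothing → area→diameter conversion →
    epoching + baseline correction → target-trial removal →
    response-based emotion classification → participant exclusion →
    dilation gradients → condition table → repeated-measures ANOVA +
    pairwise corrections + Bayes factors → behavioural checks

— on either an in-memory synthetic session (a :class:`SimConfig`) or a
directory of sample logs + a trial table. Two runs with the same config and
seed produce identical outputs; the manifest written alongside the result
CSVs suffices to re-run the analysis.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ppio
from . import metrics, stats, synthetic, trials as trials_mod
from .exceptions import ConfigurationError, InsufficientDataError
from .preprocess import Epoch, preprocess_trace, reject_pca
from .series import SampleSeries
from .synthetic import SimConfig

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "write_session", "anova_frame"]

log = logging.getLogger("pupilpipe")

ANALYSIS_FLAGS = ("uninterpolable", "velocity_peak", "pca_outlier")


@dataclass
class RunConfig:
    """Everything one analysis run depends on."""

    sim: SimConfig | None = None
    input_dir: str | Path | None = None
    modality: str | None = None
    # preprocessing thresholds
    diameter_scale: float = 1.0
    blink_vel_threshold: float | None = None
    blink_margin_ms: float = 50.0
    blink_merge_gap_ms: float = 100.0
    epoch_vel_threshold: float = 0.8
    pca_components: int = 3
    pca_z_threshold: float = 3.5
    # outcome + inference options
    gradient_per_second: bool = True
    correction_method: str = "msrb_shaffer"
    gg: str | bool = "auto"
    alpha: float = 0.05
    out_dir: str | Path | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.input_dir is None):
            raise ConfigurationError("provide exactly one of sim= or input_dir=")
        if self.modality is None:
            if self.sim is not None:
                self.modality = self.sim.modality
            else:
                raise ConfigurationError("modality required when reading from files")
        if self.modality not in ("visual", "auditory"):
            raise ConfigurationError(f"unknown modality {self.modality!r}")

    @property
    def gradient_mode(self) -> str:
        return "visual_minmax" if self.modality == "visual" else "auditory_maxmax"

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"]["response_confusion"] = np.asarray(
                self.sim.response_confusion
            ).tolist()
            d["sim"]["arousal_gain"] = dict(self.sim.arousal_gain)
            d["sim"]["task_attention_gain"] = dict(self.sim.task_attention_gain)
        return d


@dataclass
class PipelineResult:
    trials: pd.DataFrame
    condition_table: pd.DataFrame
    anova: pd.DataFrame
    pairwise: pd.DataFrame
    exclusions: pd.DataFrame
    grand_average: pd.DataFrame
    behavioral: dict
    accounting: dict
    manifest: dict
    epochs: dict = field(default_factory=dict, repr=False)


# ---------------------------------------------------------------------------
# trace access
# ---------------------------------------------------------------------------

def _sim_traces(trials_df: pd.DataFrame, sim: SimConfig):
    """Yield (row_index, SampleSeries) for every non-target trial."""
    for idx, row in trials_df.iterrows():
        if row["target_present"]:
            continue
        rng = sim.trial_rng(row["participant_id"], row["block_index"], row["trial_index"])
        series = synthetic.simulate_trace(row, sim, rng)
        series = synthetic.inject_blinks(
            series,
            sim,
            sim.blink_rng(row["participant_id"], row["block_index"], row["trial_index"]),
        )
        yield idx, series, 0.0


def _file_traces(trials_df: pd.DataFrame, input_dir: Path, pre_ms: float = 1000.0, post_ms: float = 6000.0):
    cache: dict[tuple, SampleSeries] = {}
    for idx, row in trials_df.iterrows():
        if row["target_present"] or pd.isna(row.get("onset_ms", np.nan)):
            continue
        key = (row["participant_id"], row["block_index"])
        if key not in cache:
            cache.clear()  # one block in memory at a time
            cache[key] = ppio.read_samples(
                input_dir / ppio.sample_log_name(int(key[0]), int(key[1]))
            )
        block = cache[key]
        onset = float(row["onset_ms"])
        i0 = block.index_at(onset - pre_ms)
        i1 = block.index_at(onset + post_ms - block.step_ms)
        series = SampleSeries(
            time_ms=block.time_ms[i0 : i1 + 1],
            pupil=block.pupil[i0 : i1 + 1].copy(),
            validity=block.validity[i0 : i1 + 1].copy(),
            gaze_x=None if block.gaze_x is None else block.gaze_x[i0 : i1 + 1],
            gaze_y=None if block.gaze_y is None else block.gaze_y[i0 : i1 + 1],
            units="area",
        )
        yield idx, series, onset


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def anova_frame(results) -> pd.DataFrame:
    rows = [
        (
            r.effect,
            r.F,
            r.df1,
            r.df2,
            r.p,
            r.partial_eta2,
            r.gg_epsilon,
            r.gg_applied,
            r.bf10,
        )
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["effect", "F", "df1", "df2", "p", "partial_eta2", "gg_epsilon", "gg_applied", "bf10"],
    )


def _pairwise_frame(table: pd.DataFrame, factor: str, method: str, alpha: float) -> pd.DataFrame:
    """Pairwise paired t-tests on participant marginal means of one factor,
    with the configured sequentially rejective correction."""
    marg = (
        table.groupby(["participant_id", factor], observed=True)["gradient"]
        .mean()
        .unstack(factor)
    )
    levels = list(marg.columns)
    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]]
    ps, labels = [], []
    for a, b in pairs:
        t, df, p = stats.paired_t(marg[a], marg[b])
        ps.append(p)
        labels.append(f"{a} vs {b}")
    if not ps:
        return pd.DataFrame(columns=["factor", "contrast", "p", "threshold", "rejected", "method"])
    kwargs = {"n_means": len(levels)} if method == "msrb_shaffer" else {}
    res = stats.pairwise_correct(ps, method=method, alpha=alpha, labels=labels, **kwargs)
    return pd.DataFrame(
        [(factor, r.label, r.p, r.threshold, r.rejected, r.method) for r in res],
        columns=["factor", "contrast", "p", "threshold", "rejected", "method"],
    )


def _behavioral_block(trials_df: pd.DataFrame, alpha: float) -> dict:
    out: dict = {}
    mr = metrics.match_rate(trials_df)
    out["match_rates"] = mr
    if len(mr) and mr["participant_id"].nunique() >= 2:
        res = stats.rm_anova(
            mr, dv="rate", within=["category"], subject="participant_id"
        )
        out["match_anova"] = anova_frame(res)
        marg = mr.pivot_table(index="participant_id", columns="category", values="rate")
        cats = list(marg.columns)
        ps, labels = [], []
        for i, a in enumerate(cats):
            for b in cats[i + 1 :]:
                _, _, p = stats.paired_t(marg[a], marg[b])
                ps.append(p)
                labels.append(f"{a} vs {b}")
        pw = stats.pairwise_correct(ps, method="bonferroni", alpha=alpha, labels=labels)
        out["match_pairwise"] = pd.DataFrame(
            [(r.label, r.p, r.threshold, r.rejected, r.method) for r in pw],
            columns=["contrast", "p", "threshold", "rejected", "method"],
        )
    dr = metrics.detection_rate(trials_df)
    out["detection_rates"] = dr
    wide = dr.pivot_table(index="participant_id", columns="task", values="rate")
    if {"visual_detect", "auditory_detect"} <= set(wide.columns) and len(wide.dropna()) >= 2:
        w = wide.dropna()
        t, df, p = stats.paired_t(w["visual_detect"], w["auditory_detect"])
        out["detection_t"] = {
            "t": t,
            "df": df,
            "p": p,
            "bf10": stats.bayes_t(w["visual_detect"], w["auditory_detect"]),
        }
    return out


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> PipelineResult:
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    # ---- inputs ----------------------------------------------------------
    if config.sim is not None:
        df = synthetic.simulate_session(config.sim)
        trace_iter = _sim_traces(df, config.sim)
    else:
        input_dir = Path(config.input_dir)
        df = ppio.read_trials(input_dir / "trials.csv")
        trace_iter = _file_traces(df, input_dir)
    df = df.reset_index(drop=True)
    n_generated = len(df)
    log.info("pipeline start: %d trials", n_generated)

    # ---- preprocessing ---------------------------------------------------
    epochs: dict[int, Epoch] = {}
    for col in ANALYSIS_FLAGS:
        df[f"flag_{col}"] = False
    for idx, series, onset in trace_iter:
        epoch = preprocess_trace(
            series,
            onset_ms=onset,
            diameter_scale=config.diameter_scale,
            blink_vel_threshold=config.blink_vel_threshold,
            blink_margin_ms=config.blink_margin_ms,
            blink_merge_gap_ms=config.blink_merge_gap_ms,
            epoch_vel_threshold=config.epoch_vel_threshold,
        )
        epochs[idx] = epoch
        for f in epoch.flags:
            df.loc[idx, f"flag_{f}"] = True

    # PCA rejection across all finite epochs of the run
    pca_idx = [
        i
        for i, e in epochs.items()
        if not (df.loc[i, "flag_uninterpolable"]) and np.isfinite(e.corrected).all()
    ]
    if len(pca_idx) >= 3:
        X = np.stack([epochs[i].corrected for i in pca_idx])
        rejected = reject_pca(X, config.pca_components, config.pca_z_threshold)
        for r in rejected:
            i = pca_idx[r]
            df.loc[i, "flag_pca_outlier"] = True
            epochs[i].flags.add("pca_outlier")

    # ---- trial bookkeeping ----------------------------------------------
    df = trials_mod.classify_by_response(df)
    artifact = df[[f"flag_{f}" for f in ANALYSIS_FLAGS]].any(axis=1)
    has_epoch = df.index.isin(epochs.keys())
    classified = df["assigned_condition"].isin(trials_mod.CONDITIONS)
    nontarget = ~df["target_present"].astype(bool)

    analyzable = nontarget & classified & ~artifact & has_epoch
    counts_after = trials_mod.condition_counts(df, analyzable=pd.Series(analyzable))
    rejected_per_task = (
        df.loc[nontarget & classified & has_epoch & artifact]
        .groupby(["participant_id", "task"], observed=True)
        .size()
        .rename("n_rejected")
        .reset_index()
    )
    exclusions = trials_mod.exclude_participants(counts_after, rejected_per_task)
    # participants who vanished from the counts entirely are excluded too
    seen = set(counts_after["participant_id"])
    missing = sorted(set(df["participant_id"].unique()) - seen)
    if missing:
        exclusions = pd.concat(
            [
                exclusions,
                pd.DataFrame(
                    [(pid, True, "no analyzable trials") for pid in missing],
                    columns=["participant_id", "excluded", "reason"],
                ),
            ],
            ignore_index=True,
        ).sort_values("participant_id", ignore_index=True)
    excluded_ids = set(exclusions.loc[exclusions["excluded"], "participant_id"])
    retained = ~df["participant_id"].isin(excluded_ids)

    df["analyzable"] = analyzable & retained

    # ---- outcome measures ------------------------------------------------
    grad = np.full(len(df), np.nan)
    for i in df.index[df["analyzable"]]:
        grad[i] = metrics.gradient(
            epochs[i], config.gradient_mode, per_second=config.gradient_per_second
        ).value
    df["gradient"] = grad

    table = metrics.condition_table(df.loc[df["analyzable"]])
    ga_idx = list(df.index[df["analyzable"]])
    grand = metrics.grand_average_timecourse(
        [epochs[i] for i in ga_idx],
        list(df.loc[ga_idx, "assigned_condition"]),
        list(df.loc[ga_idx, "participant_id"]),
    )

    # ---- inference --------------------------------------------------------
    anova_res: list = []
    pairwise = pd.DataFrame(
        columns=["factor", "contrast", "p", "threshold", "rejected", "method"]
    )
    if len(table) and table["participant_id"].nunique() >= 2:
        try:
            anova_res = stats.rm_anova(
                table,
                dv="gradient",
                within=["assigned_condition", "task"],
                subject="participant_id",
                gg=config.gg,
            )
        except InsufficientDataError as err:
            log.warning("ANOVA skipped: %s", err)
        else:
            pairwise = pd.concat(
                [
                    _pairwise_frame(table, "assigned_condition", config.correction_method, config.alpha),
                    _pairwise_frame(table, "task", config.correction_method, config.alpha),
                ],
                ignore_index=True,
            )
    behavioral = _behavioral_block(df, config.alpha)

    # ---- accounting -------------------------------------------------------
    n_target = int(df["target_present"].astype(bool).sum())
    n_unclassified = int((nontarget & ~classified).sum())
    n_artifact = int((nontarget & classified & has_epoch & artifact).sum())
    n_missing_trace = int((nontarget & classified & ~has_epoch & ~artifact).sum())
    n_excluded = int(
        (analyzable & df["participant_id"].isin(excluded_ids)).sum()
    )
    n_analyzed = int(df["analyzable"].sum())
    accounting = {
        "generated": n_generated,
        "target_dropped": n_target,
        "unclassified": n_unclassified,
        "artifact_rejected": n_artifact,
        "missing_trace": n_missing_trace,
        "excluded_participant": n_excluded,
        "analyzed": n_analyzed,
    }
    assert (
        n_generated
        == n_target + n_unclassified + n_artifact + n_missing_trace + n_excluded + n_analyzed
    ), "trial accounting does not conserve trials"
    log.info("accounting: %s", accounting)

    manifest = {
        "config": config.echo(),
        "package": "pupilpipe",
        "counts": accounting,
        "n_participants_retained": int(
            df.loc[df["analyzable"], "participant_id"].nunique()
        ),
    }

    result = PipelineResult(
        trials=df,
        condition_table=table,
        anova=anova_frame(anova_res),
        pairwise=pairwise,
        exclusions=exclusions,
        grand_average=grand,
        behavioral=behavioral,
        accounting=accounting,
        manifest=manifest,
        epochs=epochs,
    )
    if config.out_dir is not None:
        _write_outputs(result, Path(config.out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    ff = "%.10g"
    result.trials.drop(columns=[], errors="ignore").to_csv(
        out_dir / "trials.csv", index=False, float_format=ff
    )
    result.condition_table.to_csv(out_dir / "condition_table.csv", index=False, float_format=ff)
    result.anova.to_csv(out_dir / "anova.csv", index=False, float_format=ff)
    result.pairwise.to_csv(out_dir / "pairwise.csv", index=False, float_format=ff)
    result.exclusions.to_csv(out_dir / "exclusions.csv", index=False, float_format=ff)
    result.grand_average.to_csv(out_dir / "grand_average.csv", index=False, float_format=ff)
    for key in ("match_rates", "detection_rates", "match_anova", "match_pairwise"):
        if key in result.behavioral:
            result.behavioral[key].to_csv(out_dir / f"{key}.csv", index=False, float_format=ff)
    ppio.write_manifest(out_dir / "manifest.json", result.manifest)


# ---------------------------------------------------------------------------
# synthetic session export
# ---------------------------------------------------------------------------

def write_session(sim: SimConfig, out_dir: str | Path) -> Path:
    """Write a full synthetic session to disk in the file layout the
    pipeline reads back: one TSV sample log per participant-block (all
    trials, targets included, concatenated on a block clock) plus
    ``trials.csv`` with per-trial onset times."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = synthetic.simulate_session(sim)
    span = sim.trial_span_ms
    onsets = np.full(len(df), np.nan)
    df = df.reset_index(drop=True)
    for (pid, block), sub in df.groupby(["participant_id", "block_index"], observed=True):
        parts_t, parts = [], []
        for k, (idx, row) in enumerate(sub.sort_values("trial_index").iterrows()):
            rng = sim.trial_rng(pid, block, row["trial_index"])
            s = synthetic.simulate_trace(row, sim, rng)
            s = synthetic.inject_blinks(s, sim, sim.blink_rng(pid, block, row["trial_index"]))
            offset = k * span + sim.fixation_ms
            onsets[idx] = offset
            parts_t.append(s.time_ms + offset)
            parts.append(s)
        series = SampleSeries(
            time_ms=np.concatenate(parts_t),
            pupil=np.concatenate([p.pupil for p in parts]),
            validity=np.concatenate([p.validity for p in parts]),
            gaze_x=np.concatenate([p.gaze_x for p in parts]),
            gaze_y=np.concatenate([p.gaze_y for p in parts]),
            units="area",
        )
        ppio.write_samples(out_dir / ppio.sample_log_name(int(pid), int(block)), series)
    df["onset_ms"] = onsets
    ppio.write_trials(out_dir / "trials.csv", df)
    return out_dir
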