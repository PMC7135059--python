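# Methods

This note documents the models, numerical choices and open design decisions
behind `pupilpipe`, in the order the pipeline runs them.

## Signal model of the synthetic generator

Each trial's pupil-area trace (500 Hz, −1,000…+6,000 ms around stimulus
onset, 3,500 samples) is

```
area(t) = B + u_p + R(t)·[visual] + G · D(t) + ε(t)
```

* `B` — baseline area (`baseline_level`, default 1500 device units; video
  trackers report area on an arbitrary, diameter²-proportional scale, so
  generation happens in area units and the √-conversion stage is genuinely
  exercised).
* `u_p ~ N(0, participant_sd²)` — subject offset (default 100 units).
* `R(t)` — pupillary light reflex, picture modality only: a negative
  gamma-shaped transient starting at `reflex_latency_ms` (250 ms), reaching
  −`reflex_amplitude` (−300 units) at latency + `reflex_constriction_ms`
  (350 ms, so the trough sits near 600 ms, inside the 0–1,000 ms gradient
  search window), recovering with `reflex_recovery_tau_ms` (1,200 ms).
* `D(t)` — event-related dilation kernel: gamma bump `x^k e^{k(1−x)}`,
  `x = t/peak`, unit peak at `dilation_peak_ms` (1,300 ms, inside the
  1,000–2,000 ms window), decay constant `dilation_tau_ms` (800 ms). The
  gamma shape is the standard stylization of the slow event-related pupil
  response; its two parameters are exposed rather than fitted.
* `G = arousal_gain[valence] · task_attention_gain[task] · exp(N(0, σ_subj²))
  · exp(N(0, σ_trial²))` — the effect of interest. Defaults:
  positive/negative 120 units, neutral 50 units; lognormal subject
  (σ = 0.2) and trial (σ = 0.3) gain variability give realistic
  between-/within-subject spread. All attention gains are 1 in the
  picture-modality configuration (the arousal effect is
  attention-independent); the sound-modality configuration sets the gains of
  the unattended-modality tasks (`none`, `visual_detect`) to 0, which
  injects a valence × task interaction.
* `ε(t) ~ N(0, noise_sd²)` — measurement noise (15 units).

Magnitudes are not taken from any published table — no standard effect
sizes in physical units exist for this index — so the defaults were
fixed once to produce physiologically plausible traces whose sign patterns
and detectability at n = 24 match the study design; they are conditions of
the simulation, not tuning knobs.

Blinks are a Poisson process (`blink_rate` 15/min, durations uniform in
100–300 ms) that zeroes the pupil and clears validity; overlaps merge.
Responses: the emotional block draws reported valence from a row-stochastic
3×3 confusion matrix (default 0.8 on the diagonal); detection targets are
hit with probability 0.75, the accuracy the paradigm calibrates its targets
to. Target trials are scheduled (15 of 75 per detection block, uniformly
placed) but no trace is generated for them — the design discards them from
every pupillary analysis, and modelling the target-evoked response is out
of scope.

Randomness: one master seed; schedule, per-subject, per-trial, per-blink
and response draws come from disjoint `SeedSequence` substreams keyed by
(participant, block, trial), so any single trial is reproducible in
isolation and runs are bit-stable.

What the generator does **not** emulate: luminance differences between
stimuli, gaze-dependent pupil foreshortening, saccades, slow vigilance
drifts, or target-evoked responses. Passing tests therefore validate the
pipeline's arithmetic and inferential calibration, not its robustness to
every artifact of real recordings.

## Preprocessing

Stage order: blink repair (500 Hz, area units) → 50 Hz decimation →
±4-point smoothing → √area→diameter → epoching/baseline → trial-level
rejection. The conversion is monotone, so running it after smoothing cannot
move the gradient's extremum times; the order follows the narrative order
of the workflow the pipeline reproduces.

* **Blink detection.** Maximal runs of zero/invalid samples, widened by
  `margin_ms` (50 ms) and further (≤ 200 ms) until the smoothed-signal
  velocity drops below a threshold; the default threshold is 5× the median
  absolute velocity of the valid signal, since no absolute value transfers
  across devices. Intervals closer than 100 ms merge. Intervals touching
  the series edge are non-interpolable.
* **Repair.** For a gap [t₁, t₂] of duration d, the unique cubic through
  the four anchors t₁−d, t₁, t₂, t₂+d replaces the interior (exact on any
  cubic trend; < 1% amplitude error on a 1 Hz sinusoid with a 100 ms gap).
  Gaps whose anchors leave the recording stay missing and flag the trial
  `uninterpolable`. Because trials are simulated as isolated 7 s windows,
  edge blinks are unrepairable more often than in continuous recordings;
  the resulting rejection fraction (~20% of trials at 15 blinks/min) is an
  upper bound relative to block-continuous data, and the corresponding
  check is an order-of-magnitude band, not an exact count.
* **Resampling.** Decimation keeps every 10th sample with the phase chosen
  so 0 ms (stimulus onset) lies on the 20 ms output grid; smoothing is a
  9-point moving average with a shrinking window at the edges (preserves
  the −1,000 ms fixation segment).
* **Epoch & baseline.** Baseline = mean over −200 ≤ t < 0 ms; subtracted
  from the whole epoch (post-correction baseline mean is 0 to 1e−9 by
  construction). The analysis window for time courses is 0–5,800 ms
  (291 points at 50 Hz).
* **Velocity-peak rejection.** A trial is flagged when the max absolute
  first difference of the corrected 50 Hz trace exceeds
  `epoch_vel_threshold` (default 0.8 diameter units/sample — roughly an
  order of magnitude above both smoothed noise and the steepest clean
  light-reflex slope under the default generator scale).
* **PCA rejection.** Trials × timepoints matrix of corrected traces
  (baseline-corrected — the covariance then reflects response shape, not
  offsets; this choice is logged), column-centered, SVD; robust z
  (median/MAD) on the first 3 component scores; reject |z| > 3.5. The
  component count and cutoff are conventional robust-outlier practice and
  configurable; tests pin behaviour (a planted gross artifact is caught),
  not the constants. Zero-variance components are skipped; when MAD
  degenerates (≥ half the scores identical, e.g. noise-free simulations)
  the ordinary standard deviation replaces it, which still exposes a lone
  gross outlier but tolerates legitimate clusters of condition means.

## Trial bookkeeping

Target trials are removed first (a 75-trial detection block keeps 60).
Every trial of stimulus s by participant p inherits the valence p reported
for s in the emotional block; stimuli with no usable report (timeout)
become `unclassified` and enter no pupillary analysis — classification is
defined only through that response. A participant is excluded when (a) an
emotion condition retains zero analyzable trials, or (b) strictly more
than 75% (> 45 of 60) of a task's analyzable trials were rejected; the
boundary case 45/60 is retained. The per-condition-within-block trial
counts are soft-checked against the 10–40 band typical of
subjective-response classification in this design (9–39 after artifact
removal); the band is read per condition ×
task block, since pooling across the four blocks would sit near 72 under
veridical responding and could never fall in 10–40.

## The dilation gradient

For a corrected epoch, the early extremum is the minimum over [0, 1,000] ms
in picture mode (light-reflex trough) or the maximum over [0, 1,000] ms in
sound mode; the late extremum is the maximum over [1,000, 2,000] ms in both.
Both windows are closed — the 1,000 ms sample belongs to each — and ties
break toward the earliest time for determinism. The value is the slope
(d₂ − d₁)/(t₂ − t₁) in units/s; a same-sample degenerate pair returns 0
with a warning rather than dividing by zero. Whether the index should
divide by the time span at all is ambiguous in the source workflow; the
per-second slope is the default because the quantity is described as a
dilation *velocity*, and a raw-difference mode (`per_second=False`) is
provided — downstream F statistics are identical only when extremum spans
are equal, so the choice is exposed, not hidden.

## Inference

`rm_anova` implements the classical univariate sums-of-squares
decomposition for balanced designs: one or two within factors (subject ×
cells, one observation per cell — duplicates are cell-averaged, subjects
with missing cells dropped with a warning) and optionally one
between-subjects factor, which requires equal group sizes so the strata
stay orthogonal (the intended three-way use case compares two equal
modality groups). Per effect: F from its own error stratum, partial η² =
SS_eff/(SS_eff+SS_err), Greenhouse–Geisser ε from the orthonormal-contrast
covariance (pooled within groups in mixed designs — this matches R's
`car::Anova` and differs from implementations that ignore group structure),
clipped to [1/df₁, 1]. GG policy: `"auto"` multiplies both dfs by ε only
when df₁ > 1 and ε < 0.99 (sphericity is vacuous at two levels); `True`/
`False` force it. Error variance below 1e−12 of the stratum total is
reported as F = ∞, p = 0 with a warning.

Bayes factors use the BIC approximation, BF₁₀ = exp((BIC₀ − BIC₁)/2), with
the effect's own error stratum and the total observation count; for paired
data this reduces to (Σd²/Σ(d−d̄)²)^{n/2}/√n. This approximates a
unit-information prior, not the multivariate-Cauchy priors of JASP-style
default Bayes ANOVAs, so only the qualitative bands (< 1/3 evidence for the
null, > 3 for the alternative) are interpreted, never magnitudes.

Multiple comparisons: `bonferroni` (single step, α/k), `msrb_holm`
(sequentially rejective step-down, stage threshold α/(k−i+1)), and
`msrb_shaffer` (step-down with logically constrained stage counts — for
pairwise contrasts of m means the achievable numbers of simultaneously true
nulls are the partition sums of C(g, 2), giving s = 3, 1, 1 for three
means). Shaffer is the default for pairwise families because the
"modified sequentially rejective Bonferroni" family includes the logical
constraints; the variant is configurable since the original reference is
not reproducible here.

Power: noncentral-F with λ = f²·n·m/(1−ρ), df₁ = (m−1)ε,
df₂ = (n−1)(m−1)ε. At ε = 1 this coincides with the G*Power
repeated-measures (within) convention, which multiplies λ by ε; for ε < 1
conventions differ across programs and the formula above is the one
implemented. A 50,000-replicate Monte-Carlo simulation of the compound-
symmetric design agrees with the analytic value to < 0.003 at the
reference spec (n = 24, m = 4, f = 0.25, ρ = 0.5), and the minimal n for
80% power at that spec is 24.

## Pipeline and problem sizes

`run_pipeline` is deterministic given the configuration: identical configs
produce byte-identical result CSVs, and the JSON manifest (config echo,
stage counts, retained participants) suffices to re-run. Trial accounting
is conserved exactly: generated = target-dropped + unclassified +
artifact-rejected + missing-trace + excluded-participant + analyzed.

Problem sizes used by the shipped checks: the two reference simulations run
the full design (24 participants × 4 blocks × 60–75 trials, 500 Hz traces —
about 6,500 preprocessed trials each); unit and property tests use shrunk
sessions (6–18 stimuli) and toy ANOVA tables (≤ 8 × 3 × 4); null
calibration of the gradient → ANOVA stack uses 500 replicates at the
trial level (running the 500 Hz trace stages 500× would add nothing to the
calibration question, since the trace stages are deterministic given the
epoch and are tested end-to-end separately).

## Known limitations

* The between-subjects path requires equal group sizes; unbalanced groups
  need a regression-based (Type III) formulation that is out of scope.
* BIC Bayes factors can be extreme for large effects; they are reported for
  band classification only.
* The blink detector's auto-threshold assumes the valid signal's velocity
  distribution is dominated by genuine pupil dynamics; recordings with
  pervasive high-frequency noise may need an explicit threshold.
* Gaze data are carried through but unused: no foreshortening correction,
  no saccade handling, no luminance model.
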