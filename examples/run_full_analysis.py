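"""Run the complete analysis on a simulated 8-participant picture study.

Generates traces for every analyzable trial, preprocesses them, classifies
trials by each participant's own emotional-task responses, rejects artifact
trials, computes per-trial dilation gradients, and fits the 3 (valence) x
4 (task) repeated-measures ANOVA with Greenhouse-Geisser correction,
partial eta^2 and BIC Bayes factors, plus Shaffer-corrected pairwise
contrasts.
"""

import warnings

from pupilpipe import RunConfig, run_pipeline, visual_study_config

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = run_pipeline(
        RunConfig(sim=visual_study_config(seed=1, n_participants=8), log_level="WARNING")
    )

print("trial accounting:", result.accounting)
print("\nrepeated-measures ANOVA on dilation gradients:")
for row in result.anova.itertuples(index=False):
    print(f"  {row.effect:28s} F({row.df1:.2f}, {row.df2:.2f}) = {row.F:7.3f}  "
          f"p = {row.p:.4g}  partial eta2 = {row.partial_eta2:.3f}  BF10 = {row.bf10:.3g}")
print("  (the valence main effect carries the injected arousal difference; "
      "the interaction is null here because attention gains are equal)")

print("\npairwise contrasts (sequentially rejective Bonferroni, Shaffer stages):")
for row in result.pairwise.itertuples(index=False):
    mark = "*" if row.rejected else " "
    print(f" {mark} {row.factor}: {row.contrast:30s} p = {row.p:.4f} "
          f"(threshold {row.threshold:.4f})")

det = result.behavioral["detection_t"]
print(f"\ndetection rates visual vs auditory: t({det['df']}) = {det['t']:.3f}, "
      f"p = {det['p']:.3f}, BF10 = {det['bf10']:.3f}")
print("  (tasks are calibrated to equal 75% accuracy, so this should be null)")
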