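"""Generate a small synthetic session and inspect its design.

Builds a 4-participant picture-modality session (four blocks per
participant: emotional evaluation, no task, visual detection, auditory
detection), then prints the block sizes, target counts and behavioural
summaries. The printed marginals are the design invariants every downstream
stage relies on: 60-trial evaluation blocks, 75-trial detection blocks with
20% targets, and detection accuracy calibrated to 75%.
"""

from pupilpipe.metrics import detection_rate, match_rate
from pupilpipe.synthetic import make_schedule, simulate_responses, visual_study_config

cfg = visual_study_config(seed=1, n_participants=4)
schedule = make_schedule(cfg)
responses = simulate_responses(schedule, cfg)

print("trials per participant x task:")
print(schedule.groupby(["participant_id", "task"]).size().unstack(), "\n")

print("target trials per detection block:")
print(
    schedule[schedule.task.str.endswith("detect")]
    .groupby(["participant_id", "task"])["target_present"]
    .sum()
    .unstack(),
    "\n",
)

mr = match_rate(responses)
print(f"mean emotional-response match rate: {mr.rate.mean():.3f}")
print("  (fraction of emotional-task reports agreeing with normative valence)")

dr = detection_rate(responses)
print(f"mean target detection rate: {dr.rate.mean():.3f}")
print("  (hits / targets; the generator calibrates this near 0.75)")
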