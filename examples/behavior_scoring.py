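"""Score defensive behavior on a scripted open-field session.

The generator is told exactly where the animal freezes (6 s per trial
inside the 30 s scoring window), rears (once before each loom) and sprints
(3.5x baseline for 2 s after each loom); the scoring stage should read
those numbers back: 20% freezing, differential rearing score of -1 per
trial, one escape per trial.
"""

import photothreat as pt

schedule = pt.generate_event_schedule(
    pt.ProtocolSpec(kind="loom", n_trials=2, iti_range_s=(70.0, 80.0)), seed=3
)
onsets = schedule.trial_onsets("loom")
duration = float(schedule.events["onset_s"].max()) + 40.0

track, truth = pt.generate_behavior_track(pt.BehaviorSpec(
    duration_s=duration,
    freeze_bouts=tuple((o + 5.0, o + 11.0) for o in onsets),
    rearing_times_s=tuple(o - 10.0 for o in onsets),
    escape_windows=tuple((o + 1.0, o + 3.0, 3.5) for o in onsets),
    seed=3,
))

scores = pt.score_loom_trials(track, schedule)
print(scores[["trial", "freezing_pct", "rearing_pre", "rearing_post",
              "rearing_differential", "escape_events"]].to_string(index=False))

crosses, center_pct = pt.locomotion_metrics(
    track, grid_lines_x=[12.0, 25.0], center_rect=(9.0, 10.0, 28.0, 30.0)
)
print(f"line crosses: {crosses}, time in center: {center_pct:.1f}%")
# freezing_pct = frozen time / 30 s window x 100; the differential rearing
# score is post-loom minus pre-loom counts (negative = suppression).
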