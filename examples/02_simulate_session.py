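"""Simulate one participant's 144-trial session and inspect its structure.

Each trial draws a feedback rotation (±5…±30°) and an explicit judgment type
(hand or cursor), simulates the aiming movement with rotated visual feedback,
the explicit judged direction, and the return stroke that encodes the felt
hand direction geometrically.
"""

from vpcoupling import default_presets, simulate_participant
from vpcoupling.geometry import implicit_deviation_from_xy

preset = default_presets()["young"]
trials = simulate_participant(preset, participant_seed=42, participant_id="demo")

print(f"trials: {len(trials)}")
print(trials.groupby("judgment_type").size().rename("n per judgment type"))
print(f"rotations used: {sorted(int(r) for r in trials['rotation_deg'].unique())}")

alpha = implicit_deviation_from_xy(
    trials.t1_x, trials.t1_y, trials.end2_x, trials.end2_y,
    trials.end3_x, trials.end3_y,
)
print(f"\nimplicit angular deviation: mean {alpha.mean():+.2f} deg, "
      f"SD {alpha.std():.2f} deg")
print(trials.head(5)[["trial_idx", "rotation_deg", "judgment_type",
                      "hand_deg", "cursor_deg", "judged_deg"]].to_string(index=False))
# cursor_deg - hand_deg always equals the rotation; the implicit deviation is
# recovered from the stroke endpoints, not stored in the table.
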