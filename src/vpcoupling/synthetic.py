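"""Generative simulator of the three-stroke visuomotor-rotation judgment task.

Each simulated session follows the published design: 144 experimental trials,
one of 12 feedback rotations (±5°…±30°) crossed with one of two explicit
judgment types (hand vs cursor), six repetitions per cell, in a seeded random
order.  Per trial the participant aims a 15-cm second stroke so the rotated
cursor lands on the remembered target, then returns toward the remembered T1;
the simulator draws

* the actual hand direction (target − rotation + motor noise),
* the explicit judged direction, via a linear measurement model
  ``deviation = slope·rotation + intercept + noise`` with judgment-type
  specific parameters,
* the implicit felt-hand rotation α, via its own linear model, realised
  geometrically as the return-stroke endpoint (so the downstream geometric
  measure and the generator are exact inverses),
* sequential modulation of the effective slopes by the preceding trial's
  explicit-judgment type and its run length, and
* occasional outlier trials whose explicit judgment is shifted by a large
  constant.

Group-level defaults for the young and older cohorts carry the reported mean
proportional biases; noise magnitudes and sequential-delta magnitudes are
declared assumptions (see the package methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd
import yaml

from .geometry import wrap_angle

__all__ = [
    "ROTATIONS_DEG",
    "RING_RADIUS_CM",
    "JUDGMENT_TYPES",
    "TRIAL_COLUMNS",
    "GenerativePreset",
    "default_presets",
    "load_presets",
    "save_presets",
    "make_schedule",
    "simulate_participant",
    "simulate_cohort",
]

#: The twelve feedback rotations, degrees (CCW positive).
ROTATIONS_DEG = (-30, -25, -20, -15, -10, -5, 5, 10, 15, 20, 25, 30)
#: Radius of the stopper ring that ends the second stroke, cm.
RING_RADIUS_CM = 15.0
JUDGMENT_TYPES = ("cursor", "hand")
REPS_PER_CELL = 6
TRIALS_PER_SESSION = len(ROTATIONS_DEG) * len(JUDGMENT_TYPES) * REPS_PER_CELL

TRIAL_COLUMNS = [
    "participant",
    "group",
    "trial_idx",
    "rotation_deg",
    "judgment_type",
    "target_deg",
    "hand_deg",
    "cursor_deg",
    "judged_deg",
    "t1_x",
    "t1_y",
    "end2_x",
    "end2_y",
    "end3_x",
    "end3_y",
]


@dataclass(frozen=True)
class GenerativePreset:
    """Group-level generative parameters for one simulated cohort.

    Slopes are proportional biases in degrees of judgment deviation per degree
    of feedback rotation; intercepts are constant offsets in degrees (positive
    = counter-clockwise); SDs are trial-to-trial noise in degrees.  Sequential
    deltas modulate the effective slope according to the preceding trial's
    explicit-judgment type: explicit biases grow in magnitude by
    ``seq_delta_explicit_same`` after a same-type judgment, the implicit bias
    changes by ``seq_delta_implicit_after_hand`` (negative = weakened) after an
    explicit hand judgment; both deltas are multiplied by
    ``repetition_multiplier`` when the preceding type had just been repeated
    (run length ≥ 2).
    """

    group: str
    n_participants: int
    slope_hand_explicit: float
    slope_cursor_explicit: float
    slope_hand_implicit: float
    intercept_hand_explicit: float = 3.0
    intercept_cursor_explicit: float = 0.0
    intercept_implicit: float = 0.0
    sd_hand_explicit: float = 12.0
    sd_cursor_explicit: float = 5.0
    sd_implicit: float = 5.0
    motor_sd: float = 4.0
    return_length_cv: float = 0.05
    seq_delta_explicit_same: float = 0.02
    seq_delta_implicit_after_hand: float = -0.02
    repetition_multiplier: float = 1.5
    outlier_rate: float = 0.005
    outlier_shift: float = 40.0

    def __post_init__(self) -> None:
        for name in ("sd_hand_explicit", "sd_cursor_explicit", "sd_implicit",
                     "motor_sd", "return_length_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.outlier_rate < 0.1:
            raise ValueError("outlier_rate must lie in [0, 0.1)")
        if self.n_participants < 1:
            raise ValueError("n_participants must be at least 1")
        for name in (
            "slope_hand_explicit",
            "slope_cursor_explicit",
            "slope_hand_implicit",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def default_presets() -> dict[str, GenerativePreset]:
    """Default young/older presets carrying the reported group-mean biases."""
    return {
        "young": GenerativePreset(
            group="young",
            n_participants=16,
            slope_hand_explicit=0.63,
            slope_cursor_explicit=-0.08,
            slope_hand_implicit=0.31,
        ),
        "older": GenerativePreset(
            group="older",
            n_participants=19,
            slope_hand_explicit=0.75,
            slope_cursor_explicit=-0.07,
            slope_hand_implicit=0.30,
        ),
    }


def save_presets(presets: dict[str, GenerativePreset], path) -> None:
    """Write presets to a YAML file keyed by group label."""
    payload = {name: asdict(p) for name, p in presets.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_presets(path) -> dict[str, GenerativePreset]:
    """Read presets from YAML, filling unspecified fields from the defaults."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    defaults = default_presets()
    presets = {}
    for name, fields in payload.items():
        fields = dict(fields or {})
        base = defaults.get(fields.get("group", name))
        if base is not None:
            presets[name] = replace(base, **fields)
        else:
            presets[name] = GenerativePreset(**fields)
    return presets


def make_schedule(seed) -> pd.DataFrame:
    """Seeded trial schedule: 144 (rotation, judgment_type) pairs.

    Every rotation × judgment-type cell appears exactly six times; the order
    is a uniform random permutation drawn from ``seed``.
    """
    rng = np.random.default_rng(seed)
    rotations = np.repeat(np.array(ROTATIONS_DEG, float), len(JUDGMENT_TYPES) * REPS_PER_CELL)
    jtypes = np.tile(
        np.repeat(np.array(JUDGMENT_TYPES, object), REPS_PER_CELL), len(ROTATIONS_DEG)
    )
    order = rng.permutation(TRIALS_PER_SESSION)
    return pd.DataFrame(
        {
            "trial_idx": np.arange(1, TRIALS_PER_SESSION + 1),
            "rotation_deg": rotations[order],
            "judgment_type": jtypes[order],
        }
    )


def _sequential_slope_adjustments(jtypes: np.ndarray, preset: GenerativePreset):
    """Per-trial effective-slope adjustments from the preceding trial's type.

    Returns (d_hand_explicit, d_cursor_explicit, d_implicit): signed additive
    slope adjustments, zero on the first trial.
    """
    n = len(jtypes)
    d_hand = np.zeros(n)
    d_cursor = np.zeros(n)
    d_impl = np.zeros(n)
    for t in range(1, n):
        prev = jtypes[t - 1]
        repeated = t >= 2 and jtypes[t - 2] == prev
        mult = preset.repetition_multiplier if repeated else 1.0
        if prev == "hand":
            # stronger (more positive) explicit-hand bias after hand judgments
            d_hand[t] = preset.seq_delta_explicit_same * mult
            # implicit bias weakened after explicit hand judgments
            d_impl[t] = preset.seq_delta_implicit_after_hand * mult
        else:
            # stronger (more negative) explicit-cursor bias after cursor judgments
            d_cursor[t] = -preset.seq_delta_explicit_same * mult
    return d_hand, d_cursor, d_impl


def simulate_participant(
    preset: GenerativePreset, participant_seed, participant_id: str = "p1"
) -> pd.DataFrame:
    """Simulate one 144-trial session; returns a tidy trial table.

    The implicit felt-hand rotation is generated for every trial (it precedes
    the explicit-judgment instruction) and is materialised only through the
    stroke endpoints; downstream code must recover it geometrically.
    """
    rng = np.random.default_rng(participant_seed)
    sched = make_schedule(rng.integers(2**31))
    n = len(sched)
    rot = sched["rotation_deg"].to_numpy()
    jtype = sched["judgment_type"].to_numpy()

    target = rng.uniform(-60.0, 60.0, n)
    hand = target - rot + rng.normal(0.0, preset.motor_sd, n)
    cursor = hand + rot

    d_hand, d_cursor, d_impl = _sequential_slope_adjustments(jtype, preset)
    is_hand = jtype == "hand"
    slope_exp = np.where(
        is_hand,
        preset.slope_hand_explicit + d_hand,
        preset.slope_cursor_explicit + d_cursor,
    )
    icept_exp = np.where(
        is_hand, preset.intercept_hand_explicit, preset.intercept_cursor_explicit
    )
    sd_exp = np.where(is_hand, preset.sd_hand_explicit, preset.sd_cursor_explicit)

    judged_dev = slope_exp * rot + icept_exp + rng.normal(0.0, 1.0, n) * sd_exp
    outlier = rng.random(n) < preset.outlier_rate
    judged_dev = judged_dev + outlier * rng.choice([-1.0, 1.0], n) * preset.outlier_shift
    judged = wrap_angle(np.where(is_hand, hand, cursor) + judged_dev)

    alpha = (
        (preset.slope_hand_implicit + d_impl) * rot
        + preset.intercept_implicit
        + rng.normal(0.0, preset.sd_implicit, n)
    )

    # geometry: T1 at origin; end2 on the stopper ring along the hand direction;
    # return stroke aims at T1 from the felt (CCW-rotated by alpha) hand position
    th = np.radians(hand)
    e2x = -RING_RADIUS_CM * np.sin(th)
    e2y = RING_RADIUS_CM * np.cos(th)
    a = np.radians(alpha)
    feltx = np.cos(a) * e2x - np.sin(a) * e2y
    felty = np.sin(a) * e2x + np.cos(a) * e2y
    frac = np.clip(1.0 + rng.normal(0.0, preset.return_length_cv, n), 0.2, None)
    e3x = e2x - frac * feltx
    e3y = e2y - frac * felty

    return pd.DataFrame(
        {
            "participant": participant_id,
            "group": preset.group,
            "trial_idx": sched["trial_idx"],
            "rotation_deg": rot,
            "judgment_type": jtype,
            "target_deg": target,
            "hand_deg": wrap_angle(hand),
            "cursor_deg": wrap_angle(cursor),
            "judged_deg": judged,
            "t1_x": 0.0,
            "t1_y": 0.0,
            "end2_x": e2x,
            "end2_y": e2y,
            "end3_x": e3x,
            "end3_y": e3y,
        }
    )


def simulate_cohort(
    presets: dict[str, GenerativePreset] | None = None, master_seed: int = 0
) -> pd.DataFrame:
    """Simulate a full multi-group cohort (default: 16 young + 19 older).

    Child seeds are spawned deterministically from ``master_seed`` with a
    counter-based derivation, so each participant's data is independent of
    simulation order.
    """
    if presets is None:
        presets = default_presets()
    frames = []
    counter = 0
    root = np.random.SeedSequence(master_seed)
    for name, preset in presets.items():
        for i in range(preset.n_participants):
            child = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(counter,)
            )
            pid = f"{preset.group}_{i + 1:02d}"
            frames.append(simulate_participant(preset, child, pid))
            counter += 1
    return pd.concat(frames, ignore_index=True)
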