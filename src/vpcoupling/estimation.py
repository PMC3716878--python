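"""Per-participant bias estimation and two-level outlier screening.

For each participant and judgment kind (explicit cursor, explicit hand,
implicit hand) the angular deviation of the judged from the actual direction
is regressed on the feedback rotation.  The slope is the proportional bias
(degrees of deviation per degree of rotation: 0 = no coupling, 1 = full
capture of one modality by the other); the intercept is a constant offset
independent of the rotation.

Screening follows the two-level scheme used with such regressions:

1. trial level — trials whose judgment falls outside the regression
   prediction ±3 SD of the residuals are removed (single pass), and the
   regression is refit on the retained trials;
2. participant level — bias parameters are pooled across all participants of
   both groups per judgment kind, values outside mean ± 3 SD are excluded,
   and the computation repeats on the remaining participants until no further
   outliers are found.  A participant excluded for any kind is excluded from
   all analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import implicit_deviation_from_xy, wrap_deviation

__all__ = [
    "JUDGMENT_KINDS",
    "ParticipantEstimates",
    "fit_bias",
    "screen_trial_outliers",
    "screen_participant_outliers",
    "trial_deviations",
    "estimate_participants",
    "participant_rotation_sd",
    "summarize_group",
]

logger = logging.getLogger(__name__)

#: The three judgment kinds analysed per participant.
JUDGMENT_KINDS = ("cursor_explicit", "hand_explicit", "hand_implicit")


@dataclass
class ParticipantEstimates:
    """Regression-based bias estimates for one participant × judgment kind."""

    participant: str
    group: str
    kind: str
    slope: float
    intercept: float
    residual_sd: float
    n_trials_used: int
    n_trials_removed: int

    def as_dict(self) -> dict:
        return {
            "participant": self.participant,
            "group": self.group,
            "kind": self.kind,
            "slope": self.slope,
            "intercept": self.intercept,
            "residual_sd": self.residual_sd,
            "n_trials_used": self.n_trials_used,
            "n_trials_removed": self.n_trials_removed,
        }


class InsufficientDataError(ValueError):
    """Raised when a regression has fewer than three distinct rotations."""


def fit_bias(deviations, rotations) -> tuple[float, float, float]:
    """OLS of angular deviation on feedback rotation.

    Returns ``(slope, intercept, residual_sd)``; the slope is the proportional
    bias in deg/deg.  Residual SD uses ddof=2 (two fitted parameters).
    """
    y = np.asarray(deviations, float)
    x = np.asarray(rotations, float)
    if len(np.unique(x)) < 3:
        raise InsufficientDataError("need at least 3 distinct rotation values")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    dof = max(len(y) - 2, 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    return float(slope), float(intercept), residual_sd


def screen_trial_outliers(deviations, rotations, n_sd: float = 3.0):
    """Single-pass trial screening against the regression prediction ± n_sd·SD.

    Returns ``(kept_idx, removed_idx)`` as integer index arrays.  With zero
    residual SD (degenerate, e.g. noiseless data) nothing is removed.
    """
    y = np.asarray(deviations, float)
    x = np.asarray(rotations, float)
    slope, intercept, residual_sd = fit_bias(y, x)
    if residual_sd == 0.0:
        logger.debug("zero residual SD; no trial screening applied")
        return np.arange(len(y)), np.array([], dtype=int)
    resid = y - (slope * x + intercept)
    removed = np.flatnonzero(np.abs(resid) > n_sd * residual_sd)
    kept = np.setdiff1d(np.arange(len(y)), removed)
    return kept, removed


def screen_participant_outliers(
    biases: pd.Series, n_sd: float = 3.0
) -> tuple[list, list, int]:
    """Iterative mean ± n_sd·SD screening of bias parameters across participants.

    ``biases`` is indexed by participant id.  Returns
    ``(kept_ids, excluded_ids, n_iterations)`` where ``n_iterations`` counts
    the passes that removed at least one participant (0 = clean on the first
    pass); the final removal-free pass that certifies the fixed point is not
    counted.
    """
    if len(biases) < 3:
        raise InsufficientDataError("need at least 3 participants to screen")
    kept = biases.copy()
    excluded: list = []
    iterations = 0
    while True:
        mean, sd = kept.mean(), kept.std(ddof=1)
        out = kept[(kept - mean).abs() > n_sd * sd] if sd > 0 else kept.iloc[0:0]
        if out.empty:
            break
        iterations += 1
        excluded.extend(out.index.tolist())
        kept = kept.drop(out.index)
        if kept.empty:
            raise ValueError("participant screening excluded every participant")
    return kept.index.tolist(), excluded, iterations


def trial_deviations(trials: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Per-trial angular deviations for one judgment kind.

    Explicit kinds use only trials where that judgment was requested; the
    implicit kind pools trials across both explicit-judgment types, since the
    return stroke precedes the instruction.  Degenerate implicit trials
    (zero-length strokes) are dropped with a warning.
    """
    if kind == "hand_implicit":
        dev = implicit_deviation_from_xy(
            trials["t1_x"], trials["t1_y"],
            trials["end2_x"], trials["end2_y"],
            trials["end3_x"], trials["end3_y"],
        )
        out = trials.assign(deviation_deg=dev)
        bad = out["deviation_deg"].isna()
        if bad.any():
            logger.warning("dropping %d degenerate implicit trials", int(bad.sum()))
            out = out[~bad]
        return out
    jtype = {"cursor_explicit": "cursor", "hand_explicit": "hand"}[kind]
    sub = trials[trials["judgment_type"] == jtype]
    actual = sub["cursor_deg"] if jtype == "cursor" else sub["hand_deg"]
    return sub.assign(deviation_deg=wrap_deviation(sub["judged_deg"], actual))


def estimate_participants(
    trials: pd.DataFrame,
    screen_trials: bool = True,
    screen_participants: bool = True,
    n_sd: float = 3.0,
) -> pd.DataFrame:
    """Full estimation pipeline over a trial table.

    For every participant × judgment kind: (optionally) screen trials, refit
    the regression on retained trials; then (optionally) screen participants
    on the pooled bias parameters per kind, excluding flagged participants
    from all kinds.  Returns a tidy estimates table with one row per retained
    participant × kind and an ``excluded`` boolean column for flagged ones.
    """
    rows = []
    for kind in JUDGMENT_KINDS:
        devs = trial_deviations(trials, kind)
        for (pid, group), sub in devs.groupby(["participant", "group"], sort=False):
            y = sub["deviation_deg"].to_numpy()
            x = sub["rotation_deg"].to_numpy()
            if screen_trials:
                kept, removed = screen_trial_outliers(y, x, n_sd=n_sd)
                if len(removed):
                    logger.info(
                        "participant %s kind %s: removed %d trial outlier(s)",
                        pid, kind, len(removed),
                    )
                y, x = y[kept], x[kept]
                n_removed = len(removed)
            else:
                n_removed = 0
            slope, intercept, residual_sd = fit_bias(y, x)
            rows.append(
                ParticipantEstimates(
                    pid, group, kind, slope, intercept, residual_sd,
                    len(y), n_removed,
                ).as_dict()
            )
    est = pd.DataFrame(rows)
    est["excluded"] = False
    if screen_participants:
        flagged: set = set()
        for kind in JUDGMENT_KINDS:
            biases = est.loc[est["kind"] == kind].set_index("participant")["slope"]
            _, excluded, _ = screen_participant_outliers(biases, n_sd=n_sd)
            if excluded:
                logger.info("kind %s: excluded participant(s) %s", kind, excluded)
            flagged.update(excluded)
        est.loc[est["participant"].isin(flagged), "excluded"] = True
    return est


def summarize_group(
    estimates: pd.DataFrame, trials: pd.DataFrame | None = None
) -> dict[str, pd.DataFrame]:
    """Group-level summaries of the participant estimates.

    Returns ``{"biases": ..., "rotation_sd": ...}``: per group × kind mean and
    SE of slopes and intercepts; and, when a trial table is supplied, the mean
    intra-individual SD of the deviations per group × kind × rotation.
    """
    retained = estimates[~estimates["excluded"]]
    grp = retained.groupby(["group", "kind"])
    biases = grp.agg(
        n=("slope", "size"),
        slope_mean=("slope", "mean"),
        slope_se=("slope", "sem"),
        intercept_mean=("intercept", "mean"),
        intercept_se=("intercept", "sem"),
    ).reset_index()
    out = {"biases": biases}
    if trials is not None:
        per = participant_rotation_sd(trials, participants=set(retained["participant"]))
        agg = per.groupby(["group", "kind", "rotation_deg"])["sd"].agg(["mean", "sem"])
        out["rotation_sd"] = agg.reset_index().rename(
            columns={"mean": "sd_mean", "sem": "sd_se"}
        )
    return out


def participant_rotation_sd(
    trials: pd.DataFrame, participants: set | None = None
) -> pd.DataFrame:
    """Intra-individual SD of deviations per participant × kind × rotation."""
    rows = []
    for kind in JUDGMENT_KINDS:
        devs = trial_deviations(trials, kind)
        if participants is not None:
            devs = devs[devs["participant"].isin(participants)]
        per = (
            devs.groupby(["group", "participant", "rotation_deg"])["deviation_deg"]
            .std(ddof=1)
            .rename("sd")
            .reset_index()
        )
        per.insert(2, "kind", kind)
        rows.append(per)
    return pd.concat(rows, ignore_index=True)
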