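"""Trial-history classification and subset bias estimation for sequential effects.

Each trial (from the second onward) is classified by two properties of the
preceding trials: which explicit judgment the immediately preceding trial
required (hand vs cursor) and whether that type had just occurred once or
repeatedly (run length of the preceding same-type run ≥ ``repeat_threshold``,
default 2).  Bias regressions are then refit within each of the four
(preceding type × repetition) trial subsets per participant and judgment
kind, which is how history-dependent modulation of the coupling is measured.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .estimation import (
    JUDGMENT_KINDS,
    InsufficientDataError,
    fit_bias,
    trial_deviations,
)

__all__ = ["classify_history", "add_history_columns", "subset_biases"]

logger = logging.getLogger(__name__)


def classify_history(judgment_types, repeat_threshold: int = 2) -> pd.DataFrame:
    """Classify a session-ordered judgment-type sequence by trial history.

    Returns a DataFrame with ``preceding_type`` (type of the previous trial's
    explicit judgment) and ``repetition`` ("once" or "repeated"): the previous
    trial closed a same-type run of length ≥ ``repeat_threshold`` for
    "repeated", shorter for "once".  The first trial is unclassifiable (NaN).
    """
    types = list(judgment_types)
    if not types:
        raise ValueError("empty judgment-type sequence")
    n = len(types)
    prev = [None] + types[:-1]
    runlen = [1] * n  # length of the same-type run ending at each trial
    for i in range(1, n):
        runlen[i] = runlen[i - 1] + 1 if types[i] == types[i - 1] else 1
    rep = [None] + [
        "repeated" if runlen[t - 1] >= repeat_threshold else "once"
        for t in range(1, n)
    ]
    return pd.DataFrame(
        {"preceding_type": pd.array(prev, dtype=object),
         "repetition": pd.array(rep, dtype=object)}
    )


def add_history_columns(
    trials: pd.DataFrame, repeat_threshold: int = 2
) -> pd.DataFrame:
    """Append ``preceding_type``/``repetition`` columns per participant session."""
    out = []
    for _, sub in trials.groupby("participant", sort=False):
        sub = sub.sort_values("trial_idx")
        hist = classify_history(
            sub["judgment_type"].tolist(), repeat_threshold=repeat_threshold
        )
        hist.index = sub.index
        out.append(pd.concat([sub, hist], axis=1))
    return pd.concat(out).loc[trials.index]


def subset_biases(
    trials: pd.DataFrame,
    repeat_threshold: int = 2,
    min_rotations: int = 3,
    sign_flip_cursor: bool = False,
) -> pd.DataFrame:
    """Bias slope per participant × judgment kind × sequential category.

    Refits the deviation-on-rotation regression within each (preceding type,
    repetition) subset.  Subsets with fewer than ``min_rotations`` distinct
    rotations are dropped with a log entry.  With ``sign_flip_cursor`` the
    explicit-cursor slopes are negated so that, as for the other kinds,
    larger values mean stronger bias — the convention used for the
    strength ANOVA, not for raw reporting.
    """
    if not {"preceding_type", "repetition"} <= set(trials.columns):
        trials = add_history_columns(trials, repeat_threshold=repeat_threshold)
    classifiable = trials[trials["preceding_type"].notna()]
    rows = []
    for kind in JUDGMENT_KINDS:
        devs = trial_deviations(classifiable, kind)
        grouped = devs.groupby(
            ["participant", "group", "preceding_type", "repetition"], sort=False
        )
        for (pid, group, prev, rep), sub in grouped:
            x = sub["rotation_deg"].to_numpy()
            if len(np.unique(x)) < min_rotations:
                logger.info(
                    "dropping subset %s/%s/%s/%s: only %d distinct rotations",
                    pid, kind, prev, rep, len(np.unique(x)),
                )
                continue
            try:
                slope, intercept, _ = fit_bias(sub["deviation_deg"].to_numpy(), x)
            except InsufficientDataError:
                continue
            if sign_flip_cursor and kind == "cursor_explicit":
                slope = -slope
            rows.append(
                {
                    "participant": pid,
                    "group": group,
                    "kind": kind,
                    "preceding_type": prev,
                    "repetition": rep,
                    "slope": slope,
                    "intercept": intercept,
                    "n_trials": len(sub),
                }
            )
    return pd.DataFrame(rows)
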