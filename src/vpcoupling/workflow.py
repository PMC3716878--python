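"""End-to-end pipeline stages: simulate → analyze → report.

Thin orchestration over the library modules with CSV/YAML file I/O, used by
the command-line interface and directly scriptable.  All angles in files are
degrees; trial tables follow the column schema in
:data:`vpcoupling.synthetic.TRIAL_COLUMNS`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import estimation, group_stats, sequential, synthetic

__all__ = ["RunConfig", "run_simulate", "run_analyze", "run_report", "SchemaError"]

logger = logging.getLogger(__name__)

NUMERIC_COLUMNS = [
    c for c in synthetic.TRIAL_COLUMNS
    if c not in ("participant", "group", "judgment_type")
]


class SchemaError(ValueError):
    """Raised when an input CSV does not match the trial-table schema."""


@dataclass
class RunConfig:
    """Run-level configuration for the pipeline commands."""

    seed: int = 0
    preset_file: str | None = None
    out_dir: str = "."
    screen_trials: bool = True
    screen_participants: bool = True
    repeat_threshold: int = 2
    anova_correction: str | None = None

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        if self.preset_file is not None and not Path(self.preset_file).exists():
            raise FileNotFoundError(f"preset file not found: {self.preset_file}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def presets(self) -> dict[str, synthetic.GenerativePreset]:
        if self.preset_file is None:
            return synthetic.default_presets()
        return synthetic.load_presets(self.preset_file)


def run_simulate(config: RunConfig, out_path=None) -> pd.DataFrame:
    """Simulate a cohort under the configured presets; optionally write CSV."""
    trials = synthetic.simulate_cohort(config.presets(), master_seed=config.seed)
    if out_path is not None:
        Path(out_path).parent.mkdir(parents=True, exist_ok=True)
        trials.to_csv(out_path, index=False, lineterminator="\n")
        logger.info("wrote %d trials to %s", len(trials), out_path)
    return trials


def load_trials(path) -> pd.DataFrame:
    """Read and schema-check a trial CSV; malformed rows are named."""
    trials = pd.read_csv(path)
    missing = set(synthetic.TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")
    for col in NUMERIC_COLUMNS:
        numeric = pd.to_numeric(trials[col], errors="coerce")
        bad = numeric.isna() & trials[col].notna()
        if bad.any():
            rows = (trials.index[bad] + 2).tolist()[:5]  # 1-based incl. header
            raise SchemaError(f"non-numeric values in column {col!r} at line(s) {rows}")
        if numeric.isna().any():
            rows = (trials.index[numeric.isna()] + 2).tolist()[:5]
            raise SchemaError(f"missing values in column {col!r} at line(s) {rows}")
        trials[col] = numeric
    bad_type = ~trials["judgment_type"].isin(synthetic.JUDGMENT_TYPES)
    if bad_type.any():
        rows = (trials.index[bad_type] + 2).tolist()[:5]
        raise SchemaError(f"unknown judgment_type at line(s) {rows}")
    return trials


def run_analyze(config: RunConfig, trials: pd.DataFrame, out_dir=None) -> dict:
    """Screen, estimate and summarise a trial table.

    Returns ``{"estimates", "summary", "rotation_sd", "sequential"}`` as
    DataFrames and, if ``out_dir`` is given, writes each as CSV.
    """
    estimates = estimation.estimate_participants(
        trials,
        screen_trials=config.screen_trials,
        screen_participants=config.screen_participants,
    )
    retained = set(estimates.loc[~estimates["excluded"], "participant"])
    summary = estimation.summarize_group(estimates, trials)
    with_hist = sequential.add_history_columns(
        trials[trials["participant"].isin(retained)],
        repeat_threshold=config.repeat_threshold,
    )
    seq = sequential.subset_biases(with_hist, repeat_threshold=config.repeat_threshold)
    result = {
        "estimates": estimates,
        "summary": summary["biases"],
        "rotation_sd": estimation.participant_rotation_sd(trials, retained),
        "sequential": seq,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in result.items():
            frame.to_csv(out / f"{name}.csv", index=False, lineterminator="\n")
        logger.info("analysis tables written to %s", out)
    return result


def _anova_rows(results, analysis: str) -> list[dict]:
    return [{"analysis": analysis, **r.as_dict()} for r in results]


def run_report(
    config: RunConfig,
    estimates: pd.DataFrame,
    rotation_sd: pd.DataFrame | None = None,
    sequential_biases: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full inferential battery over saved analysis tables.

    Emits a tidy results table: the 2 (group) × 2 (cursor vs hand explicit)
    bias ANOVA, the 2 × 2 (explicit vs implicit hand) ANOVA, one-sample
    t-tests of slopes and intercepts against zero, implicit–explicit bias
    correlations per group, the 2 × 3 × 12 variability ANOVA, and the
    sequential-effect ANOVAs.
    """
    retained = estimates[~estimates["excluded"]] if "excluded" in estimates else estimates
    if retained["group"].nunique() < 2:
        raise ValueError("report requires at least two groups")
    if (retained.groupby(["group", "kind"])["participant"].nunique() < 2).any():
        raise ValueError("report requires >= 2 participants per group and kind")
    rows: list[dict] = []

    # bias ANOVAs on slopes
    explicit = retained[retained["kind"].isin(["cursor_explicit", "hand_explicit"])]
    rows += _anova_rows(
        group_stats.mixed_anova(
            explicit, "slope", "participant", "group", ["kind"],
            correction=config.anova_correction,
        ),
        "bias: group x judgment type (explicit)",
    )
    hand = retained[retained["kind"].isin(["hand_explicit", "hand_implicit"])]
    rows += _anova_rows(
        group_stats.mixed_anova(
            hand, "slope", "participant", "group", ["kind"],
            correction=config.anova_correction,
        ),
        "bias: group x judgment type (hand explicit vs implicit)",
    )

    # one-sample t-tests of slopes per group x kind, intercepts pooled
    for (group, kind), sub in retained.groupby(["group", "kind"]):
        t = group_stats.one_sample_t(sub["slope"], label=f"slope {group}/{kind} vs 0")
        rows.append({"analysis": "slope vs zero", **t.as_dict()})
    for kind, sub in retained.groupby("kind"):
        t = group_stats.one_sample_t(sub["intercept"], label=f"intercept {kind} vs 0")
        rows.append({"analysis": "offset vs zero", **t.as_dict()})

    # implicit-explicit correlations per group
    wide = retained.pivot(index=["participant", "group"], columns="kind", values="slope")
    for group, sub in wide.groupby(level="group"):
        for other in ("hand_explicit", "cursor_explicit"):
            r = group_stats.pearson_corr(
                sub["hand_implicit"], sub[other],
                label=f"implicit vs {other} ({group})",
            )
            rows.append({"analysis": "bias correlation", **r.as_dict()})

    # intra-individual variability: group x kind x rotation
    if rotation_sd is not None and not rotation_sd.empty:
        rows += _anova_rows(
            group_stats.mixed_anova(
                rotation_sd, "sd", "participant", "group", ["kind", "rotation_deg"],
                correction=config.anova_correction,
            ),
            "variability: group x judgment type x rotation",
        )

    # sequential-effect ANOVAs (bias strength: cursor slopes sign-flipped)
    if sequential_biases is not None and not sequential_biases.empty:
        seq = sequential_biases.copy()
        seq.loc[seq["kind"] == "cursor_explicit", "slope"] *= -1.0
        for kinds, label in [
            (["cursor_explicit", "hand_explicit"], "sequential: explicit biases"),
            (["hand_explicit", "hand_implicit"], "sequential: hand explicit vs implicit"),
        ]:
            sub = seq[seq["kind"].isin(kinds)]
            counts = sub.groupby("participant").size()
            full = counts[counts == 8].index  # 2 kinds x 2 prev x 2 repetition
            dropped = counts.index.difference(full)
            if len(dropped):
                logger.info("sequential ANOVA drops incomplete participants %s",
                            list(dropped))
            sub = sub[sub["participant"].isin(full)]
            rows += _anova_rows(
                group_stats.mixed_anova(
                    sub, "slope", "participant", "group",
                    ["kind", "preceding_type", "repetition"],
                    correction=config.anova_correction,
                ),
                label,
            )
    report = pd.DataFrame(rows)
    cols = ["analysis", "effect", "statistic", "df", "df1", "df2", "p"]
    return report[[c for c in cols if c in report.columns]]
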