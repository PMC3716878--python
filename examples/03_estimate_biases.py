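"""Full cohort analysis: screening, bias estimation, group summaries, tests.

Simulates the default cohort (16 young + 19 older participants), removes
trial and participant outliers, regresses each participant's judgment
deviations on the feedback rotation, and prints the group-mean proportional
biases with the main inferential tests.
"""

from vpcoupling import (
    RunConfig,
    estimate_participants,
    run_report,
    simulate_cohort,
    summarize_group,
)
from vpcoupling.estimation import participant_rotation_sd
from vpcoupling.sequential import add_history_columns, subset_biases

trials = simulate_cohort(master_seed=1)
estimates = estimate_participants(trials)
summary = summarize_group(estimates)["biases"]

print("group-mean proportional biases (slope, deg/deg) ± SE:")
for _, row in summary.iterrows():
    print(f"  {row['group']:>5} {row['kind']:<16} "
          f"{row['slope_mean']:+.3f} ± {row['slope_se']:.3f}")

removed = estimates["n_trials_removed"].sum()
total = removed + estimates["n_trials_used"].sum()
print(f"\ntrial outliers removed: {removed} of {total} ({100 * removed / total:.2f}%)")

stats = run_report(
    RunConfig(),
    estimates,
    participant_rotation_sd(trials),
    subset_biases(add_history_columns(trials)),
)
bias_anova = stats[stats["analysis"] == "bias: group x judgment type (explicit)"]
print("\n2 (group) x 2 (judgment type) ANOVA on explicit biases:")
print(bias_anova[["effect", "statistic", "df1", "df2", "p"]].to_string(index=False))
# A slope near 1 would mean full visual capture of the felt hand direction;
# the hand bias ~0.6-0.75 with cursor bias ~ -0.1 shows strong but partial,
# asymmetric coupling (their magnitudes sum to less than 1).
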