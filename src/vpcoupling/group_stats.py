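"""Inferential statistics for the bias analyses.

One-sample t-tests against zero (slopes/intercepts), Pearson correlations
between bias measures, Bonferroni-corrected pairwise t-tests, and a balanced
mixed-design ANOVA with one between-participant factor (age group) crossed
with an arbitrary number of within-participant factors (judgment type,
rotation, preceding-trial type, repetition, ...).

The ANOVA uses the classical univariate sums-of-squares decomposition for
balanced designs with subjects nested in the between factor.  Each
within-effect combination V (including its interaction with the group factor)
is tested against the V × subject-within-group stratum; the group main effect
is tested against subjects-within-groups.  Sphericity corrections are not
applied by default; a Greenhouse–Geisser option exists for the curious but is
off for fidelity to the uncorrected univariate F's this analysis reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "one_sample_t",
    "pearson_corr",
    "bonferroni_pairwise",
    "mixed_anova",
]


@dataclass(frozen=True)
class TestResult:
    """One inferential test: statistic, degrees of freedom, p-value."""

    effect: str
    statistic: float
    df: tuple
    p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    def as_dict(self) -> dict:
        d = {"effect": self.effect, "statistic": self.statistic, "p": self.p}
        if len(self.df) == 1:
            d["df"] = self.df[0]
        else:
            d["df1"], d["df2"] = self.df
        return d


def one_sample_t(values, mu0: float = 0.0, label: str = "mean vs mu0") -> TestResult:
    """Two-sided one-sample t-test of the mean against ``mu0``."""
    v = np.asarray(values, float)
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    if np.ptp(v) == 0:
        raise ValueError("zero variance: t-test undefined")
    t, p = stats.ttest_1samp(v, mu0)
    return TestResult(label, float(t), (len(v) - 1,), float(p))


def pearson_corr(x, y, label: str = "r") -> TestResult:
    """Pearson correlation with a two-sided p from the t transform."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(x, y)
    return TestResult(label, float(r), (len(x) - 2,), float(p))


def bonferroni_pairwise(
    cells: dict, paired: bool = False, alpha: float = 0.05
) -> list[TestResult]:
    """All pairwise t-tests between named cells, Bonferroni-corrected.

    Raw two-sided p-values are multiplied by the number of comparisons and
    capped at 1.  ``paired=True`` uses paired t-tests (cells must align).
    """
    names = list(cells)
    if len(names) < 2:
        raise ValueError("need at least 2 cells")
    pairs = list(combinations(names, 2))
    m = len(pairs)
    results = []
    for a, b in pairs:
        va, vb = np.asarray(cells[a], float), np.asarray(cells[b], float)
        if paired:
            diff = va - vb
            if np.ptp(diff) == 0:
                t, p, df = 0.0, 1.0, len(diff) - 1
            else:
                t, p = stats.ttest_rel(va, vb)
                df = len(diff) - 1
        else:
            t, p = stats.ttest_ind(va, vb)
            df = len(va) + len(vb) - 2
        results.append(
            TestResult(f"{a} vs {b}", float(t), (df,), min(float(p) * m, 1.0))
        )
    return results


def _margin_sum(df: pd.DataFrame, dv: str, cols: tuple) -> float:
    """Sum over margin cells of n_cell · mean_cell² (the 'M' functional)."""
    if not cols:
        return len(df) * df[dv].mean() ** 2
    g = df.groupby(list(cols), observed=True)[dv]
    return float((g.size() * g.mean() ** 2).sum())


def _gg_epsilon(data, dv, subject, between, V) -> float:
    """Greenhouse–Geisser epsilon for within-effect V (cells averaged over
    the remaining within factors; covariance pooled within groups)."""
    wide = data.pivot_table(index=subject, columns=list(V), values=dv, observed=True)
    groups = data.groupby(subject, observed=True)[between].first().loc[wide.index]
    k = wide.shape[1]
    pooled = np.zeros((k, k))
    dof = 0
    for _, sub in wide.groupby(groups.values):
        centered = sub.to_numpy() - sub.to_numpy().mean(axis=0)
        pooled += centered.T @ centered
        dof += len(sub) - 1
    s = pooled / dof
    # orthonormal contrasts: any basis of the mean-zero subspace works
    q, _ = np.linalg.qr(np.vstack([np.eye(k - 1), -np.ones(k - 1)]))
    a = q.T @ s @ q
    return float(np.trace(a) ** 2 / ((k - 1) * np.sum(a * a)))


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    between: str,
    within: list[str],
    correction: str | None = None,
) -> list[TestResult]:
    """Balanced mixed-design ANOVA: one between factor, crossed within factors.

    ``data`` is long-format with exactly one observation per subject per
    within-cell; subjects are nested in ``between``.  Returns a
    :class:`TestResult` per main effect and interaction (between, each within
    combination, and each within × between combination).
    ``correction="gg"`` applies the Greenhouse–Geisser sphericity correction
    to within-effect p-values; the default reports uncorrected univariate F's.

    Raises ``ValueError`` if the design is unbalanced or has missing cells.
    """
    within = list(within)
    cells = data.groupby([subject] + within, observed=True)[dv].size()
    if (cells != 1).any():
        raise ValueError("design must have exactly one observation per subject × cell")
    n_cells_expected = int(np.prod([data[w].nunique() for w in within])) if within else 1
    per_subj = data.groupby(subject, observed=True)[dv].size()
    if (per_subj != n_cells_expected).any():
        raise ValueError("missing within-cells: unbalanced design")
    groups_of = data.groupby(subject, observed=True)[between].nunique()
    if (groups_of != 1).any():
        raise ValueError("each subject must belong to exactly one group")

    n_subj = data[subject].nunique()
    n_groups = data[between].nunique()
    levels = {w: data[w].nunique() for w in within}

    def M(cols) -> float:
        return _margin_sum(data, dv, tuple(cols))

    def ie_sum(V, extra=()) -> float:
        """Inclusion–exclusion SS of effect V, each margin augmented by `extra`."""
        total = 0.0
        for k in range(len(V) + 1):
            for B in combinations(V, k):
                total += (-1) ** (len(V) - len(B)) * M(tuple(B) + tuple(extra))
        return total

    results = []
    # between main effect, tested against subjects within groups; with a
    # single group the design degenerates to repeated measures and the
    # between test is skipped
    def safe_f(ss_effect, df_effect, ms_error):
        # SS can come out as a tiny negative from cancellation; clamp, and
        # treat a zero effect SS as F = 0 even when the error stratum is empty
        ss_effect = max(ss_effect, 0.0)
        if ss_effect == 0.0:
            return 0.0
        return (ss_effect / df_effect) / ms_error if ms_error > 0 else np.inf

    if n_groups >= 2:
        ss_g = ie_sum((between,))
        ss_sg = M((subject,)) - M((between,))
        df_g, df_sg = n_groups - 1, n_subj - n_groups
        f = safe_f(ss_g, df_g, ss_sg / df_sg)
        results.append(
            TestResult(
                between, float(f), (df_g, df_sg), float(stats.f.sf(f, df_g, df_sg))
            )
        )

    # every within-effect combination V: V and V×group vs V×subject(group)
    for k in range(1, len(within) + 1):
        for V in combinations(within, k):
            df_v = int(np.prod([levels[w] - 1 for w in V]))
            ss_v = ie_sum(V)
            ss_vg = ie_sum(tuple(V) + (between,))
            # error stratum: V × subjects within groups
            ss_err = sum(
                (-1) ** (len(V) - len(B))
                * (M(tuple(B) + (subject,)) - M(tuple(B) + (between,)))
                for kk in range(len(V) + 1)
                for B in combinations(V, kk)
            )
            df_err = df_v * (n_subj - n_groups)
            ms_err = ss_err / df_err
            eps = 1.0
            if correction == "gg" and df_v > 1:
                eps = _gg_epsilon(data, dv, subject, between, V)
            f_v = safe_f(ss_v, df_v, ms_err)
            results.append(
                TestResult(
                    " * ".join(V), float(f_v), (df_v, df_err),
                    float(stats.f.sf(f_v, eps * df_v, eps * df_err)),
                )
            )
            if n_groups >= 2:
                df_vg = df_v * (n_groups - 1)
                f_vg = safe_f(ss_vg, df_vg, ms_err)
                results.append(
                    TestResult(
                        " * ".join(V + (between,)), float(f_vg), (df_vg, df_err),
                        float(stats.f.sf(f_vg, eps * df_vg, eps * df_err)),
                    )
                )
    return results
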