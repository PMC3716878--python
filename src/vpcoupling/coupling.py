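"""Weighted-average model of sensory coupling and its variance-reduction curves.

Two sensory signals refer to related but distinct spatial characteristics —
here the proprioceptively felt hand direction and the visually seen cursor
direction.  Instead of fusing into one percept, each estimate is pulled toward
the other by a proportional bias ``b``:

    biased_own = (1 − b) · own + b · other,     0 ≤ b ≤ 1.

With independent zero-mean noises the variance of the biased estimate,
relative to the unbiased own-modality variance, is

    var(biased)/var(own) = (1 − b)² + b² · r,   r = var(other)/var(own),

which dips below 1 for any 0 < b < 2/(1+r): even a weak coupling reduces
variability, including for the more precise modality.  The minimum sits at
b* = 1/(1+r) with relative variance r/(1+r) — the classic inverse-variance
weighting, recovered here as the optimal degree of partial coupling.

An optional noise correlation ``rho`` generalises the formula; it defaults to
zero (independent noises).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CouplingParams",
    "coupled_estimate",
    "relative_variance",
    "optimal_bias",
    "variance_reduction_grid",
]


@dataclass(frozen=True)
class CouplingParams:
    """Coupling parameters: bias and the two modality noise variances (deg²)."""

    b: float
    var_self: float
    var_other: float
    r: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.b <= 1.0:
            raise ValueError("bias b must lie in [0, 1]")
        if self.var_self <= 0:
            raise ValueError("var_self must be positive")
        if self.var_other < 0:
            raise ValueError("var_other must be non-negative")
        object.__setattr__(self, "r", self.var_other / self.var_self)


def coupled_estimate(own, other, b):
    """Weighted-average coupled estimate (1−b)·own + b·other, degrees."""
    b = np.asarray(b, dtype=float)
    if np.any((b < 0) | (b > 1)):
        raise ValueError("bias b must lie in [0, 1]")
    out = (1.0 - b) * np.asarray(own, float) + b * np.asarray(other, float)
    return out if out.ndim else float(out)


def relative_variance(b, r, rho: float = 0.0):
    """Variance of the coupled estimate relative to the unbiased own-modality variance.

    Parameters
    ----------
    b : float or array
        Proportional bias toward the other modality, in [0, 1].
    r : float or array
        Variance ratio var(other)/var(own), ≥ 0.
    rho : float, optional
        Correlation between the two modality noises; 0 (default) assumes
        independent noises.

    Returns
    -------
    (1−b)² + b²·r + 2·rho·b·(1−b)·√r
    """
    b = np.asarray(b, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("variance ratio r must be non-negative")
    if not -1.0 <= rho <= 1.0:
        raise ValueError("noise correlation rho must lie in [-1, 1]")
    out = (1.0 - b) ** 2 + b**2 * r + 2.0 * rho * b * (1.0 - b) * np.sqrt(r)
    return out if out.ndim else float(out)


def optimal_bias(r) -> tuple[float, float]:
    """Bias minimising the relative variance, and the minimum itself.

    With independent noises the optimum is b* = 1/(1+r), where the relative
    variance equals r/(1+r): inverse-variance weighting.
    """
    r = float(r)
    if r < 0:
        raise ValueError("variance ratio r must be non-negative")
    b_star = 1.0 / (1.0 + r)
    return b_star, r / (1.0 + r)


def variance_reduction_grid(
    biases=None, ratios=(0.2, 0.3, 0.4, 0.5, 0.6, 0.7)
) -> pd.DataFrame:
    """Tidy grid of relative variances over bias × variance-ratio combinations.

    Defaults reproduce the textbook family of curves: bias 0..1 in steps of
    0.01, ratios 0.2..0.7.  One row per (bias, ratio) with the relative
    variance of the coupled estimate.
    """
    if biases is None:
        biases = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)
    b, r = np.meshgrid(np.asarray(biases, float), np.asarray(ratios, float))
    return pd.DataFrame(
        {
            "bias": b.ravel(),
            "variance_ratio": r.ravel(),
            "relative_variance": relative_variance(b, r).ravel(),
        }
    )
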