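"""Differential-susceptibility vs diathesis-stress indices for a fitted
crossover interaction.

Given the model Y = b0 + b1*X + b2*Z + b3*X*Z, the group difference at
environment value x is b2 + b3*x.  The module computes, over an
evaluation range conventionally set to the environment mean +- 2 SD:

* the crossover point -b2/b3 where the two group lines intersect;
* Johnson-Neyman regions of significance on X (the x values beyond which
  the group difference is significant at level alpha);
* PoI, the fraction of the total between-line area lying on the
  "for-better" side of the crossover (0.40-0.60 suggests differential
  susceptibility, near 0 diathesis-stress);
* PA, the proportion of a normally distributed environment falling on the
  for-better side of the crossover (> 0.16 supports differential
  susceptibility, < 0.02 diathesis-stress);
* a pattern label combining these verdicts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .exceptions import NoInteractionError
from .regression import GxEResults


@dataclass(frozen=True)
class EnvironmentSummary:
    """Environment distribution summary and evaluation range.

    The range defaults to mean +- 2 SD; explicit bounds override it (the
    override is needed to reproduce published tables computed on a fixed
    printed range).
    """

    mean: float
    sd: float
    x_lower: float = None
    x_upper: float = None

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("environment SD must be positive")
        if self.x_lower is None:
            object.__setattr__(self, "x_lower", self.mean - 2 * self.sd)
        if self.x_upper is None:
            object.__setattr__(self, "x_upper", self.mean + 2 * self.sd)
        if not self.x_lower < self.x_upper:
            raise ValueError("evaluation range must have x_lower < x_upper")

    @classmethod
    def from_sample(cls, x, range_override=None) -> "EnvironmentSummary":
        x = np.asarray(x, float)
        lo, hi = (None, None) if range_override is None else range_override
        return cls(
            mean=float(x.mean()), sd=float(x.std(ddof=1)), x_lower=lo, x_upper=hi
        )


@dataclass(frozen=True)
class OutcomePolarity:
    """Whether larger outcome values are worse (true for symptom scales)."""

    higher_is_worse: bool = True


@dataclass(frozen=True)
class RegionsOfSignificance:
    """Johnson-Neyman bounds on X and within-range side significance.

    The group difference is significant for x below ``lower`` and above
    ``upper``.  ``left_significant`` / ``right_significant`` report
    whether those regions intrude into the evaluation range.  When the
    boundaries are not finite (degenerate quadratic), side significance
    falls back to pointwise tests at the range endpoints and the bounds
    are ``None``.
    """

    lower: Optional[float]
    upper: Optional[float]
    left_significant: bool
    right_significant: bool
    t_crit: float
    alpha: float
    fallback: bool = False


def crossover(fit: GxEResults, tol: float = 1e-8) -> float:
    """Environment value -b2/b3 at which the two group lines intersect."""
    b2 = float(fit.params["z"])
    b3 = float(fit.params["x:z"])
    if b3 == 0:
        raise NoInteractionError("b3 = 0: parallel lines have no crossover")
    if abs(b3) < tol * abs(b2):
        warnings.warn(
            "interaction coefficient is vanishingly small relative to the "
            "moderator main effect; the crossover lies far outside any "
            "plausible environment range",
            stacklevel=2,
        )
    return -b2 / b3


def ros_on_x(
    fit: GxEResults, env: EnvironmentSummary, alpha: float = 0.05
) -> RegionsOfSignificance:
    """Regions of significance on X for the group difference b2 + b3*x.

    Solves (b2 + b3 x)^2 = t^2 (var(b2) + x^2 var(b3) + 2 x cov(b2, b3)),
    a quadratic in x, with t the two-sided critical value at ``alpha`` on
    the fit's residual df.  A side counts as significant when its region
    falls inside the evaluation range.
    """
    cov = fit.cov_params()
    if fit.df_resid is None or fit.df_resid < 1:
        raise ValueError("regions of significance require residual df >= 1")
    b2 = float(fit.params["z"])
    b3 = float(fit.params["x:z"])
    v22 = float(cov.loc["z", "z"])
    v33 = float(cov.loc["x:z", "x:z"])
    v23 = float(cov.loc["z", "x:z"])
    t_crit = float(stats.t.ppf(1 - alpha / 2, fit.df_resid))
    t2 = t_crit * t_crit

    def pointwise_significant(x: float) -> bool:
        diff = b2 + b3 * x
        var = v22 + x * x * v33 + 2 * x * v23
        if var <= 0:
            return diff != 0
        return diff * diff > t2 * var

    a = b3 * b3 - t2 * v33
    b = 2 * (b2 * b3 - t2 * v23)
    c = b2 * b2 - t2 * v22
    disc = b * b - 4 * a * c
    if a > 0 and disc >= 0:
        root = np.sqrt(disc)
        r1 = (-b - root) / (2 * a)
        r2 = (-b + root) / (2 * a)
        lower, upper = (r1, r2) if r1 <= r2 else (r2, r1)
        return RegionsOfSignificance(
            lower=float(lower),
            upper=float(upper),
            left_significant=bool(lower > env.x_lower),
            right_significant=bool(upper < env.x_upper),
            t_crit=t_crit,
            alpha=alpha,
        )
    # No finite boundaries (difference significant nowhere or everywhere,
    # or the interaction itself is not significant): fall back to direct
    # tests at the range endpoints.
    return RegionsOfSignificance(
        lower=None,
        upper=None,
        left_significant=pointwise_significant(env.x_lower),
        right_significant=pointwise_significant(env.x_upper),
        t_crit=t_crit,
        alpha=alpha,
        fallback=True,
    )


def for_better_side(fit: GxEResults, polarity: OutcomePolarity) -> str:
    """Side of the crossover on which risk carriers fare *better*.

    With a higher-is-worse outcome and b3 < 0 the risk group's predicted
    outcome drops below the reference group's for x above the crossover,
    so the for-better side is the right side (the configuration of all
    published fits this package mirrors); the rule generalizes to the
    mirrored cases.
    """
    b3 = float(fit.params["x:z"])
    if b3 == 0:
        raise NoInteractionError("b3 = 0: no for-better side exists")
    if polarity.higher_is_worse:
        return "right" if b3 < 0 else "left"
    return "left" if b3 < 0 else "right"


def poi(
    fit: GxEResults,
    env: EnvironmentSummary,
    polarity: OutcomePolarity = OutcomePolarity(),
) -> float:
    """Proportion of Interaction: for-better share of the between-line area.

    For straight lines the area between the group lines on each side of
    the crossover xc is a triangle proportional to the squared distance
    from xc to the range edge, so the right-side share reduces to
    (x_upper - xc)^2 / [(x_upper - xc)^2 + (xc - x_lower)^2].  A crossover
    outside the range clamps the index to 0 or 1.
    """
    xc = crossover(fit)
    side = for_better_side(fit, polarity)
    if xc <= env.x_lower:
        right_share = 1.0
    elif xc >= env.x_upper:
        right_share = 0.0
    else:
        right = (env.x_upper - xc) ** 2
        left = (xc - env.x_lower) ** 2
        right_share = right / (right + left)
    return right_share if side == "right" else 1.0 - right_share


def pa(
    crossover_point: float,
    env: EnvironmentSummary,
    polarity: OutcomePolarity = OutcomePolarity(),
    side: str = "right",
) -> float:
    """Proportion Affected: normal-model share of individuals on the
    for-better side of the crossover, 1 - Phi((xc - mean)/sd) when the
    for-better side is the right side."""
    if side not in ("right", "left"):
        raise ValueError("side must be 'right' or 'left'")
    upper_tail = float(stats.norm.sf((crossover_point - env.mean) / env.sd))
    return upper_tail if side == "right" else 1.0 - upper_tail


@dataclass(frozen=True)
class DSIndices:
    """Bundle of susceptibility indices and the resulting pattern label."""

    crossover: float
    ros_lower: Optional[float]
    ros_upper: Optional[float]
    left_side_significant: bool
    right_side_significant: bool
    poi: float
    pa: float
    for_better_side: str
    alpha: float
    pattern: str = "inconclusive"


def classify_pattern(indices: DSIndices) -> str:
    """Label the interaction pattern from the component verdicts.

    differential_susceptibility: both sides significant, 0.40 <= PoI <= 0.60
    and PA > 0.16; diathesis_stress: only the negative-environment side
    significant and PoI < 0.40; vantage_sensitivity: only the positive
    side significant and PoI > 0.60; anything else is inconclusive.
    """
    left = indices.left_side_significant
    right = indices.right_side_significant
    if left and right and 0.40 <= indices.poi <= 0.60 and indices.pa > 0.16:
        return "differential_susceptibility"
    if left and not right and indices.poi < 0.40:
        return "diathesis_stress"
    if right and not left and indices.poi > 0.60:
        return "vantage_sensitivity"
    return "inconclusive"


def compute_indices(
    fit: GxEResults,
    env: EnvironmentSummary,
    polarity: OutcomePolarity = OutcomePolarity(),
    alpha: float = 0.05,
) -> DSIndices:
    """Crossover, RoS-on-X, PoI, PA and pattern label for a fitted model."""
    xc = crossover(fit)
    side = for_better_side(fit, polarity)
    ros = ros_on_x(fit, env, alpha=alpha)
    out = DSIndices(
        crossover=xc,
        ros_lower=ros.lower,
        ros_upper=ros.upper,
        left_side_significant=ros.left_significant,
        right_side_significant=ros.right_significant,
        poi=poi(fit, env, polarity),
        pa=pa(xc, env, polarity, side=side),
        for_better_side=side,
        alpha=alpha,
    )
    return DSIndices(**{**out.__dict__, "pattern": classify_pattern(out)})


def plot_interaction(
    fit: GxEResults,
    env: EnvironmentSummary,
    indices: DSIndices | None = None,
    path=None,
):
    """Group regression lines over the evaluation range with the crossover
    marked and significant regions shaded.  Returns the Figure (and writes
    ``path`` when given).  Deterministic for identical inputs."""
    from matplotlib.figure import Figure

    b0, b1, b2, b3 = fit.b
    xs = np.linspace(env.x_lower, env.x_upper, 200)
    fig = Figure(figsize=(6, 4))
    ax = fig.add_subplot(111)
    ax.plot(xs, b0 + b1 * xs, color="tab:blue", label="non-risk group (Z=0)")
    ax.plot(
        xs, (b0 + b2) + (b1 + b3) * xs, color="black", label="risk carriers (Z=1)"
    )
    if indices is not None:
        if env.x_lower < indices.crossover < env.x_upper:
            ax.axvline(indices.crossover, color="gray", linestyle=":", linewidth=1)
        if indices.left_side_significant:
            right_edge = (
                min(indices.ros_lower, env.x_upper)
                if indices.ros_lower is not None
                else min(indices.crossover, env.x_upper)
            )
            ax.axvspan(env.x_lower, right_edge, color="0.85", zorder=0)
        if indices.right_side_significant:
            left_edge = (
                max(indices.ros_upper, env.x_lower)
                if indices.ros_upper is not None
                else max(indices.crossover, env.x_lower)
            )
            ax.axvspan(left_edge, env.x_upper, color="0.85", zorder=0)
    ax.set_xlabel("environment score (X)")
    ax.set_ylabel("predicted outcome")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
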