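"""Expected value of control (EVC) under joint reward and efficacy incentives.

The model formalizes how much cognitive control is worth investing on a cued
incentive trial.  A control intensity ``u`` on [0, 1] buys a higher chance of
meeting the speed/accuracy criterion, at a quadratic effort cost.  The payoff
of ``u`` mixes two routes to reward: with probability ``efficacy`` the outcome
is determined by performance, otherwise reward arrives at a fixed,
performance-independent base rate (the yoked route).  The allocated control is
the grid argmax of ``EVC(u) = payoff(u) - cost(u)``.

Success probability is logistic in control, shifted down one step per level of
Stroop interference (congruent < neutral < incongruent).  An intrinsic value
of responding accurately (independent of money) keeps the optimum above zero
even when efficacy is nil, reflecting the residual effort people invest in
fully non-contingent conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "CONGRUENCY_LEVELS",
    "IncentiveCondition",
    "EvcParams",
    "EvcCurve",
    "success_probability",
    "payoff",
    "evc_curve",
    "optimal_control_surface",
]

#: Stroop congruency levels in increasing order of control demand.
CONGRUENCY_LEVELS = ("congruent", "neutral", "incongruent")


def _congruency_step(congruency: str) -> int:
    try:
        return CONGRUENCY_LEVELS.index(congruency)
    except ValueError:
        raise ValueError(
            f"unknown congruency {congruency!r}; expected one of {CONGRUENCY_LEVELS}"
        ) from None


@dataclass(frozen=True)
class IncentiveCondition:
    """Reward magnitude (dollars) and efficacy (probability) cued on a trial."""

    reward_magnitude: float
    efficacy: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficacy <= 1.0:
            raise ValueError(f"efficacy must be in [0, 1], got {self.efficacy}")
        if self.reward_magnitude < 0:
            raise ValueError(
                f"reward_magnitude must be >= 0, got {self.reward_magnitude}"
            )


@dataclass(frozen=True)
class EvcParams:
    """Parameters of the control-allocation model.

    cost_coefficient
        Curvature of the quadratic effort cost ``c * u**2`` (currency units).
    performance_intercept, performance_slope
        Log-odds intercept/slope of criterion success in control intensity.
    congruency_penalty
        Log-odds decrement per congruency step (congruent -> neutral -> incongruent).
    intrinsic_accuracy_value
        Currency-equivalent value of an accurate response regardless of payout;
        keeps allocated control positive at zero efficacy.
    noncontingent_reward_rate
        Fixed reward probability on the performance-independent route.
    """

    cost_coefficient: float = 0.5
    performance_intercept: float = -1.0
    performance_slope: float = 4.0
    congruency_penalty: float = 1.0
    intrinsic_accuracy_value: float = 0.05
    noncontingent_reward_rate: float = 0.7

    def __post_init__(self) -> None:
        vals = (
            self.cost_coefficient,
            self.performance_intercept,
            self.performance_slope,
            self.congruency_penalty,
            self.intrinsic_accuracy_value,
            self.noncontingent_reward_rate,
        )
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("all EvcParams fields must be finite")
        if self.performance_slope <= 0:
            raise ValueError("performance_slope must be > 0")
        if self.cost_coefficient < 0 or self.congruency_penalty < 0:
            raise ValueError("cost_coefficient and congruency_penalty must be >= 0")
        if self.intrinsic_accuracy_value < 0:
            raise ValueError("intrinsic_accuracy_value must be >= 0")
        if not 0.0 <= self.noncontingent_reward_rate <= 1.0:
            raise ValueError("noncontingent_reward_rate must be in [0, 1]")


@dataclass
class EvcCurve:
    """Payoff, cost and EVC evaluated on a control grid, with the argmax."""

    control_grid: np.ndarray
    payoff: np.ndarray
    cost: np.ndarray
    evc: np.ndarray = field(init=False)
    u_star: float = field(init=False)

    def __post_init__(self) -> None:
        self.evc = self.payoff - self.cost
        # ties broken toward the smallest u: argmax returns the first maximum
        self.u_star = float(self.control_grid[int(np.argmax(self.evc))])

    def to_frame(self):
        """Tabular view with columns u, payoff, cost, evc (CSV-ready)."""
        import pandas as pd

        return pd.DataFrame({
            "u": self.control_grid, "payoff": self.payoff,
            "cost": self.cost, "evc": self.evc,
        })


def success_probability(u, congruency: str, params: EvcParams):
    """Probability of meeting the speed/accuracy criterion at control ``u``.

    Logistic in control intensity, penalized one log-odds step per congruency
    level.  Accepts scalar or array ``u`` in [0, 1].
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or np.any(u > 1):
        raise ValueError("control intensity u must lie in [0, 1]")
    k = _congruency_step(congruency)
    lp = (
        params.performance_intercept
        + params.performance_slope * u
        - params.congruency_penalty * k
    )
    out = expit(lp)
    return float(out) if out.ndim == 0 else out


def payoff(u, cond: IncentiveCondition, params: EvcParams, congruency: str = "neutral"):
    """Expected payoff of control ``u`` under a reward x efficacy condition.

    ``R * [E * P(u) + (1 - E) * base_rate] + intrinsic_value * P(u)``: reward is
    earned through performance with probability ``efficacy`` and through the
    fixed-rate route otherwise; accurate responding carries an intrinsic value
    regardless of the monetary route.
    """
    p = success_probability(u, congruency, params)
    contingent = cond.efficacy * p + (1.0 - cond.efficacy) * params.noncontingent_reward_rate
    return cond.reward_magnitude * contingent + params.intrinsic_accuracy_value * p


def evc_curve(
    cond: IncentiveCondition,
    params: EvcParams,
    congruency: str = "neutral",
    grid_size: int = 101,
) -> EvcCurve:
    """Evaluate payoff, quadratic cost and EVC on an even grid over [0, 1].

    ``u_star`` is the grid argmax of EVC, ties broken toward smaller control
    (effort is costly, so the cheaper optimum is taken).
    """
    if grid_size < 2:
        raise ValueError(f"grid_size must be >= 2, got {grid_size}")
    grid = np.linspace(0.0, 1.0, grid_size)
    pay = payoff(grid, cond, params, congruency)
    cost = params.cost_coefficient * grid**2
    return EvcCurve(control_grid=grid, payoff=pay, cost=cost)


def optimal_control_surface(
    reward_levels,
    efficacy_levels,
    params: EvcParams,
    congruency: str = "neutral",
    grid_size: int = 101,
) -> np.ndarray:
    """Matrix of allocated control ``u_star`` over reward x efficacy levels.

    Rows index reward levels, columns efficacy levels.  Under the default
    parameterization the surface is nondecreasing along both axes: more money
    at stake, or a tighter link between performance and outcome, both raise
    the control worth investing.
    """
    reward_levels = list(reward_levels)
    efficacy_levels = list(efficacy_levels)
    if not reward_levels or not efficacy_levels:
        raise ValueError("reward_levels and efficacy_levels must be nonempty")
    surface = np.empty((len(reward_levels), len(efficacy_levels)))
    for i, r in enumerate(reward_levels):
        for j, e in enumerate(efficacy_levels):
            cond = IncentiveCondition(reward_magnitude=r, efficacy=e)
            surface[i, j] = evc_curve(cond, params, congruency, grid_size).u_star
    return surface
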