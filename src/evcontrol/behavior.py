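"""Trial-level behavior simulation: control allocation, RT, accuracy, reward.

Each subject allocates control ``u*`` per cued reward x efficacy condition by
maximizing EVC (congruency is unknown at cue time, so allocation assumes a
neutral target).  Reaction time decreases linearly in allocated control and
carries congruency costs, a practice trend, subject-level random variation and
right-skewed (shifted-lognormal, zero-mean) noise; responses slower than the
recording window are missing.  Accuracy follows the logistic success model at
the allocated control plus a subject-level accuracy bias.  Reward outcomes
implement the yoking procedure: on performance-determined trials a fast and
accurate response is always rewarded; otherwise reward is drawn at the rolling
reward rate of recent performance-determined trials (window 10), which equates
expected reward across efficacy levels.

Every planted coefficient is recorded so downstream model fits can be checked
against ground truth.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from ._rng import stream
from .design import DesignConfig
from .evc import CONGRUENCY_LEVELS, EvcParams, IncentiveCondition, evc_curve

__all__ = [
    "BehaviorParams",
    "SubjectParams",
    "draw_subjects",
    "centered_levels",
    "design_codes",
    "yoked_reward_probability",
    "allocated_control",
    "simulate_behavior",
]


@dataclass(frozen=True)
class BehaviorParams:
    """Population-level generator coefficients for behavior.

    RT units are ms; accuracy parameters are log-odds.  Congruency RT costs
    are the neutral-minus-congruent and incongruent-minus-neutral increments.
    Trend coefficients apply per within-subject SD of trial number.
    """

    rt_intercept: float = 650.0
    rt_control_gain: float = 15.0  # ms speeding per unit allocated control
    rt_congruency: tuple = (16.0, 64.0)  # (neutral - congruent, incongruent - neutral)
    rt_trend: float = -10.0
    rt_noise_sd: float = 90.0
    rt_lognorm_sigma: float = 0.4
    accuracy_offset: float = 2.5  # population accuracy bias added to the EVC log-odds
    accuracy_trend: float = 0.04
    # subject-level random variation (SDs of the multivariate-normal draws)
    rt_intercept_sd: float = 20.0
    rt_slope_sd: tuple = (2.0, 2.0, 3.0)  # reward, efficacy, interaction slopes
    accuracy_offset_sd: float = 0.3
    # control policy: "evc" allocates via the EVC model; "fixed" holds control
    # constant across conditions (used by null / type-I-error configurations)
    control_policy: str = "evc"
    fixed_control: float = 0.4
    yoking_window: int = 10
    yoking_cold_start: float = 0.5

    def __post_init__(self) -> None:
        if self.control_policy not in ("evc", "fixed"):
            raise ValueError("control_policy must be 'evc' or 'fixed'")
        if self.yoking_window < 0:
            raise ValueError("yoking_window must be >= 0")


@dataclass(frozen=True)
class SubjectParams:
    """One subject's random effects, drawn from the declared population."""

    subject: int
    rt_intercept: float
    rt_slope_reward: float
    rt_slope_efficacy: float
    rt_slope_interaction: float
    accuracy_intercept: float
    p3b_offset: float = 0.0
    cnv_offset: float = 0.0
    ern_offset: float = 0.0
    frn_offset: float = 0.0
    pupil_gain: float = 0.0


def draw_subjects(
    n_subjects: int, params: BehaviorParams, seed: int,
    erp_offset_sds=(1.5, 1.2, 1.0, 1.0), pupil_gain_sd: float = 0.15,
) -> list[SubjectParams]:
    """Draw per-subject random effects (independent normals, declared SDs)."""
    out = []
    for subject in range(1, n_subjects + 1):
        rng = stream(seed, "subject", subject)
        out.append(
            SubjectParams(
                subject=subject,
                rt_intercept=params.rt_intercept
                + rng.normal(0.0, params.rt_intercept_sd),
                rt_slope_reward=rng.normal(0.0, params.rt_slope_sd[0]),
                rt_slope_efficacy=rng.normal(0.0, params.rt_slope_sd[1]),
                rt_slope_interaction=rng.normal(0.0, params.rt_slope_sd[2]),
                accuracy_intercept=params.accuracy_offset
                + rng.normal(0.0, params.accuracy_offset_sd),
                p3b_offset=rng.normal(0.0, erp_offset_sds[0]),
                cnv_offset=rng.normal(0.0, erp_offset_sds[1]),
                ern_offset=rng.normal(0.0, erp_offset_sds[2]),
                frn_offset=rng.normal(0.0, erp_offset_sds[3]),
                pupil_gain=rng.normal(0.0, pupil_gain_sd),
            )
        )
    return out


def centered_levels(values: np.ndarray, levels) -> np.ndarray:
    """Center and scale factor levels so a 2-level factor codes to +/-0.5.

    ``(x - mean(levels)) / (max - min)``; for the dichotomous studies this is
    exactly +/-0.5 effect coding, for Study 3 it maps the four levels onto a
    comparable [-0.5, 0.5] span.
    """
    levels = np.asarray(sorted(set(levels)), dtype=float)
    span = levels.max() - levels.min()
    if span == 0:
        return np.zeros_like(np.asarray(values, dtype=float))
    return (np.asarray(values, dtype=float) - levels.mean()) / span


def design_codes(specs: pd.DataFrame, config: DesignConfig) -> pd.DataFrame:
    """Coded incentive/congruency/trend regressors shared by the generator
    and the ground-truth bookkeeping.

    Columns: ``rew_c, eff_c, inter`` (centered incentive codes), ``cong_step``
    (0/1/2), ``trial_c`` (trial number standardized within subject using the
    exact discrete-uniform mean/SD, so the coding is deterministic).
    """
    rew_c = centered_levels(specs.reward.to_numpy(), config.reward_levels)
    eff_c = centered_levels(specs.efficacy.to_numpy(), config.efficacy_levels)
    k = np.array([CONGRUENCY_LEVELS.index(c) for c in specs.congruency])
    n_per = specs.groupby("subject")["trial"].transform("count").to_numpy()
    trial_c = (specs.trial.to_numpy() - (n_per + 1) / 2.0) / np.sqrt(
        (n_per**2 - 1) / 12.0
    )
    return pd.DataFrame(
        {"rew_c": rew_c, "eff_c": eff_c, "inter": rew_c * eff_c,
         "cong_step": k, "trial_c": trial_c},
        index=specs.index,
    )


def yoked_reward_probability(high_eff_outcomes, window: int = 10,
                             cold_start: float = 0.5) -> float:
    """Reward probability for a non-contingent trial: rolling mean of the last
    ``window`` performance-determined criterion outcomes (0/1), or the
    cold-start default when no history exists."""
    if window < 0:
        raise ValueError("window must be >= 0")
    outcomes = list(high_eff_outcomes)
    if not outcomes:
        return float(cold_start)
    tail = outcomes[-window:] if window else []
    if not tail:
        return float(cold_start)
    return float(np.mean(tail))


def _shifted_lognormal_noise(rng, n, sd, sigma):
    """Zero-mean right-skewed noise with the requested SD."""
    raw = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    mu = np.exp(sigma**2 / 2.0)
    raw_sd = np.sqrt((np.exp(sigma**2) - 1.0) * np.exp(sigma**2))
    return (raw - mu) * (sd / raw_sd)


def allocated_control(
    reward: float, efficacy: float, evc_params: EvcParams, params: BehaviorParams
) -> float:
    """Control intensity the generator allocates for a cued condition."""
    if params.control_policy == "fixed":
        return params.fixed_control
    cond = IncentiveCondition(reward_magnitude=reward, efficacy=efficacy)
    return evc_curve(cond, evc_params, congruency="neutral").u_star


def simulate_behavior(
    specs: pd.DataFrame,
    subjects: list[SubjectParams],
    evc_params: EvcParams,
    params: BehaviorParams,
    config: DesignConfig,
    seed: int,
    rt_coupling: np.ndarray | None = None,
    acc_coupling: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate one study's behavior from its trial table.

    ``rt_coupling`` (ms) and ``acc_coupling`` (log-odds) are optional
    per-trial additive terms used to couple behavior to cue-locked neural
    residuals; they must be condition-orthogonal for the behavioral
    ground-truth contrasts to stay exact.

    Returns the trial table augmented with ``u_star, rt, rt_missing, accuracy,
    criterion_met, performance_determined, rewarded, outcome_amount``.
    Chronological order per subject is required (the yoking draws are
    sequential).
    """
    specs = specs.sort_values(["subject", "trial"], kind="stable").reset_index(drop=True)
    for subject, g in specs.groupby("subject"):
        t = g["trial"].to_numpy()
        if not np.array_equal(t, np.arange(t[0], t[0] + len(t))):
            raise ValueError(f"subject {subject}: trial indices are not contiguous")
    by_id = {s.subject: s for s in subjects}

    u_map = {
        (r, e): allocated_control(r, e, evc_params, params)
        for r in config.reward_levels
        for e in config.efficacy_levels
    }
    u = np.array([u_map[(r, e)] for r, e in zip(specs.reward, specs.efficacy)])
    codes = design_codes(specs, config)
    k = codes.cong_step.to_numpy()
    cong_rt = np.array([0.0, params.rt_congruency[0],
                        params.rt_congruency[0] + params.rt_congruency[1]])[k]
    rew_c, eff_c, inter = (codes.rew_c.to_numpy(), codes.eff_c.to_numpy(),
                           codes.inter.to_numpy())
    trial_c = codes.trial_c.to_numpy()

    subj_int = np.array([by_id[s].rt_intercept for s in specs.subject])
    subj_br = np.array([by_id[s].rt_slope_reward for s in specs.subject])
    subj_be = np.array([by_id[s].rt_slope_efficacy for s in specs.subject])
    subj_bi = np.array([by_id[s].rt_slope_interaction for s in specs.subject])
    subj_acc = np.array([by_id[s].accuracy_intercept for s in specs.subject])

    rt_struct = (
        subj_int
        - params.rt_control_gain * u
        + subj_br * rew_c + subj_be * eff_c + subj_bi * inter
        + cong_rt
        + params.rt_trend * trial_c
    )
    if rt_coupling is not None:
        rt_struct = rt_struct + np.asarray(rt_coupling, dtype=float)

    rng = stream(seed, "behavior")
    rt = rt_struct + _shifted_lognormal_noise(
        rng, len(specs), params.rt_noise_sd, params.rt_lognorm_sigma
    )
    rt_missing = rt >= config.recording_window_ms
    rt = np.where(rt_missing, np.nan, rt)

    acc_lp = (
        evc_params.performance_intercept
        + evc_params.performance_slope * u
        - evc_params.congruency_penalty * k
        + subj_acc
        + params.accuracy_trend * trial_c
    )
    if acc_coupling is not None:
        acc_lp = acc_lp + np.asarray(acc_coupling, dtype=float)
    accuracy = (rng.random(len(specs)) < expit(acc_lp)).astype(int)
    accuracy[rt_missing] = 0  # no response in the recording window

    criterion = (
        (accuracy == 1) & ~rt_missing & (rt < config.response_deadline_ms)
    ).astype(int)

    # sequential yoked reward outcomes, per subject in chronological order
    perf_det = np.zeros(len(specs), dtype=int)
    rewarded = np.zeros(len(specs), dtype=int)
    for subject, g in specs.groupby("subject"):
        hist: deque = deque(maxlen=max(params.yoking_window, 1))
        srng = stream(seed, "yoking", subject)
        for i in g.index:
            e = specs.efficacy.iloc[i]
            pd_trial = int(srng.random() < e)
            perf_det[i] = pd_trial
            if pd_trial:
                rewarded[i] = criterion[i]
                hist.append(int(rewarded[i]))
            else:
                p = yoked_reward_probability(
                    hist, params.yoking_window, params.yoking_cold_start
                )
                rewarded[i] = int(srng.random() < p)

    out = specs.copy()
    out["u_star"] = u
    out["rt"] = rt
    out["rt_missing"] = rt_missing.astype(int)
    out["accuracy"] = accuracy
    out["criterion_met"] = criterion
    out["performance_determined"] = perf_det
    out["rewarded"] = rewarded
    out["outcome_amount"] = rewarded * out["reward"]
    return out
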