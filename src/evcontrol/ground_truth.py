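"""Analytic expected coefficients for every fitted model.

The generator plants all of its effects as explicit linear structures, so
the estimand of each mixed model can be written down rather than guessed:

* Behavior models — the structural RT (or accuracy log-odds) per trial is an
  exact linear function of the model's coded regressors in the dichotomous
  studies (the 2x2 incentive cells are saturated by reward, efficacy and
  their interaction; congruency costs are spanned by the sliding-difference
  contrasts; the trend is linear).  Truths are obtained by projecting the
  structural expectation onto the model's design columns (for Study 3 the
  4x4 surface is not saturated and the projection is the pseudo-true
  parameter).
* ERP models — planted effects carry over directly; because the CNV leak
  applies to the full P3b amplitude and the model includes that amplitude as
  a regressor, the CNV model's incentive truths are the planted CNV effects
  and the P3b slope truth is the leak itself.
* ERP-to-behavior models — behavior couples to the *standardized residuals*
  of the cue-locked amplitudes.  Rewriting the residual in terms of the
  z-scored amplitude regressor (residual = s*z - condition part - baseline
  leak) reallocates known amounts of each planted effect between the z
  regressors, the incentive terms and the baseline covariate; the algebra is
  carried out below using the population within-subject SDs.
* The accuracy model omits the residual coupling when ERP regressors are
  absent; its truths carry the standard logistic marginalization
  attenuation, which at the default couplings is a ~0.4% shrinkage.

* Recording-window truncation — responses slower than the recording window
  are missing, which (a) truncates the RT noise distribution (the kept-trial
  mean shifts down, more so for slow cells, which attenuates the congruency
  and trend estimands) and (b) forces accuracy to 0 on missing trials, which
  on the log-odds scale deflates high-accuracy cells disproportionately.
  Both effects are computed in closed form from the shifted-lognormal noise
  (partial expectations), integrating over the subject intercept
  distribution by Gauss-Hermite quadrature.

All functions are deterministic in the configuration and the trial design;
nothing here looks at simulated outcomes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .behavior import BehaviorParams, allocated_control, design_codes
from .design import DesignConfig
from .eeg_sim import ErpEffects
from .evc import CONGRUENCY_LEVELS, EvcParams
from .stats import _CONG_CODES

__all__ = [
    "structural_rt",
    "structural_accuracy_logodds",
    "model_truths",
]

_BEHAVIOR_COLS = ("rew_c", "eff_c", "inter", "cong_i_n", "cong_n_c", "trial_c")


def _design_matrix(specs: pd.DataFrame, config: DesignConfig) -> pd.DataFrame:
    codes = design_codes(specs, config)
    cong = specs.congruency.map(_CONG_CODES)
    return pd.DataFrame({
        "const": 1.0,
        "rew_c": codes.rew_c,
        "eff_c": codes.eff_c,
        "inter": codes.inter,
        "cong_i_n": cong.str[1],
        "cong_n_c": cong.str[0],
        "trial_c": codes.trial_c,
    })


def _lognormal_keep_stats(cutoff: np.ndarray, sd: float, sigma: float):
    """Keep probability and kept-mean of the shifted-lognormal RT noise.

    The noise is ``(L - E[L]) * s`` with ``L ~ LogNormal(0, sigma^2)`` scaled
    to standard deviation ``sd``.  For a cutoff ``d`` (noise < d is kept)
    returns ``(P[kept], E[noise | kept])`` via the lognormal partial
    expectation ``E[L 1{L<k}] = exp(sigma^2/2) Phi(ln k / sigma - sigma)``.
    """
    mu = np.exp(sigma**2 / 2.0)
    raw_sd = np.sqrt((np.exp(sigma**2) - 1.0) * np.exp(sigma**2))
    s = sd / raw_sd
    k = cutoff / s + mu
    keep = np.where(k > 0, norm.cdf(np.log(np.maximum(k, 1e-300)) / sigma), 0.0)
    partial = mu * norm.cdf(np.log(np.maximum(k, 1e-300)) / sigma - sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        kept_mean = np.where(keep > 0, s * (partial - mu * keep) / keep, 0.0)
    return keep, kept_mean


def _keep_and_kept_rt(struct: np.ndarray, config: DesignConfig,
                      bp: BehaviorParams, extra_spread_sd: float = 0.0,
                      n_nodes: int = 21):
    """Per-trial response probability and kept-trial expected RT.

    Integrates the subject RT-intercept distribution (widened by any
    additional gaussian RT spread, e.g. the neural coupling) by
    Gauss-Hermite quadrature; random incentive slopes contribute far less
    spread than the intercept and are neglected.
    """
    z, w = np.polynomial.hermite_e.hermegauss(n_nodes)
    w = w / w.sum()
    spread = float(np.hypot(bp.rt_intercept_sd, extra_spread_sd))
    keep_acc = np.zeros_like(struct)
    rt_acc = np.zeros_like(struct)
    for zi, wi in zip(z, w):
        struct_i = struct + spread * zi
        cutoff = config.recording_window_ms - struct_i
        keep, kept_mean = _lognormal_keep_stats(
            cutoff, bp.rt_noise_sd, bp.rt_lognorm_sigma
        )
        keep_acc += wi * keep
        # subjects enter the mixed model with (near-)equal weight, so the
        # kept-trial RT averages subject-level kept means unweighted
        rt_acc += wi * (struct_i + kept_mean)
    return keep_acc, rt_acc


def structural_rt(specs: pd.DataFrame, config: DesignConfig,
                  evc: EvcParams, bp: BehaviorParams,
                  truncated: bool = True,
                  extra_spread_sd: float = 0.0) -> np.ndarray:
    """Population expected recorded RT per trial.

    With ``truncated`` (the estimand of the accurate-RT models) the
    expectation conditions on a response inside the recording window.
    """
    u = np.array([
        allocated_control(r, e, evc, bp)
        for r, e in zip(specs.reward, specs.efficacy)
    ])
    k = np.array([CONGRUENCY_LEVELS.index(c) for c in specs.congruency])
    cong_rt = np.array([0.0, bp.rt_congruency[0],
                        bp.rt_congruency[0] + bp.rt_congruency[1]])[k]
    trial_c = design_codes(specs, config).trial_c.to_numpy()
    struct = (bp.rt_intercept - bp.rt_control_gain * u + cong_rt
              + bp.rt_trend * trial_c)
    if not truncated:
        return struct
    _, kept_rt = _keep_and_kept_rt(struct, config, bp, extra_spread_sd)
    return kept_rt


def structural_accuracy_logodds(specs: pd.DataFrame, config: DesignConfig,
                                evc: EvcParams, bp: BehaviorParams,
                                observed: bool = True) -> np.ndarray:
    """Population accuracy log-odds per trial (subject offsets at the mean).

    With ``observed`` (the estimand of the accuracy models) the log-odds are
    those of *recorded* accuracy: a missing response counts as inaccurate,
    so the latent success probability is multiplied by the per-trial
    response probability before taking the logit.
    """
    u = np.array([
        allocated_control(r, e, evc, bp)
        for r, e in zip(specs.reward, specs.efficacy)
    ])
    k = np.array([CONGRUENCY_LEVELS.index(c) for c in specs.congruency])
    trial_c = design_codes(specs, config).trial_c.to_numpy()
    lp = (evc.performance_intercept + evc.performance_slope * u
          - evc.congruency_penalty * k + bp.accuracy_offset
          + bp.accuracy_trend * trial_c)
    if not observed:
        return lp
    cong_rt = np.array([0.0, bp.rt_congruency[0],
                        bp.rt_congruency[0] + bp.rt_congruency[1]])[k]
    rt_struct = (bp.rt_intercept - bp.rt_control_gain * u + cong_rt
                 + bp.rt_trend * trial_c)
    keep, _ = _keep_and_kept_rt(rt_struct, config, bp)
    p_obs = np.clip(expit(lp) * keep, 1e-12, 1 - 1e-12)
    return np.log(p_obs / (1.0 - p_obs))


def _project(expected: np.ndarray, X: pd.DataFrame,
             weights: np.ndarray | None = None) -> dict:
    """Least-squares projection of a structural expectation onto a design.

    ``weights`` reproduce the fitting sample's trial density (e.g. the
    accurate-RT models only see trials that were answered correctly inside
    the recording window); they matter only for the part of the expectation
    that is not exactly linear in the design columns.
    """
    A = X.to_numpy()
    y = np.asarray(expected, dtype=float)
    if weights is not None:
        sw = np.sqrt(np.asarray(weights, dtype=float))
        A = A * sw[:, None]
        y = y * sw
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    out = dict(zip(X.columns, beta))
    out["Intercept"] = out.pop("const")
    return out


def _logit_attenuation(omitted_var: float) -> float:
    """Marginalization shrinkage for a logit model omitting N(0, v) noise."""
    c2 = (16.0 * np.sqrt(3.0) / (15.0 * np.pi)) ** 2
    return 1.0 / np.sqrt(1.0 + c2 * omitted_var)


def model_truths(specs: pd.DataFrame, config: DesignConfig, evc: EvcParams,
                 bp: BehaviorParams, effects: ErpEffects) -> dict:
    """Expected fixed-effect values for the full model battery.

    Returns ``{model: {term: truth}}`` for the behavior, ERP (P3b/CNV),
    outcome (ERN/FRN) and ERP-to-behavior models as fitted by
    :mod:`evcontrol.stats` on data from this generator configuration.
    """
    X = _design_matrix(specs, config)

    coupling_sd = float(np.hypot(effects.rt_gamma_p3b, effects.rt_gamma_cnv))
    rt_struct = structural_rt(specs, config, evc, bp,
                              extra_spread_sd=coupling_sd)
    # The accurate-RT models only see correct, in-window responses.  That
    # sample over-represents easy (congruent, high-incentive) trials, which
    # matters for the nonlinear truncation part of the expectation, and
    # conditioning on accuracy selects on the shared neural coupling
    # (cov(rt_coupling, acc_coupling) != 0), shifting kept RT by
    # cov * (1 - p_acc) per trial.
    lp_lat = structural_accuracy_logodds(specs, config, evc, bp, observed=False)
    p_acc = expit(lp_lat)
    rt_base = structural_rt(specs, config, evc, bp, truncated=False)
    keep, _ = _keep_and_kept_rt(rt_base, config, bp,
                                extra_spread_sd=coupling_sd)
    cov_coupling = (effects.rt_gamma_p3b * effects.acc_gamma_p3b
                    + effects.rt_gamma_cnv * effects.acc_gamma_cnv)
    rt_expected = rt_struct + cov_coupling * (1.0 - p_acc)
    rt_weights = keep * p_acc
    rt_truth = _project(rt_expected, X, weights=rt_weights)

    acc_lp = structural_accuracy_logodds(specs, config, evc, bp)
    acc_proj = _project(acc_lp, X)
    shrink = _logit_attenuation(
        effects.acc_gamma_p3b**2 + effects.acc_gamma_cnv**2
    )
    acc_truth = {k: v * shrink for k, v in acc_proj.items()}

    p3b_truth = {
        "Intercept": effects.p3b_mean,
        "rew_c": effects.p3b_reward,
        "eff_c": effects.p3b_efficacy,
        "inter": effects.p3b_interaction,
        "trial_c": effects.p3b_trend,
        "p3b_baseline_c": effects.p3b_baseline_leak,
    }
    cnv_truth = {
        "Intercept": effects.cnv_mean,
        "rew_c": effects.cnv_reward,
        "eff_c": effects.cnv_efficacy,
        "inter": effects.cnv_interaction,
        "trial_c": effects.cnv_trend,
        "p3b_c": effects.cnv_p3b_leak,
        "cnv_baseline_c": effects.cnv_baseline_leak,
    }
    ern_truth = {
        "acc_dev": effects.ern_accuracy,
        "rew_c": effects.ern_reward,
        "eff_c": effects.ern_efficacy,
        "inter": effects.ern_interaction,
        "cong_i_n": 0.0, "cong_n_c": 0.0,
        "trial_c": 0.0, "ern_baseline_c": 0.0,
    }
    frn_truth = {
        "rwd_dev": effects.frn_rewarded,
        "rwd_x_rew": effects.frn_rewarded_x_reward,
        "rwd_x_eff": effects.frn_rewarded_x_efficacy,
        "rew_c": effects.frn_reward,
        "eff_c": effects.frn_efficacy,
        "inter": 0.0, "trial_c": 0.0, "frn_baseline_c": 0.0,
    }

    # --- ERP-to-behavior (Table-2 style) truths ---------------------------
    # population condition parts of the cue-locked amplitudes
    a = {  # P3b structural effects on the behavior design columns
        "rew_c": effects.p3b_reward, "eff_c": effects.p3b_efficacy,
        "inter": effects.p3b_interaction, "trial_c": effects.p3b_trend,
    }
    ctot = {  # total CNV condition effects including the P3b leak
        "rew_c": effects.cnv_reward + effects.cnv_p3b_leak * a["rew_c"],
        "eff_c": effects.cnv_efficacy + effects.cnv_p3b_leak * a["eff_c"],
        "inter": effects.cnv_interaction + effects.cnv_p3b_leak * a["inter"],
        "trial_c": effects.cnv_trend + effects.cnv_p3b_leak * a["trial_c"],
    }
    cond_p = sum(a[k] * X[k].to_numpy() for k in a)
    cond_c = sum(ctot[k] * X[k].to_numpy() for k in ctot)
    tau_p = effects.p3b_noise_sd
    tau_c = effects.cnv_resid_sd
    bsd = effects.baseline_sd
    s_p = float(np.sqrt(np.var(cond_p)
                        + (effects.p3b_baseline_leak * bsd) ** 2 + tau_p**2))
    s_c = float(np.sqrt(
        np.var(cond_c)
        + (effects.cnv_p3b_leak * effects.p3b_baseline_leak * bsd) ** 2
        + (effects.cnv_baseline_leak * bsd) ** 2 + tau_c**2
    ))

    def _erp_behavior_truth(base: dict, g_p: float, g_c: float) -> dict:
        out = dict(base)
        for k in ("rew_c", "eff_c", "inter", "trial_c"):
            out[k] = out.get(k, 0.0) - (g_p / tau_p) * a[k] - (g_c / tau_c) * ctot[k]
        out["p3b_z"] = g_p * s_p / tau_p
        out["cnv_z"] = g_c * s_c / tau_c
        out["cnv_baseline_c"] = -(g_c / tau_c) * effects.cnv_baseline_leak
        return out

    rt_erp_truth = _erp_behavior_truth(
        rt_truth, effects.rt_gamma_p3b, effects.rt_gamma_cnv
    )
    acc_erp_truth = _erp_behavior_truth(
        acc_proj, effects.acc_gamma_p3b, effects.acc_gamma_cnv
    )

    return {
        "rt": rt_truth,
        "accuracy": acc_truth,
        "p3b": p3b_truth,
        "cnv": cnv_truth,
        "ern": ern_truth,
        "frn": frn_truth,
        "rt_erp": rt_erp_truth,
        "accuracy_erp": acc_erp_truth,
    }
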