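"""Hierarchical (mixed-effects) regression stage.

Mirrors the analysis structure of the incentive Stroop studies: single-trial
two-level models (trials nested in participants) with random intercepts and
slopes, fitted by statsmodels.  Gaussian responses use ``MixedLM`` (REML by
default; ML inside likelihood-ratio comparisons).  Binomial responses
(accuracy, reward receipt) use a conditional fixed-effects logit with
sum-coded subject effects: the stack has no frequentist binomial GLMM, and
the conditional logit targets the same within-subject estimands with
well-calibrated ML standard errors (the intercept SE additionally carries
the between-subject sampling term).  Normal-approximation two-sided
p-values are reported throughout.

Random-effects structures are declared maximally and pruned as supported by
the data: after each fit the random-effects covariance is examined by SVD
and, while its relative smallest singular value falls below 1e-6 (or the fit
fails), the slope with the smallest variance share is removed and the model
refitted.  The pruning path is recorded and deterministic.

``build_analysis_table`` assembles the single-trial analysis table: centered
incentive codes (two-level factors to +/-0.5), sliding-difference congruency
contrasts (coefficients estimate neutral-congruent and incongruent-neutral
differences), within-subject standardized trial number, within-subject
centered baselines, and ERP amplitudes both centered (for the ERP models)
and z-scored within subject (for the ERP-to-behavior models).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.api as sm
import statsmodels.formula.api as smf

from .behavior import centered_levels
from .design import DesignConfig

__all__ = [
    "FitError",
    "ModelSpec",
    "FitResult",
    "build_analysis_table",
    "fit_mixed",
    "behavior_models",
    "erp_models",
    "erp_to_behavior_models",
    "outcome_models",
    "pupil_models",
    "compare_erp_slopes",
]

SINGULARITY_TOL = 1e-6


class FitError(RuntimeError):
    """A mixed model could not be fit (degenerate data or no convergence)."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one mixed model.

    ``fixed`` is the right-hand side of the fixed-effects formula (numeric
    columns built by :func:`build_analysis_table`); ``random_slopes`` lists
    the columns declared as by-subject random slopes (a random intercept is
    always included).
    """

    name: str
    response: str
    fixed: tuple
    family: str = "gaussian"  # or "binomial"
    random_slopes: tuple = ()
    reml: bool = True  # REML for well-calibrated SEs; ML inside LRTs

    @property
    def formula(self) -> str:
        return f"{self.response} ~ " + " + ".join(self.fixed)


@dataclass
class FitResult:
    """Fixed effects, random variances and diagnostics of one fitted model."""

    name: str
    params: pd.DataFrame  # term, estimate, se, stat, p, ci_low, ci_high
    random_variances: dict
    converged: bool
    singular: bool
    llf: float
    nobs: int
    pruning_path: tuple = ()
    family: str = "gaussian"

    def estimate(self, term: str) -> float:
        return float(self.params.set_index("term").loc[term, "estimate"])

    def ci(self, term: str) -> tuple:
        row = self.params.set_index("term").loc[term]
        return float(row.ci_low), float(row.ci_high)

    def pvalue(self, term: str) -> float:
        return float(self.params.set_index("term").loc[term, "p"])

    def covers(self, term: str, value: float) -> bool:
        lo, hi = self.ci(term)
        return lo <= value <= hi


# ---------------------------------------------------------------------------
# analysis table

#: backward-difference congruency contrasts; coefficients estimate the
#: neutral-minus-congruent and incongruent-minus-neutral mean differences
_CONG_CODES = {
    "congruent": (-2 / 3, -1 / 3),
    "neutral": (1 / 3, -1 / 3),
    "incongruent": (1 / 3, 2 / 3),
}


def _center_within(df: pd.DataFrame, col: str) -> pd.Series:
    return df[col] - df.groupby("subject")[col].transform("mean")


def _zscore_within(df: pd.DataFrame, col: str) -> pd.Series:
    g = df.groupby("subject")[col]
    return (df[col] - g.transform("mean")) / g.transform("std")


def build_analysis_table(
    records: pd.DataFrame,
    erp_amplitudes: pd.DataFrame | None = None,
    pupil_coefficients: pd.DataFrame | None = None,
    config: DesignConfig | None = None,
) -> pd.DataFrame:
    """Merge trial records with quantified amplitudes and code regressors.

    All continuous regressors are within-subject mean-centered; incentive
    levels are coded to a +/-0.5 span (dichotomous studies) or within the
    same span for parametric levels; congruency enters as sliding-difference
    contrasts; ERP amplitudes additionally get within-subject z-scored
    variants for the ERP-to-behavior models.  Rejection flags from the
    quantification stage are preserved so ERP models can drop rejected
    epochs while behavior models keep every trial.
    """
    df = records.copy()
    if df.duplicated(["subject", "trial"]).any():
        raise ValueError("duplicate subject/trial keys in trial records")
    if erp_amplitudes is not None:
        if erp_amplitudes.duplicated(["subject", "trial"]).any():
            raise ValueError("duplicate subject/trial keys in ERP table")
        df = df.merge(erp_amplitudes, on=["subject", "trial"], how="left")

    reward_levels = config.reward_levels if config else sorted(df.reward.unique())
    efficacy_levels = config.efficacy_levels if config else sorted(df.efficacy.unique())
    df["rew_c"] = centered_levels(df.reward.to_numpy(), reward_levels)
    df["eff_c"] = centered_levels(df.efficacy.to_numpy(), efficacy_levels)
    df["inter"] = df.rew_c * df.eff_c
    codes = df.congruency.map(_CONG_CODES)
    df["cong_n_c"] = codes.str[0]
    df["cong_i_n"] = codes.str[1]
    n_per = df.groupby("subject")["trial"].transform("count")
    df["trial_c"] = (df.trial - (n_per + 1) / 2.0) / np.sqrt((n_per**2 - 1) / 12.0)
    df["acc_dev"] = df.accuracy - 0.5
    if "rewarded" in df:
        df["rwd_dev"] = df.rewarded - 0.5
        df["rwd_x_rew"] = df.rwd_dev * df.rew_c
        df["rwd_x_eff"] = df.rwd_dev * df.eff_c

    for col in ("p3b_baseline", "cnv_baseline", "ern_baseline", "frn_baseline"):
        if col in df:
            df[f"{col}_c"] = _center_within(df, col)
    for col in ("p3b", "cnv", "ern", "frn"):
        if col in df:
            df[f"{col}_c"] = _center_within(df, col)
            df[f"{col}_z"] = _zscore_within(df, col)
    for col in ("cue_rejected", "response_rejected", "feedback_rejected"):
        if col not in df:
            df[col] = 0
        df[col] = df[col].fillna(0).astype(int)

    if pupil_coefficients is not None:
        df = df.merge(pupil_coefficients, on="subject", how="left")
    return df


# ---------------------------------------------------------------------------
# fitting engines

def _wald_table(terms, est, se) -> pd.DataFrame:
    est = np.asarray(est, dtype=float)
    se = np.asarray(se, dtype=float)
    z = np.divide(est, se, out=np.full_like(est, np.nan), where=se > 0)
    p = 2 * sps.norm.sf(np.abs(z))
    return pd.DataFrame({
        "term": list(terms), "estimate": est, "se": se, "stat": z, "p": p,
        "ci_low": est - 1.96 * se, "ci_high": est + 1.96 * se,
    })


def _fit_gaussian(spec: ModelSpec, data: pd.DataFrame, slopes: tuple):
    re_formula = "1" + "".join(f" + {s}" for s in slopes)
    model = smf.mixedlm(
        spec.formula, data, groups=data["subject"], re_formula=re_formula
    )
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # the default optimizer occasionally reports non-convergence on
        # well-behaved problems; fall through a deterministic sequence
        for method in (None, "cg", "powell"):
            kw = {} if method is None else {"method": method}
            result = model.fit(reml=spec.reml, **kw)
            if result.converged and np.isfinite(result.llf):
                break
    return model, result


def _gaussian_singular(result) -> bool:
    cov = np.asarray(result.cov_re)
    if not np.all(np.isfinite(cov)):
        return True
    sv = np.linalg.svd(cov, compute_uv=False)
    return bool(sv[-1] < SINGULARITY_TOL * max(sv[0], 1e-300))


def _fit_binomial(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Two-level binomial model via conditional (fixed-effects) logit.

    Subject-level variation enters as sum-coded subject effects, so the
    reported intercept is the mean of the subject intercepts and the slope
    coefficients are the conditional (within-subject) effects — the same
    estimands as a binomial GLMM's.  Subjects whose response is constant are
    perfectly separated on their own effect and are dropped from the fit
    (their trials carry no conditional information); if every subject is
    constant the model is degenerate.  The intercept SE additionally carries
    the between-subject sampling term ``var(subject effects) / n_subjects``.
    """
    y = data[spec.response]
    if y.nunique() < 2:
        raise FitError(f"{spec.name}: response is constant (complete separation)")
    const = data.groupby("subject")[spec.response].nunique() == 1
    dropped = const[const].index.tolist()
    if dropped:
        warnings.warn(
            f"{spec.name}: dropping {len(dropped)} subject(s) with constant "
            "response (perfect separation on the subject effect)",
            stacklevel=2,
        )
        data = data[~data["subject"].isin(dropped)]
        if data["subject"].nunique() < 2:
            raise FitError(f"{spec.name}: separation leaves < 2 subjects")

    import patsy

    y_mat, X = patsy.dmatrices(spec.formula, data, return_type="dataframe")
    subjects = np.sort(data["subject"].unique())
    ref, others = subjects[0], subjects[1:]
    dummies = pd.DataFrame(0.0, index=data.index,
                           columns=[f"subj_{s}" for s in others])
    for s in others:
        dummies.loc[data["subject"] == s, f"subj_{s}"] = 1.0
        dummies.loc[data["subject"] == ref, f"subj_{s}"] = -1.0
    design = pd.concat([X, dummies], axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = sm.GLM(np.asarray(y_mat).ravel(), design,
                        family=sm.families.Binomial()).fit()
    if not np.all(np.isfinite(result.bse[: X.shape[1]])):
        raise FitError(f"{spec.name}: binomial fit did not converge")

    terms = list(X.columns)
    est = result.params[: len(terms)].to_numpy()
    se = result.bse[: len(terms)].to_numpy().copy()
    alpha = result.params[len(terms):].to_numpy()
    alpha = np.append(alpha, -alpha.sum())  # sum-coded: reference effect
    subj_var = float(np.var(alpha, ddof=1)) if len(alpha) > 1 else 0.0
    for i, t in enumerate(terms):
        if t == "Intercept":
            se[i] = np.sqrt(se[i] ** 2 + subj_var / len(alpha))
    params = _wald_table(terms, est, se)
    return FitResult(
        name=spec.name, params=params,
        random_variances={"subject": subj_var},
        converged=bool(result.converged), singular=False,
        llf=float(result.llf), nobs=int(result.nobs),
        pruning_path=(), family="binomial",
    )


def fit_mixed(spec: ModelSpec, table: pd.DataFrame) -> FitResult:
    """Fit one declared mixed model with singularity-driven pruning.

    Gaussian: MixedLM with the declared random intercept + slopes; while the
    random-effects covariance is singular (relative smallest singular value
    below 1e-6) the slope with the smallest variance share is dropped and
    the model refitted.  Binomial: conditional fixed-effects logit with
    subject effects (see :func:`_fit_binomial`).  Raises :class:`FitError`
    for degenerate inputs or if no structure converges.
    """
    cols = [spec.response, "subject", *dict.fromkeys(
        c for term in spec.fixed for c in term.split(":"))]
    data = table.dropna(subset=[c for c in cols if c in table]).copy()
    if not len(data):
        raise FitError(f"{spec.name}: no complete observations")
    if data["subject"].nunique() < 2:
        raise FitError(f"{spec.name}: a two-level model needs >= 2 subjects")

    if spec.family == "binomial":
        return _fit_binomial(spec, data)

    slopes = tuple(spec.random_slopes)
    path = []
    while True:
        try:
            model, result = _fit_gaussian(spec, data, slopes)
            ok = bool(result.converged) and np.isfinite(result.llf)
            singular = _gaussian_singular(result)
        except (np.linalg.LinAlgError, ValueError):
            ok, singular, result = False, True, None
        if ok and not singular:
            break
        if not slopes:
            if result is None or not ok:
                raise FitError(
                    f"{spec.name}: intercept-only random structure failed to "
                    f"converge (pruning path: {path})"
                )
            break  # intercept-only but singular: report with the flag set
        # drop the slope with the smallest variance share
        if result is not None and np.all(np.isfinite(np.asarray(result.cov_re))):
            diag = pd.Series(np.diag(result.cov_re), index=result.cov_re.index)
            slope_vars = diag[[s for s in slopes]]
            drop = slope_vars.idxmin()
        else:
            drop = slopes[-1]
        path.append(str(drop))
        slopes = tuple(s for s in slopes if s != drop)

    fe = result.fe_params
    params = _wald_table(fe.index, fe.values, result.bse_fe.values)
    cov = pd.DataFrame(result.cov_re)
    rv = {str(k): float(v) for k, v in zip(cov.index, np.diag(cov))}
    rv["residual"] = float(result.scale)
    return FitResult(
        name=spec.name, params=params, random_variances=rv,
        converged=bool(result.converged), singular=_gaussian_singular(result),
        llf=float(result.llf), nobs=int(result.nobs),
        pruning_path=tuple(path), family="gaussian",
    )


# ---------------------------------------------------------------------------
# the study's model battery

_BEHAVIOR_TERMS = ("rew_c", "eff_c", "inter", "cong_i_n", "cong_n_c", "trial_c")


def behavior_models(table: pd.DataFrame,
                    random_slopes=("rew_c", "eff_c", "inter")) -> dict:
    """Accurate-RT (gaussian) and accuracy (binomial) incentive models."""
    rt_spec = ModelSpec(
        name="rt", response="rt", fixed=_BEHAVIOR_TERMS,
        family="gaussian", random_slopes=tuple(random_slopes),
    )
    acc_spec = ModelSpec(
        name="accuracy", response="accuracy", fixed=_BEHAVIOR_TERMS,
        family="binomial",
    )
    accurate = table[(table.accuracy == 1) & table.rt.notna()]
    return {
        "rt": fit_mixed(rt_spec, accurate),
        "accuracy": fit_mixed(acc_spec, table),
    }


def erp_models(table: pd.DataFrame, random_slopes=("rew_c",)) -> dict:
    """Cue-locked amplitude models: P3b, and CNV with the P3b carry-over.

    Rejected cue epochs are excluded; baselines enter as nuisance
    covariates; the CNV model additionally controls for the same trial's
    P3b amplitude (signal autocorrelation).
    """
    ok = table[table.cue_rejected == 0]
    p3b_spec = ModelSpec(
        name="p3b",
        response="p3b",
        fixed=("rew_c", "eff_c", "inter", "trial_c", "p3b_baseline_c"),
        random_slopes=tuple(random_slopes),
    )
    cnv_spec = ModelSpec(
        name="cnv",
        response="cnv",
        fixed=("rew_c", "eff_c", "inter", "trial_c", "p3b_c",
               "cnv_baseline_c"),
        random_slopes=tuple(random_slopes),
    )
    return {"p3b": fit_mixed(p3b_spec, ok), "cnv": fit_mixed(cnv_spec, ok)}


_TABLE2_TERMS = ("eff_c", "rew_c", "p3b_z", "cnv_z", "cong_i_n", "cong_n_c",
                 "cnv_baseline_c", "trial_c", "inter")


def erp_to_behavior_models(table: pd.DataFrame,
                           random_slopes=("rew_c",)) -> dict:
    """ERP-to-behavior models plus the CNV-vs-P3b slope comparison.

    Accurate RT (gaussian) and accuracy (binomial) are regressed on the
    incentive terms and the within-subject z-scored single-trial P3b and
    CNV.  The slope comparison asks whether the CNV's association with
    accurate RT is stronger than the P3b's: a likelihood-ratio test of the
    full RT model against one constraining the two slopes to equal
    magnitude after sign alignment (the CNV, a negative-going component, is
    negated), chi-square with 1 df.
    """
    ok = table[table.cue_rejected == 0].copy()
    accurate = ok[(ok.accuracy == 1) & ok.rt.notna()]
    rt_spec = ModelSpec(
        name="rt_erp", response="rt", fixed=_TABLE2_TERMS,
        random_slopes=tuple(random_slopes),
    )
    acc_spec = ModelSpec(
        name="accuracy_erp", response="accuracy", fixed=_TABLE2_TERMS,
        family="binomial",
    )
    rt_fit = fit_mixed(rt_spec, accurate)
    comparison = compare_erp_slopes(accurate)
    return {
        "rt": rt_fit,
        "accuracy": fit_mixed(acc_spec, ok),
        "slope_comparison": comparison,
    }


def compare_erp_slopes(accurate: pd.DataFrame) -> dict:
    """LRT of equal (sign-aligned) P3b and CNV slopes on accurate RT.

    The constrained model replaces the two z-scored ERP regressors with
    their sign-aligned sum ``p3b_z - cnv_z``, i.e. it forces the RT change
    per SD of ERP magnitude to be equal for the two components.  Both
    models are fitted by maximum likelihood with the same (random-intercept)
    random structure, so they are strictly nested; the statistic is
    ``2 * (llf_full - llf_constrained)`` on 1 df.
    """
    accurate = accurate.copy()
    accurate["erp_aligned"] = accurate["p3b_z"] - accurate["cnv_z"]
    full = fit_mixed(ModelSpec(
        name="rt_erp_full", response="rt", fixed=_TABLE2_TERMS,
        random_slopes=(), reml=False,
    ), accurate)
    constrained_terms = tuple(
        "erp_aligned" if t == "p3b_z" else t
        for t in _TABLE2_TERMS if t != "cnv_z"
    )
    constrained = fit_mixed(ModelSpec(
        name="rt_erp_constrained", response="rt", fixed=constrained_terms,
        random_slopes=(), reml=False,
    ), accurate)
    full_fit = full
    stat = 2.0 * (full_fit.llf - constrained.llf)
    return {
        "chi2": float(stat),
        "df": 1,
        "p": float(sps.chi2.sf(max(stat, 0.0), 1)),
        "llf_full": full_fit.llf,
        "llf_constrained": constrained.llf,
    }


def outcome_models(table: pd.DataFrame) -> dict:
    """Response-monitoring (ERN/CRN) and feedback (FRN) models."""
    ern_ok = table[(table.response_rejected == 0)]
    ern_spec = ModelSpec(
        name="ern",
        response="ern",
        fixed=("acc_dev", "rew_c", "eff_c", "inter", "cong_i_n", "cong_n_c",
               "trial_c", "ern_baseline_c"),
        random_slopes=(),
    )
    frn_ok = table[table.feedback_rejected == 0]
    frn_spec = ModelSpec(
        name="frn",
        response="frn",
        fixed=("rwd_dev", "rwd_x_rew", "rwd_x_eff", "rew_c", "eff_c", "inter",
               "trial_c", "frn_baseline_c"),
        random_slopes=(),
    )
    return {"ern": fit_mixed(ern_spec, ern_ok), "frn": fit_mixed(frn_spec, frn_ok)}


def pupil_models(coefficients: pd.DataFrame) -> FitResult:
    """Mixed model of z-scored cue-response coefficients on the incentives.

    ``coefficients`` needs columns subject, reward, efficacy and
    ``coefficient_z`` (one row per subject x condition).
    """
    df = coefficients.copy()
    df["rew_c"] = centered_levels(df.reward.to_numpy(), sorted(df.reward.unique()))
    df["eff_c"] = centered_levels(df.efficacy.to_numpy(), sorted(df.efficacy.unique()))
    df["inter"] = df.rew_c * df.eff_c
    spec = ModelSpec(
        name="pupil_cue", response="coefficient_z",
        fixed=("rew_c", "eff_c", "inter"), random_slopes=(),
    )
    return fit_mixed(spec, df)
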