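"""Mixed-model stage: table coding, pruning, engines, slope comparison."""

import numpy as np
import pandas as pd
import pytest

from evcontrol.behavior import BehaviorParams, draw_subjects, simulate_behavior
from evcontrol.design import generate_design, study_design
from evcontrol.evc import EvcParams
from evcontrol.stats import (
    FitError,
    ModelSpec,
    build_analysis_table,
    compare_erp_slopes,
    fit_mixed,
    pupil_models,
)


@pytest.fixture(scope="module")
def table():
    cfg = study_design(2, n_subjects=6, blocks=2, seed=31)
    specs = generate_design(cfg)
    bp = BehaviorParams()
    subjects = draw_subjects(cfg.n_subjects, bp, seed=31)
    records = simulate_behavior(specs, subjects, EvcParams(), bp, cfg, seed=31)
    amps = pd.DataFrame({
        "subject": records.subject, "trial": records.trial,
        "p3b": np.random.default_rng(31).normal(5, 2, len(records)),
        "cnv": np.random.default_rng(32).normal(-2, 2, len(records)),
        "p3b_baseline": np.random.default_rng(33).normal(0, 3, len(records)),
        "cnv_baseline": np.random.default_rng(34).normal(0, 3, len(records)),
        "cue_rejected": ([1] * 10 + [0] * (len(records) - 10)),
    })
    return build_analysis_table(records, amps, config=cfg), cfg


class TestAnalysisTable:
    def test_centered_columns_zero_mean_within_subject(self, table):
        t, _ = table
        for col in ("trial_c", "p3b_c", "cnv_baseline_c"):
            means = t.groupby("subject")[col].mean()
            assert np.allclose(means, 0.0, atol=1e-9), col

    def test_zscored_columns_unit_sd(self, table):
        t, _ = table
        sds = t.groupby("subject")["p3b_z"].std()
        assert np.allclose(sds, 1.0, atol=1e-9)

    def test_incentive_codes_half_span(self, table):
        t, _ = table
        assert set(np.round(t.rew_c.unique(), 6)) == {-0.5, 0.5}
        assert set(np.round(t.eff_c.unique(), 6)) == {-0.5, 0.5}

    def test_congruency_contrasts_orthogonal_to_intercept(self, table):
        t, _ = table
        # equal congruency frequencies make both contrast columns zero-mean
        assert abs(t.cong_i_n.mean()) < 0.02
        assert abs(t.cong_n_c.mean()) < 0.02
        # and the coding recovers the backward differences exactly
        codes = t.groupby("congruency")[["cong_n_c", "cong_i_n"]].first()
        M = np.column_stack([np.ones(3), codes.loc[
            ["congruent", "neutral", "incongruent"]].to_numpy()])
        mu = np.array([1.0, 3.0, 7.0])  # arbitrary level means
        beta = np.linalg.solve(M, mu)
        assert beta[1] == pytest.approx(2.0)  # neutral - congruent
        assert beta[2] == pytest.approx(4.0)  # incongruent - neutral

    def test_duplicate_keys_rejected(self, table):
        t, cfg = table
        dup = pd.concat([t.iloc[:5], t.iloc[:5]])
        with pytest.raises(ValueError):
            build_analysis_table(dup, config=cfg)

    def test_rejected_epochs_kept_for_behavior_dropped_for_erp(self, table):
        t, _ = table
        assert (t.cue_rejected == 1).sum() == 10
        assert t.rt.notna().sum() > 0  # behavior rows intact

    def test_centering_idempotent(self, table):
        t, _ = table
        once = t.p3b_c
        twice = once - once.groupby(t.subject).transform("mean")
        assert np.allclose(once, twice, atol=1e-12)


def _synthetic_mixed(n_subj=44, n_per=600, slope_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    subj = np.repeat(np.arange(n_subj), n_per)
    x = rng.choice([-0.5, 0.5], n_subj * n_per)
    intercepts = rng.normal(0, 5, n_subj)
    slopes = rng.normal(0, slope_sd, n_subj)
    y = 10 + 2 * x + intercepts[subj] + slopes[subj] * x + rng.normal(0, 3, len(x))
    return pd.DataFrame({"y": y, "x": x, "subject": subj})


class TestFitMixed:
    def test_intercept_only_data_prunes_slope(self):
        # generated without slope variation: declared slope must be pruned
        # and the intercept variance recovered within 20%
        df = _synthetic_mixed(slope_sd=0.0, seed=1)
        spec = ModelSpec(name="m", response="y", fixed=("x",),
                         random_slopes=("x",))
        fit = fit_mixed(spec, df)
        assert "x" in fit.pruning_path
        assert fit.random_variances["Group"] == pytest.approx(25.0, rel=0.2)

    def test_true_slope_variance_retained(self):
        df = _synthetic_mixed(slope_sd=2.0, seed=2)
        spec = ModelSpec(name="m", response="y", fixed=("x",),
                         random_slopes=("x",))
        fit = fit_mixed(spec, df)
        assert fit.pruning_path == ()
        assert not fit.singular

    def test_pruning_deterministic(self):
        df = _synthetic_mixed(n_subj=12, n_per=100, slope_sd=0.0, seed=3)
        spec = ModelSpec(name="m", response="y", fixed=("x",),
                         random_slopes=("x",))
        assert fit_mixed(spec, df).pruning_path == fit_mixed(spec, df).pruning_path

    def test_fixed_effect_matches_demeaned_ols_sign(self):
        df = _synthetic_mixed(n_subj=10, n_per=200, seed=4)
        spec = ModelSpec(name="m", response="y", fixed=("x",))
        fit = fit_mixed(spec, df)
        demeaned = df.assign(
            yd=df.y - df.groupby("subject").y.transform("mean"))
        beta = np.polyfit(demeaned.x, demeaned.yd, 1)[0]
        assert np.sign(fit.estimate("x")) == np.sign(beta)
        assert fit.estimate("x") == pytest.approx(beta, rel=0.05)

    def test_binomial_separation_errors(self):
        df = _synthetic_mixed(n_subj=4, n_per=50, seed=5)
        df["acc"] = 1  # all correct: no conditional information at all
        spec = ModelSpec(name="m", response="acc", fixed=("x",),
                         family="binomial")
        with pytest.raises(FitError):
            fit_mixed(spec, df)

    def test_binomial_recovers_conditional_effect(self):
        rng = np.random.default_rng(6)
        subj = np.repeat(np.arange(30), 300)
        x = rng.choice([-0.5, 0.5], len(subj))
        off = rng.normal(0, 0.5, 30)
        p = 1 / (1 + np.exp(-(0.5 + 1.2 * x + off[subj])))
        df = pd.DataFrame({"acc": (rng.random(len(subj)) < p).astype(int),
                           "x": x, "subject": subj})
        spec = ModelSpec(name="m", response="acc", fixed=("x",),
                         family="binomial")
        fit = fit_mixed(spec, df)
        assert fit.estimate("x") == pytest.approx(1.2, abs=3 * 0.06)
        assert fit.covers("Intercept", 0.5)

    def test_single_subject_rejected(self):
        df = _synthetic_mixed(n_subj=1, n_per=50, seed=7)
        spec = ModelSpec(name="m", response="y", fixed=("x",))
        with pytest.raises(FitError):
            fit_mixed(spec, df)


def test_pupil_models_single_subject_errors():
    df = pd.DataFrame({
        "subject": [1, 1, 1, 1],
        "reward": [0.1, 0.1, 1.0, 1.0],
        "efficacy": [0.0, 1.0, 0.0, 1.0],
        "coefficient_z": [0.5, -0.5, 1.0, -1.0],
    })
    with pytest.raises(FitError):
        pupil_models(df)


def test_constrained_model_never_beats_full():
    rng = np.random.default_rng(8)
    n_subj, n_per = 8, 120
    subj = np.repeat(np.arange(n_subj), n_per)
    df = pd.DataFrame({
        "subject": subj,
        "rt": rng.normal(650, 50, len(subj)),
        "p3b_z": rng.normal(0, 1, len(subj)),
        "cnv_z": rng.normal(0, 1, len(subj)),
        "eff_c": rng.choice([-0.5, 0.5], len(subj)),
        "rew_c": rng.choice([-0.5, 0.5], len(subj)),
        "cong_i_n": 0.0, "cong_n_c": 0.0,
        "cnv_baseline_c": rng.normal(0, 1, len(subj)),
        "trial_c": rng.normal(0, 1, len(subj)),
    })
    df["inter"] = df.rew_c * df.eff_c
    df["cong_i_n"] = rng.choice([-1 / 3, 2 / 3], len(subj))
    df["cong_n_c"] = rng.choice([-1 / 3, 1 / 3], len(subj))
    cmp = compare_erp_slopes(df)
    assert cmp["llf_constrained"] <= cmp["llf_full"] + 1e-6
    assert cmp["chi2"] >= -1e-6
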