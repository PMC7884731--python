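"""Pipeline orchestration: simulate -> quantify -> deconvolve -> fit -> recover.

`simulate_study` produces a complete synthetic study (behavior + planted
single-trial ERP amplitudes, optionally rendered into epochs and re-quantified
from the waveforms).  `run_pipeline` executes every stage and writes CSV/JSON
artifacts with a manifest; `run_recovery` repeats the pipeline over derived
seeds and scores sign recovery and CI coverage of every planted fixed effect
against the analytic ground truths.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import stream
from .behavior import draw_subjects, simulate_behavior
from .config import RunConfig, config_hash, load_config
from .design import generate_design
from .eeg_sim import (
    acc_coupling_from_amplitudes,
    rt_coupling_from_amplitudes,
    simulate_cue_amplitudes,
    simulate_eeg_epochs,
    simulate_outcome_amplitudes,
)
from .erp import quantify_epochs
from .ground_truth import model_truths
from .pupil import deconvolve, interpolate_blinks, preprocess
from .pupil_sim import simulate_pupil
from .stats import (
    behavior_models,
    build_analysis_table,
    erp_models,
    erp_to_behavior_models,
    outcome_models,
    pupil_models,
)

__all__ = [
    "SimulatedStudy",
    "simulate_study",
    "fit_study",
    "pupil_stage",
    "run_pipeline",
    "run_recovery",
    "RecoveryReport",
]


@dataclass
class SimulatedStudy:
    """One simulated study with its ground-truth ledger."""

    config: RunConfig
    specs: pd.DataFrame
    subjects: list
    records: pd.DataFrame
    amplitudes: pd.DataFrame  # per-trial ERP amplitude table fed to analysis
    truth_amplitudes: pd.DataFrame  # planted ground-truth amplitudes
    truths: dict  # analytic expected coefficients per model
    epoch_sets: dict | None = None


def simulate_study(config: RunConfig, seed: int | None = None) -> SimulatedStudy:
    """Simulate design, behavior and single-trial ERP amplitudes.

    With ``config.render_eeg`` the amplitudes are additionally rendered into
    512 Hz epochs and re-quantified from the waveforms (artifact rejection
    included); otherwise the planted amplitudes feed the analysis directly.
    """
    seed = config.seed if seed is None else seed
    cfg = config.design
    if cfg.seed != seed:
        cfg = dataclasses.replace(cfg, seed=seed)
    specs = generate_design(cfg)
    subjects = draw_subjects(cfg.n_subjects, config.behavior, seed)
    cue = simulate_cue_amplitudes(specs, subjects, config.erp, cfg, seed)
    records = simulate_behavior(
        specs, subjects, config.evc, config.behavior, cfg, seed,
        rt_coupling=rt_coupling_from_amplitudes(cue, config.erp),
        acc_coupling=acc_coupling_from_amplitudes(cue, config.erp),
    )
    outcome = simulate_outcome_amplitudes(records, subjects, config.erp, cfg, seed)
    truth_amps = cue.merge(outcome, on=["subject", "trial"])

    epoch_sets = None
    if config.render_eeg:
        epoch_sets, _ = simulate_eeg_epochs(
            records, subjects, config.erp, cfg, seed,
            noise_rms=config.noise_rms,
            artifact_fraction=config.artifact_fraction,
        )
        amplitudes = quantify_epochs(epoch_sets)
    else:
        amplitudes = truth_amps.drop(columns=["p3b_resid", "cnv_resid"])

    truths = model_truths(specs, cfg, config.evc, config.behavior, config.erp)
    return SimulatedStudy(
        config=config, specs=specs, subjects=subjects, records=records,
        amplitudes=amplitudes, truth_amplitudes=truth_amps, truths=truths,
        epoch_sets=epoch_sets,
    )


def fit_study(study: SimulatedStudy, include=("behavior", "erp", "erp_behavior",
                                              "outcome")) -> dict:
    """Fit the study's model battery on its analysis table."""
    table = build_analysis_table(
        study.records, study.amplitudes, config=study.config.design
    )
    fits = {}
    if "behavior" in include:
        fits.update(behavior_models(table))
    if "erp" in include:
        fits.update({f"{k}": v for k, v in erp_models(table).items()})
    if "erp_behavior" in include:
        eb = erp_to_behavior_models(table)
        fits["rt_erp"] = eb["rt"]
        fits["accuracy_erp"] = eb["accuracy"]
        fits["slope_comparison"] = eb["slope_comparison"]
    if "outcome" in include:
        fits.update(outcome_models(table))
    return fits


def pupil_stage(study: SimulatedStudy, seed: int | None = None):
    """Simulate, preprocess and deconvolve every subject's pupil trace.

    Returns ``(coefficients, fit)``: the per-subject, per-condition cue
    coefficients (z-scored within subject) and the mixed model of those
    coefficients on the incentives.
    """
    config = study.config
    seed = config.seed if seed is None else seed
    rows = []
    for subject_id, series, events in simulate_pupil(
        study.records, study.subjects, config.pupil, config.irf,
        config.design, seed,
    ):
        clean = interpolate_blinks(series)
        z = preprocess(clean)
        fit = deconvolve(z, events, config.irf, include_drift=True)
        for label, coef in fit.coefficients.items():
            if not label.startswith("cue_"):
                continue
            r, e = label[4:].split("_")
            rows.append((subject_id, float(r[1:]), float(e[1:]), coef))
    coefs = pd.DataFrame(rows, columns=["subject", "reward", "efficacy",
                                        "coefficient"])
    g = coefs.groupby("subject")["coefficient"]
    coefs["coefficient_z"] = (coefs["coefficient"] - g.transform("mean")) / g.transform("std")
    return coefs, pupil_models(coefs)


# ---------------------------------------------------------------------------
# artifact-writing pipeline

def _write_fit(fit, path: Path) -> None:
    fit.params.to_csv(path.with_suffix(".csv"), index=False)
    meta = {
        "name": fit.name, "family": fit.family, "nobs": fit.nobs,
        "converged": fit.converged, "singular": fit.singular,
        "llf": None if np.isnan(fit.llf) else fit.llf,
        "random_variances": fit.random_variances,
        "pruning_path": list(fit.pruning_path),
        "terms": fit.params.to_dict(orient="records"),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def run_pipeline(config, outdir, seed: int | None = None,
                 with_pupil: bool = True) -> Path:
    """Run every stage and write all artifacts to ``outdir``.

    Writes the trial table, the amplitude table, pupil coefficients, model
    coefficient tables (CSV + JSON), the ground-truth ledger and a manifest
    with stage timings, seeds and the config hash.  Byte-identical outputs
    under identical config + seed.
    """
    config = load_config(config)
    seed = config.seed if seed is None else seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    manifest = {"config_hash": chash, "seed": seed, "stages": {}, "files": []}

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:
            manifest["stages"][name] = {"error": repr(exc)}
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
        return out

    study = _stage("simulate", lambda: simulate_study(config, seed))
    study.records.to_csv(outdir / "trials.csv", index=False)
    study.amplitudes.to_csv(outdir / "erp_amplitudes.csv", index=False)
    study.truth_amplitudes.to_csv(outdir / "ground_truth_amplitudes.csv",
                                  index=False)
    (outdir / "ground_truth_models.json").write_text(
        json.dumps(study.truths, indent=1)
    )
    manifest["files"] += ["trials.csv", "erp_amplitudes.csv",
                          "ground_truth_amplitudes.csv",
                          "ground_truth_models.json"]

    fits = _stage("fit", lambda: fit_study(study))
    for name, fit in fits.items():
        if name == "slope_comparison":
            (outdir / "slope_comparison.json").write_text(json.dumps(fit, indent=1))
            manifest["files"].append("slope_comparison.json")
            continue
        _write_fit(fit, outdir / f"model_{name}")
        manifest["files"] += [f"model_{name}.csv", f"model_{name}.json"]

    if with_pupil:
        coefs, pupil_fit = _stage("pupil", lambda: pupil_stage(study, seed))
        coefs.to_csv(outdir / "pupil_coefficients.csv", index=False)
        _write_fit(pupil_fit, outdir / "model_pupil_cue")
        manifest["files"] += ["pupil_coefficients.csv", "model_pupil_cue.csv",
                              "model_pupil_cue.json"]

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


# ---------------------------------------------------------------------------
# recovery

@dataclass
class RecoveryReport:
    """Aggregated sign-recovery and CI-coverage over pipeline replicates."""

    table: pd.DataFrame  # one row per (replicate, model, term)
    n_replicates: int
    failures: list = field(default_factory=list)

    @property
    def coverage_rate(self) -> float:
        return float(self.table["covered"].mean())

    def sign_rate(self, model: str, term: str) -> float:
        sel = self.table[(self.table.model == model) & (self.table.term == term)]
        return float(sel["sign_ok"].mean())

    def coverage(self, model: str, term: str) -> float:
        sel = self.table[(self.table.model == model) & (self.table.term == term)]
        return float(sel["covered"].mean())

    def summary(self) -> pd.DataFrame:
        return (self.table.groupby(["model", "term"])
                .agg(truth=("truth", "first"),
                     mean_estimate=("estimate", "mean"),
                     sign_rate=("sign_ok", "mean"),
                     coverage=("covered", "mean"))
                .reset_index())


def run_recovery(config, n_replicates: int = 20, seed: int | None = None,
                 include=("behavior", "erp", "erp_behavior", "outcome"),
                 collect_comparisons: bool = False):
    """Replicate the simulate->fit pipeline and score parameter recovery.

    Each replicate draws a derived seed, regenerates the full study and
    refits the battery; every planted fixed effect contributes one row per
    replicate with its estimate, CI, sign agreement and coverage flag.
    Replicate failures are recorded, not fatal.
    """
    config = load_config(config)
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    master = config.seed if seed is None else seed
    rows, comparisons, failures = [], [], []
    for rep in range(n_replicates):
        rep_seed = int(stream(master, "recovery", rep).integers(2**31 - 1))
        try:
            study = simulate_study(config, rep_seed)
            fits = fit_study(study, include=include)
        except Exception as exc:  # pragma: no cover - defensive
            failures.append({"replicate": rep, "error": repr(exc)})
            continue
        for model_name, fit in fits.items():
            if model_name == "slope_comparison":
                comparisons.append({"replicate": rep, **fit})
                continue
            truth = study.truths.get(model_name)
            if truth is None:
                continue
            tab = fit.params.set_index("term")
            for term, value in truth.items():
                if term not in tab.index:
                    continue
                est = float(tab.loc[term, "estimate"])
                lo, hi = float(tab.loc[term, "ci_low"]), float(tab.loc[term, "ci_high"])
                rows.append({
                    "replicate": rep, "model": model_name, "term": term,
                    "truth": value, "estimate": est,
                    "ci_low": lo, "ci_high": hi,
                    "sign_ok": bool(np.sign(est) == np.sign(value)) if value != 0
                    else bool(lo <= 0 <= hi),
                    "covered": bool(lo <= value <= hi),
                    "p": float(tab.loc[term, "p"]),
                })
    report = RecoveryReport(
        table=pd.DataFrame(rows), n_replicates=n_replicates, failures=failures
    )
    if collect_comparisons:
        return report, pd.DataFrame(comparisons)
    return report
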