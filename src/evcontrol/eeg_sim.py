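"""Synthetic single-trial ERP amplitudes and rendered EEG epochs.

The generator works in two stages so that statistical recovery and waveform
quantification can be tested independently:

1.  *Amplitude planting.*  Per-trial P3b, CNV, ERN/CRN and FRN amplitudes are
    drawn from the declared linear models (condition effects, trial trend,
    baseline leaks, subject offsets, gaussian noise) and logged to a
    ground-truth table.  The cue-locked stage also returns the pure noise
    residuals, which the behavior simulator may couple into RT.
2.  *Rendering.*  Amplitudes are painted into 512 Hz multichannel epochs as
    temporally and topographically separated components (P3b: parietal
    positivity 250-550 ms; CNV: frontocentral ramp over the final 500 ms
    before the target; ERN: frontocentral deflection 0-100 ms post-response;
    FRN: positive-then-negative peak pair at FCz), on top of per-trial
    baseline offsets, 1/f background noise and a configured fraction of
    injected artifact epochs.  Component shapes are normalized against the
    quantifier's exact sample masks, so with noise switched off the windowed
    quantification recovers every planted amplitude to machine precision.

Epochs follow the Study-2 recording geometry (cue -200..1500 ms, stimulus /
response / feedback -200..800 ms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import stream
from .behavior import SubjectParams, design_codes
from .design import DesignConfig
from .epochs import EpochSet, epoch_time_axis

__all__ = [
    "ErpEffects",
    "CHANNELS",
    "EPOCH_WINDOWS_MS",
    "simulate_cue_amplitudes",
    "simulate_outcome_amplitudes",
    "rt_coupling_from_amplitudes",
    "acc_coupling_from_amplitudes",
    "render_epochs",
    "simulate_eeg_epochs",
]

CHANNELS = ("Fz", "FCz", "Cz", "Pz", "P3", "P4")
SAMPLING_RATE = 512.0
EPOCH_WINDOWS_MS = {
    "cue": (-200.0, 1500.0),
    "stimulus": (-200.0, 800.0),
    "response": (-200.0, 800.0),
    "feedback": (-200.0, 800.0),
}

# quantification geometry shared with erp.py
P3B_WINDOW = (250.0, 550.0)
P3B_ROI = ("Pz", "P3", "P4")
CNV_WINDOW = (1000.0, 1500.0)
CNV_ROI = ("Fz", "FCz", "Cz")
ERN_WINDOW = (0.0, 100.0)
ERN_ROI = ("FCz",)
FRN_CHANNEL = "FCz"


@dataclass(frozen=True)
class ErpEffects:
    """Planted population effects (microvolts) for the four components.

    Incentive predictors use the same centered codes as the analysis stage
    (two-level factors code to +/-0.5), ``trial`` applies per within-subject
    SD of trial number, ``acc`` codes accuracy - 0.5 and ``rewarded`` codes
    reward receipt - 0.5.  ``cnv_p3b_leak`` is the within-trial carry-over of
    P3b amplitude into the CNV (autocorrelation of the cue-locked signal),
    and the baseline leaks couple each amplitude to its own epoch baseline.
    RT gammas couple behavior to the standardized cue-locked residuals (ms
    per residual SD).
    """

    # P3b: positive parietal cue-locked component
    p3b_mean: float = 5.0
    p3b_reward: float = 0.7
    p3b_efficacy: float = 0.9
    p3b_interaction: float = 0.0
    p3b_trend: float = -1.1
    p3b_baseline_leak: float = 0.0
    p3b_noise_sd: float = 2.0
    # CNV: negative frontocentral ramp; effects grow the negativity
    cnv_mean: float = -2.0
    cnv_reward: float = -0.55
    cnv_efficacy: float = -0.6
    cnv_interaction: float = -0.7
    cnv_trend: float = 0.0
    cnv_p3b_leak: float = 0.16
    cnv_baseline_leak: float = -0.05
    cnv_noise_sd: float = 2.0
    # ERN/CRN: response-locked; errors more negative than correct responses
    ern_mean: float = -1.0
    ern_accuracy: float = 3.0
    ern_reward: float = 0.0
    ern_efficacy: float = 0.0
    ern_interaction: float = 1.5
    ern_noise_sd: float = 2.5
    # FRN: feedback-locked peak-to-peak magnitude (positive by construction)
    frn_mean: float = 5.0
    frn_rewarded: float = -0.8
    frn_rewarded_x_reward: float = -0.8
    frn_rewarded_x_efficacy: float = 0.8
    frn_reward: float = 0.0
    frn_efficacy: float = 0.0
    frn_noise_sd: float = 1.0
    frn_floor: float = 0.5
    # per-trial baseline offsets (SD, microvolts)
    baseline_sd: float = 3.0
    # behavior coupling to the standardized cue-locked residuals:
    # RT in ms per residual SD, accuracy in log-odds per residual SD
    rt_gamma_p3b: float = -4.0
    rt_gamma_cnv: float = 8.0
    acc_gamma_p3b: float = 0.10
    acc_gamma_cnv: float = -0.12

    @property
    def cnv_resid_sd(self) -> float:
        """SD of the CNV residual (own noise plus leaked P3b noise)."""
        return float(np.hypot(self.cnv_p3b_leak * self.p3b_noise_sd,
                              self.cnv_noise_sd))


def simulate_cue_amplitudes(
    specs: pd.DataFrame,
    subjects: list[SubjectParams],
    effects: ErpEffects,
    config: DesignConfig,
    seed: int,
) -> pd.DataFrame:
    """Plant cue-locked P3b/CNV amplitudes and their epoch baselines.

    Returns one row per trial with the planted amplitudes, the baselines and
    the pure noise residuals (``p3b_resid``, ``cnv_resid``) used for RT
    coupling.  Depends only on the trial design, so it can run before the
    behavior stage.
    """
    codes = design_codes(specs, config)
    by_id = {s.subject: s for s in subjects}
    p3b_off = np.array([by_id[s].p3b_offset for s in specs.subject])
    cnv_off = np.array([by_id[s].cnv_offset for s in specs.subject])

    rng = stream(seed, "erp-cue")
    n = len(specs)
    p3b_base = rng.normal(0.0, effects.baseline_sd, n)
    cnv_base = rng.normal(0.0, effects.baseline_sd, n)
    p3b_resid = rng.normal(0.0, effects.p3b_noise_sd, n)
    cnv_own = rng.normal(0.0, effects.cnv_noise_sd, n)

    p3b = (
        effects.p3b_mean
        + effects.p3b_reward * codes.rew_c
        + effects.p3b_efficacy * codes.eff_c
        + effects.p3b_interaction * codes.inter
        + effects.p3b_trend * codes.trial_c
        + effects.p3b_baseline_leak * p3b_base
        + p3b_off
        + p3b_resid
    )
    # The CNV leak applies to the full P3b amplitude (condition part included):
    # cnv = struct + leak * (p3b - p3b_mean) + baseline leak + offset + noise.
    cnv = (
        effects.cnv_mean
        + effects.cnv_reward * codes.rew_c
        + effects.cnv_efficacy * codes.eff_c
        + effects.cnv_interaction * codes.inter
        + effects.cnv_trend * codes.trial_c
        + effects.cnv_p3b_leak * (p3b - effects.p3b_mean)
        + effects.cnv_baseline_leak * cnv_base
        + cnv_off
        + cnv_own
    )
    return pd.DataFrame(
        {
            "subject": specs.subject.to_numpy(),
            "trial": specs.trial.to_numpy(),
            "p3b": p3b,
            "cnv": cnv,
            "p3b_baseline": p3b_base,
            "cnv_baseline": cnv_base,
            "p3b_resid": p3b_resid,
            "cnv_resid": effects.cnv_p3b_leak * p3b_resid + cnv_own,
        },
        index=specs.index,
    )


def simulate_outcome_amplitudes(
    records: pd.DataFrame,
    subjects: list[SubjectParams],
    effects: ErpEffects,
    config: DesignConfig,
    seed: int,
) -> pd.DataFrame:
    """Plant response-locked ERN/CRN and feedback-locked FRN amplitudes.

    Requires behavior (accuracy and reward outcomes).  Trials without a
    response carry NaN ERN (no response-locked epoch exists).  FRN is a
    peak-to-peak magnitude, floored at ``frn_floor``.
    """
    codes = design_codes(records, config)
    by_id = {s.subject: s for s in subjects}
    ern_off = np.array([by_id[s].ern_offset for s in records.subject])
    frn_off = np.array([by_id[s].frn_offset for s in records.subject])

    rng = stream(seed, "erp-outcome")
    n = len(records)
    ern_base = rng.normal(0.0, effects.baseline_sd, n)
    frn_base = rng.normal(0.0, effects.baseline_sd, n)

    acc_dev = records.accuracy.to_numpy() - 0.5
    ern = (
        effects.ern_mean
        + effects.ern_accuracy * acc_dev
        + effects.ern_reward * codes.rew_c
        + effects.ern_efficacy * codes.eff_c
        + effects.ern_interaction * codes.inter
        + ern_off
        + rng.normal(0.0, effects.ern_noise_sd, n)
    )
    ern[records.rt_missing.to_numpy().astype(bool)] = np.nan

    rwd_dev = records.rewarded.to_numpy() - 0.5
    frn = (
        effects.frn_mean
        + effects.frn_rewarded * rwd_dev
        + effects.frn_rewarded_x_reward * rwd_dev * codes.rew_c
        + effects.frn_rewarded_x_efficacy * rwd_dev * codes.eff_c
        + effects.frn_reward * codes.rew_c
        + effects.frn_efficacy * codes.eff_c
        + frn_off
        + rng.normal(0.0, effects.frn_noise_sd, n)
    )
    frn = np.maximum(frn, effects.frn_floor)
    return pd.DataFrame(
        {
            "subject": records.subject.to_numpy(),
            "trial": records.trial.to_numpy(),
            "ern": ern,
            "frn": frn,
            "ern_baseline": ern_base,
            "frn_baseline": frn_base,
        },
        index=records.index,
    )


def rt_coupling_from_amplitudes(cue_amps: pd.DataFrame,
                                effects: ErpEffects) -> np.ndarray:
    """Additive RT term (ms) from standardized cue-locked residuals.

    Coupling to residuals (not full amplitudes) keeps the behavioral
    condition contrasts orthogonal to the neural noise, so the behavior-only
    model ground truths remain exact.
    """
    z_p3b = cue_amps.p3b_resid.to_numpy() / effects.p3b_noise_sd
    z_cnv = cue_amps.cnv_resid.to_numpy() / effects.cnv_resid_sd
    return effects.rt_gamma_p3b * z_p3b + effects.rt_gamma_cnv * z_cnv


def acc_coupling_from_amplitudes(cue_amps: pd.DataFrame,
                                 effects: ErpEffects) -> np.ndarray:
    """Additive accuracy log-odds term from standardized cue residuals."""
    z_p3b = cue_amps.p3b_resid.to_numpy() / effects.p3b_noise_sd
    z_cnv = cue_amps.cnv_resid.to_numpy() / effects.cnv_resid_sd
    return effects.acc_gamma_p3b * z_p3b + effects.acc_gamma_cnv * z_cnv


# ---------------------------------------------------------------------------
# rendering

def _hann_bump(times: np.ndarray, center: float, half_width: float) -> np.ndarray:
    """Compact-support raised-cosine bump, zero outside +/- half_width."""
    x = (times - center) / half_width
    out = np.where(np.abs(x) < 1.0, 0.5 * (1.0 + np.cos(np.pi * x)), 0.0)
    return out


def _component_kernels(times: np.ndarray) -> dict:
    """Temporal kernels normalized against the quantifier's sample masks."""
    kernels = {}
    # P3b: raised cosine spanning its window, unit mean over the window samples
    mask = (times >= P3B_WINDOW[0] - 1e-9) & (times <= P3B_WINDOW[1] + 1e-9)
    k = _hann_bump(times, center=np.mean(P3B_WINDOW),
                   half_width=(P3B_WINDOW[1] - P3B_WINDOW[0]) / 2.0)
    kernels["p3b"] = k / k[mask].mean()
    # CNV: linear ramp over the final 500 ms pre-target, unit window mean
    mask = (times >= CNV_WINDOW[0] - 1e-9) & (times <= CNV_WINDOW[1] + 1e-9)
    ramp = np.clip((times - CNV_WINDOW[0]) / (CNV_WINDOW[1] - CNV_WINDOW[0]), 0, None)
    ramp[times < CNV_WINDOW[0]] = 0.0
    kernels["cnv"] = ramp / ramp[mask].mean()
    return kernels


def _topography(channel_weights: dict) -> np.ndarray:
    w = np.zeros(len(CHANNELS))
    for name, val in channel_weights.items():
        w[CHANNELS.index(name)] = val
    return w


# smooth weight vectors, unit mean over each component's quantification ROI
P3B_WEIGHTS = {"Pz": 1.2, "P3": 0.9, "P4": 0.9}
CNV_WEIGHTS = {"Fz": 0.9, "FCz": 1.1, "Cz": 1.0}
ERN_WEIGHTS = {"FCz": 1.0, "Cz": 0.7, "Fz": 0.5}


def _one_over_f_noise(rng: np.random.Generator, shape: tuple, n_times: int,
                      rms: float) -> np.ndarray:
    """Background noise with a 1/f amplitude spectrum, target RMS per trace."""
    if rms <= 0:
        return np.zeros(shape + (n_times,))
    n_freq = n_times // 2 + 1
    spec = rng.normal(size=shape + (n_freq,)) + 1j * rng.normal(size=shape + (n_freq,))
    freqs = np.arange(n_freq, dtype=float)
    freqs[0] = np.inf  # no DC component
    spec = spec / np.sqrt(freqs)
    noise = np.fft.irfft(spec, n=n_times, axis=-1)
    scale = rms / np.sqrt(np.mean(noise**2, axis=-1, keepdims=True))
    return noise * scale


def render_epochs(
    records: pd.DataFrame,
    cue_amps: pd.DataFrame,
    outcome_amps: pd.DataFrame,
    seed: int,
    anchors=("cue", "response", "feedback"),
    noise_rms: float = 8.0,
    artifact_fraction: float = 0.05,
    frn_positive_peak: float = 2.0,
) -> dict:
    """Render amplitude tables into 512 Hz multichannel epochs.

    Returns ``{anchor: EpochSet}``.  Response-locked epochs exist only for
    trials with a recorded response.  ``artifact_fraction`` of each anchor's
    epochs receive an injected artifact (alternating >150 uV spikes and
    >50 uV sample-to-sample jumps); injection is deterministic under seed and
    the injected count is exactly ``round(fraction * n_epochs)``.
    """
    merged = records.merge(cue_amps, on=["subject", "trial"]).merge(
        outcome_amps, on=["subject", "trial"]
    )
    out = {}
    rng = stream(seed, "render")
    for anchor in anchors:
        times = epoch_time_axis(EPOCH_WINDOWS_MS[anchor], SAMPLING_RATE)
        if anchor == "response":
            rows = merged[merged.rt_missing == 0].reset_index(drop=True)
        else:
            rows = merged.reset_index(drop=True)
        n, n_ch, n_t = len(rows), len(CHANNELS), len(times)
        data = np.zeros((n, n_ch, n_t))

        if anchor == "cue":
            kernels = _component_kernels(times)
            w_p3b = _topography(P3B_WEIGHTS)
            w_cnv = _topography(CNV_WEIGHTS)
            data += (
                rows.p3b.to_numpy()[:, None, None]
                * w_p3b[None, :, None] * kernels["p3b"][None, None, :]
            )
            data += (
                rows.cnv.to_numpy()[:, None, None]
                * w_cnv[None, :, None] * kernels["cnv"][None, None, :]
            )
            # baseline offsets: parietal channels carry the P3b-epoch baseline,
            # frontocentral the CNV baseline (constant across the epoch)
            par = _topography({c: 1.0 for c in P3B_ROI})
            fro = _topography({c: 1.0 for c in CNV_ROI})
            data += rows.p3b_baseline.to_numpy()[:, None, None] * par[None, :, None]
            data += rows.cnv_baseline.to_numpy()[:, None, None] * fro[None, :, None]
        elif anchor == "response":
            mask = (times >= ERN_WINDOW[0] - 1e-9) & (times <= ERN_WINDOW[1] + 1e-9)
            # support exactly [0, 100] ms so the component cannot bleed into
            # the baseline interval
            k = _hann_bump(times, center=np.mean(ERN_WINDOW),
                           half_width=(ERN_WINDOW[1] - ERN_WINDOW[0]) / 2.0)
            k = k / k[mask].mean()
            w = _topography(ERN_WEIGHTS)
            data += (
                rows.ern.to_numpy()[:, None, None]
                * w[None, :, None] * k[None, None, :]
            )
            data += rows.ern_baseline.to_numpy()[:, None, None]
        elif anchor == "feedback":
            ch = CHANNELS.index(FRN_CHANNEL)
            # positive peak ~220 ms then trough ~300 ms; both centered on
            # exact sample times so the sampled extrema equal the targets
            t_peak = times[np.argmin(np.abs(times - 220.0))]
            t_trough = times[np.argmin(np.abs(times - 300.0))]
            bump = _hann_bump(times, t_peak, 30.0)
            bump /= bump.max()
            trough = _hann_bump(times, t_trough, 40.0)
            trough /= trough.max()
            p2p = rows.frn.to_numpy()
            # cap the positive peak at half the planted peak-to-peak so the
            # trough stays negative and the quantified difference is exact
            # even for small planted values
            pos = np.minimum(frn_positive_peak, p2p / 2.0)
            data[:, ch, :] += pos[:, None] * bump[None, :]
            data[:, ch, :] -= (p2p - pos)[:, None] * trough[None, :]
            data += rows.frn_baseline.to_numpy()[:, None, None]
        elif anchor == "stimulus":
            pass  # background-only epochs; nothing is quantified here
        else:
            raise ValueError(f"unknown anchor {anchor!r}")

        data += _one_over_f_noise(rng, (n, n_ch), n_t, noise_rms)

        n_artifacts = int(round(artifact_fraction * n))
        if n_artifacts:
            post = np.flatnonzero(times >= 0)
            idx = rng.choice(n, size=n_artifacts, replace=False)
            for j, i in enumerate(sorted(idx)):
                c = int(rng.integers(n_ch))
                s = int(rng.choice(post[:-6]))
                if j % 2 == 0:
                    data[i, c, s] += 200.0  # amplitude artifact
                else:
                    data[i, c, s : s + 3] += 60.0  # gradient artifact

        out[anchor] = EpochSet(
            data=data,
            times=times,
            channels=CHANNELS,
            anchor=anchor,
            sampling_rate=SAMPLING_RATE,
            subjects=rows.subject.to_numpy(),
            trials=rows.trial.to_numpy(),
        )
    return out


def simulate_eeg_epochs(
    records: pd.DataFrame,
    subjects: list[SubjectParams],
    effects: ErpEffects,
    config: DesignConfig,
    seed: int,
    **render_kwargs,
):
    """Plant amplitudes for all components and render their epochs.

    Returns ``(epoch_sets, ground_truth)`` where ``ground_truth`` is the
    merged per-trial amplitude table (the generator's ledger).
    """
    cue = simulate_cue_amplitudes(records, subjects, effects, config, seed)
    outcome = simulate_outcome_amplitudes(records, subjects, effects, config, seed)
    truth = cue.merge(outcome, on=["subject", "trial"])
    epoch_sets = render_epochs(records, cue, outcome, seed, **render_kwargs)
    return epoch_sets, truth
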