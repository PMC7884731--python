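"""Single-trial ERP quantification.

All quantities are computed condition-agnostically, with ROIs and time
windows fixed a priori:

* baseline correction by the mean over the 200 ms preceding the anchor,
  returning the subtracted means for use as nuisance regressors;
* artifact rejection at +/-150 uV absolute amplitude or 50 uV
  sample-to-sample gradient;
* windowed mean amplitudes — cue-locked P3b (250-550 ms over Pz/P3/P4),
  cue-locked late CNV (1000-1500 ms over Fz/FCz/Cz), response-locked
  ERN/CRN (0-100 ms at FCz);
* feedback-locked FRN quantified peak-to-peak at FCz: the negative peak in
  250-350 ms minus the positive peak in the 100 ms preceding it;
* odd/even-trial split-half reliability of any per-trial measure.

Conventions: the baseline interval is half-open [-200, 0) ms; quantification
windows are closed at both ends; the gradient is the absolute difference of
successive samples.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .epochs import EpochSet

__all__ = [
    "baseline_correct",
    "reject_artifacts",
    "mean_amplitude",
    "frn_peak_to_peak",
    "split_half_reliability",
    "quantify_epochs",
    "zscore_within",
]

BASELINE_MS = (-200.0, 0.0)
AMP_LIMIT_UV = 150.0
GRADIENT_LIMIT_UV = 50.0

P3B_WINDOW_MS = (250.0, 550.0)
P3B_ROI = ("Pz", "P3", "P4")
CNV_WINDOW_MS = (1000.0, 1500.0)
CNV_ROI = ("Fz", "FCz", "Cz")
ERN_WINDOW_MS = (0.0, 100.0)
ERN_ROI = ("FCz",)
FRN_CHANNEL = "FCz"
FRN_TROUGH_WINDOW_MS = (250.0, 350.0)
FRN_PRECEDING_MS = 100.0


def baseline_correct(epochs: EpochSet):
    """Subtract each trial/channel's pre-anchor mean ([-200, 0) ms).

    Returns ``(corrected EpochSet, baselines)`` where baselines has shape
    (n_trials, n_channels) and holds the subtracted means, later used as
    nuisance covariates in the single-trial models.
    """
    mask = epochs.time_mask(*BASELINE_MS, closed="left")
    if not mask.any():
        raise ValueError("epoch window does not cover the baseline interval")
    baselines = epochs.data[:, :, mask].mean(axis=2)
    corrected = EpochSet(
        data=epochs.data - baselines[:, :, None],
        times=epochs.times,
        channels=epochs.channels,
        anchor=epochs.anchor,
        sampling_rate=epochs.sampling_rate,
        subjects=epochs.subjects,
        trials=epochs.trials,
    )
    return corrected, baselines


def reject_artifacts(
    epochs: EpochSet,
    amp_limit: float = AMP_LIMIT_UV,
    gradient_limit: float = GRADIENT_LIMIT_UV,
) -> np.ndarray:
    """Boolean mask of rejected epochs.

    An epoch is rejected if any channel sample exceeds ``amp_limit`` in
    absolute value or if any two successive samples differ by more than
    ``gradient_limit``.  Invariant to channel and epoch ordering.
    """
    amp_bad = np.abs(epochs.data) > amp_limit
    grad_bad = np.abs(np.diff(epochs.data, axis=2)) > gradient_limit
    return amp_bad.any(axis=(1, 2)) | grad_bad.any(axis=(1, 2))


def mean_amplitude(epochs: EpochSet, window_ms: tuple, channels) -> np.ndarray:
    """Per-trial mean amplitude over a closed time window and an ROI."""
    ch = epochs.channel_index(channels)
    mask = epochs.time_mask(*window_ms, closed="both")
    if not mask.any():
        raise ValueError(f"window {window_ms} falls outside the epoch")
    return epochs.data[:, ch, :][:, :, mask].mean(axis=(1, 2))


def frn_peak_to_peak(epochs: EpochSet, channel: str = FRN_CHANNEL) -> np.ndarray:
    """Peak-to-peak FRN per trial.

    Finds the negative peak within 250-350 ms post-feedback, then the
    positive peak within the 100 ms strictly preceding that latency, and
    returns their difference (positive peak minus negative peak).  A flat
    epoch yields 0.
    """
    ch = epochs.channel_index([channel])[0]
    trough_mask = epochs.time_mask(*FRN_TROUGH_WINDOW_MS, closed="both")
    trough_idx = np.flatnonzero(trough_mask)
    x = epochs.data[:, ch, :]
    rel_min = np.argmin(x[:, trough_idx], axis=1)
    out = np.empty(epochs.n_trials)
    for i in range(epochs.n_trials):
        j = trough_idx[rel_min[i]]
        t_trough = epochs.times[j]
        pre = epochs.time_mask(t_trough - FRN_PRECEDING_MS, t_trough, closed="left")
        if not pre.any():
            out[i] = 0.0
            continue
        out[i] = x[i, pre].max() - x[i, j]
    return out


def split_half_reliability(values, subjects, trials) -> float:
    """Odd/even-trial split-half reliability of a per-trial measure.

    Per subject, the measure is averaged over odd- and even-numbered trials;
    the returned value is the Pearson correlation of the two subject-level
    mean vectors.  Subjects lacking a finite value in either half are
    excluded with a warning.
    """
    df = pd.DataFrame({
        "subject": np.asarray(subjects),
        "odd": np.asarray(trials) % 2 == 1,
        "value": np.asarray(values, dtype=float),
    }).dropna(subset=["value"])
    halves = df.groupby(["subject", "odd"])["value"].mean().unstack("odd")
    complete = halves.dropna()
    if len(complete) < len(halves):
        warnings.warn(
            f"excluding {len(halves) - len(complete)} subject(s) with an empty "
            "odd or even half", stacklevel=2,
        )
    if len(complete) < 2:
        raise ValueError("split-half reliability needs >= 2 complete subjects")
    return float(np.corrcoef(complete[False], complete[True])[0, 1])


def zscore_within(values, subjects) -> np.ndarray:
    """Z-score a measure within subject (mean 0, SD 1 per subject)."""
    s = pd.Series(np.asarray(values, dtype=float))
    grp = s.groupby(np.asarray(subjects))
    return ((s - grp.transform("mean")) / grp.transform("std")).to_numpy()


def quantify_epochs(epoch_sets: dict) -> pd.DataFrame:
    """Quantify all available anchors into a per-trial amplitude table.

    Expects a dict with any of the keys ``cue``, ``response``, ``feedback``
    mapping to raw (uncorrected) EpochSets.  Each anchor is baseline-
    corrected, artifact-flagged and quantified; rejected trials carry NaN
    amplitudes and ``<anchor>_rejected = 1``.  Columns: ``p3b, cnv,
    p3b_baseline, cnv_baseline, ern, ern_baseline, frn, frn_baseline`` plus
    rejection flags, keyed by subject/trial.
    """
    frames = []
    if "cue" in epoch_sets:
        corrected, baselines = baseline_correct(epoch_sets["cue"])
        rejected = reject_artifacts(corrected)
        p3b = mean_amplitude(corrected, P3B_WINDOW_MS, P3B_ROI)
        cnv = mean_amplitude(corrected, CNV_WINDOW_MS, CNV_ROI)
        p3b_base = baselines[:, corrected.channel_index(P3B_ROI)].mean(axis=1)
        cnv_base = baselines[:, corrected.channel_index(CNV_ROI)].mean(axis=1)
        p3b[rejected] = np.nan
        cnv[rejected] = np.nan
        frames.append(pd.DataFrame({
            "subject": corrected.subjects, "trial": corrected.trials,
            "p3b": p3b, "cnv": cnv,
            "p3b_baseline": p3b_base, "cnv_baseline": cnv_base,
            "cue_rejected": rejected.astype(int),
        }))
    if "response" in epoch_sets:
        corrected, baselines = baseline_correct(epoch_sets["response"])
        rejected = reject_artifacts(corrected)
        ern = mean_amplitude(corrected, ERN_WINDOW_MS, ERN_ROI)
        ern_base = baselines[:, corrected.channel_index(ERN_ROI)].mean(axis=1)
        ern[rejected] = np.nan
        frames.append(pd.DataFrame({
            "subject": corrected.subjects, "trial": corrected.trials,
            "ern": ern, "ern_baseline": ern_base,
            "response_rejected": rejected.astype(int),
        }))
    if "feedback" in epoch_sets:
        corrected, baselines = baseline_correct(epoch_sets["feedback"])
        rejected = reject_artifacts(corrected)
        frn = frn_peak_to_peak(corrected)
        frn_base = baselines[:, corrected.channel_index([FRN_CHANNEL])].mean(axis=1)
        frn[rejected] = np.nan
        frames.append(pd.DataFrame({
            "subject": corrected.subjects, "trial": corrected.trials,
            "frn": frn, "frn_baseline": frn_base,
            "feedback_rejected": rejected.astype(int),
        }))
    if not frames:
        raise ValueError("no quantifiable anchors in epoch_sets")
    out = frames[0]
    for f in frames[1:]:
        out = out.merge(f, on=["subject", "trial"], how="outer")
    return out.sort_values(["subject", "trial"]).reset_index(drop=True)
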