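"""Synthetic continuous pupil recordings for the incentive Stroop task.

Each subject's session is a single 500 Hz trace built by forward convolution:
every task event (cue, target, response, feedback, and the inter-trial
fixation) contributes an Erlang-gamma impulse response scaled by its planted
amplitude.  The cue response shrinks with cued efficacy — the planted
counterpart of the empirical finding that pupil responses are larger under
low efficacy (arousal tracking outcome uncertainty, not control).  Slow
sinusoidal drift, white noise and blink gaps complete the trace.  All planted
amplitudes are logged per event for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import stream
from .behavior import SubjectParams
from .design import DesignConfig
from .pupil import IrfParams, PupilSeries, irf_train

__all__ = ["PupilSimParams", "simulate_pupil_subject", "simulate_pupil"]

SAMPLING_RATE = 500.0


@dataclass(frozen=True)
class PupilSimParams:
    """Planted pupil response amplitudes (arbitrary trace units) and noise.

    The cue amplitude is ``cue_base - cue_efficacy_gain * efficacy``
    (+ the subject's gain offset): 1.0 for 0% efficacy, 0.7 for 100% at the
    defaults.  Reward does not modulate the planted cue response.
    """

    cue_base: float = 1.0
    cue_efficacy_gain: float = 0.3
    fixation_amplitude: float = 0.3
    target_amplitude: float = 0.8
    response_amplitude: float = 0.5
    feedback_amplitude: float = 0.9
    noise_sd: float = 0.1  # white noise per 500 Hz sample
    drift_amplitude: float = 0.05
    drift_period_s: float = 120.0
    blink_rate_per_min: float = 15.0
    blink_duration_ms: float = 120.0
    blink_duration_sd_ms: float = 30.0
    iti_range_s: tuple = (0.5, 1.0)


def _trial_events(records: pd.DataFrame, config: DesignConfig,
                  rng: np.random.Generator,
                  params: PupilSimParams) -> pd.DataFrame:
    """Chronological event table (time_s, event, trial) for one subject."""
    rows = []
    t = 1.0  # settle-in before the first trial
    for r in records.itertuples():
        cue_t = t
        target_t = cue_t + (config.cue_duration_ms + config.fixation_ms) / 1000.0
        rows.append((cue_t, "cue", r.trial))
        rows.append((target_t, "target", r.trial))
        if r.rt_missing:
            # no response; feedback after the full recording window
            fb_t = target_t + (config.recording_window_ms
                               + config.post_response_blank_ms) / 1000.0
        else:
            resp_t = target_t + r.rt / 1000.0
            rows.append((resp_t, "response", r.trial))
            fb_t = resp_t + config.post_response_blank_ms / 1000.0
        rows.append((fb_t, "feedback", r.trial))
        iti_t = fb_t + config.feedback_duration_ms / 1000.0
        rows.append((iti_t, "fixation", r.trial))
        t = iti_t + rng.uniform(*params.iti_range_s)
    return pd.DataFrame(rows, columns=["time_s", "event", "trial"])


def simulate_pupil_subject(
    records: pd.DataFrame,
    subject: SubjectParams,
    params: PupilSimParams,
    irf: IrfParams,
    config: DesignConfig,
    seed: int,
) -> tuple[PupilSeries, pd.DataFrame]:
    """Simulate one subject's continuous 500 Hz pupil trace.

    Returns ``(series, events)``; ``events`` carries one row per event with
    its planted amplitude and a ``regressor`` label (cue events are labelled
    per incentive condition so condition-specific coefficients can be fit).
    """
    records = records.sort_values("trial")
    rng = stream(seed, "pupil", subject.subject)
    events = _trial_events(records, config, rng, params)

    amp_map = {
        "fixation": params.fixation_amplitude,
        "target": params.target_amplitude,
        "response": params.response_amplitude,
        "feedback": params.feedback_amplitude,
    }
    cond = records.set_index("trial")[["reward", "efficacy"]]
    amplitudes, labels = [], []
    for r in events.itertuples():
        if r.event == "cue":
            e = cond.loc[r.trial, "efficacy"]
            rew = cond.loc[r.trial, "reward"]
            amplitudes.append(
                params.cue_base - params.cue_efficacy_gain * e + subject.pupil_gain
            )
            labels.append(f"cue_r{rew:g}_e{e:g}")
        else:
            amplitudes.append(amp_map[r.event])
            labels.append(r.event)
    events = events.assign(amplitude=amplitudes, regressor=labels)

    duration = events.time_s.max() + 6.0  # room for the last response to decay
    n = int(np.ceil(duration * SAMPLING_RATE / 25.0)) * 25  # multiple of the
    # 500 -> 20 Hz decimation factor, so no samples are trimmed downstream
    trace = np.zeros(n)
    for amp, grp in events.groupby("amplitude"):
        trace += amp * irf_train(grp.time_s.to_numpy(), n, SAMPLING_RATE, irf)
    t = np.arange(n) / SAMPLING_RATE
    if params.drift_amplitude:
        trace += params.drift_amplitude * np.sin(
            2 * np.pi * t / params.drift_period_s + rng.uniform(0, 2 * np.pi)
        )
    if params.noise_sd:
        trace += rng.normal(0.0, params.noise_sd, n)

    blink_mask = np.zeros(n, dtype=bool)
    n_blinks = rng.poisson(params.blink_rate_per_min * duration / 60.0)
    for _ in range(n_blinks):
        onset = rng.uniform(1.0, duration - 1.0)
        dur = max(rng.normal(params.blink_duration_ms,
                             params.blink_duration_sd_ms), 20.0) / 1000.0
        if onset + dur >= duration:
            raise ValueError("blink extends beyond the trace")
        lo = int(onset * SAMPLING_RATE)
        hi = min(int((onset + dur) * SAMPLING_RATE), n - 1)
        blink_mask[lo : hi + 1] = True
        trace[lo : hi + 1] -= 2.0  # signal loss during lid closure

    series = PupilSeries(
        time=t, diameter=trace, sampling_rate=SAMPLING_RATE, blink_mask=blink_mask
    )
    return series, events


def simulate_pupil(
    records: pd.DataFrame,
    subjects: list[SubjectParams],
    params: PupilSimParams,
    irf: IrfParams,
    config: DesignConfig,
    seed: int,
):
    """Yield ``(subject_id, series, events)`` per subject.

    A generator, so callers can process one subject's trace at a time
    without holding every 500 Hz session in memory.
    """
    by_id = {s.subject: s for s in subjects}
    for subject_id, g in records.groupby("subject"):
        series, events = simulate_pupil_subject(
            g, by_id[subject_id], params, irf, config, seed
        )
        yield subject_id, series, events
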