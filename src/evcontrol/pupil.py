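"""Pupillometry: Erlang-gamma impulse response, preprocessing, deconvolution.

The pupil is treated as a linear time-invariant system: each task event
(fixation, cue, target, response, feedback) triggers a stereotyped impulse
response and the recorded trace is the superposition of all responses plus
drift and noise.  The impulse response is the Erlang-gamma form

    h(t) = t**n * exp(-n * t / t_max)

with shape ``n = 10.1`` and response-maximum latency ``t_max = 1.30 s``,
rescaled to unit peak so that fitted coefficients are in trace units.

Deconvolution builds one regressor per event type — the superposed
unit-amplitude impulse responses of that type's events — on an oversampled
grid, decimates it exactly like the data (non-overlapping block means), and
solves ordinary least squares.  Because regressor construction mirrors the
forward model, the noise-free forward-then-inverse round trip is exact to
numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IrfParams",
    "PupilSeries",
    "PupilFit",
    "erlang_irf",
    "irf_train",
    "interpolate_blinks",
    "downsample",
    "preprocess",
    "deconvolve",
]


@dataclass(frozen=True)
class IrfParams:
    """Erlang-gamma impulse response parameters.

    ``n`` is the dimensionless shape; ``t_max`` (seconds) is the latency at
    which the response peaks.
    """

    n: float = 10.1
    t_max: float = 1.30

    def __post_init__(self) -> None:
        if self.n <= 0 or self.t_max <= 0:
            raise ValueError("IrfParams require n > 0 and t_max > 0")


def erlang_irf(t, params: IrfParams = IrfParams()):
    """Unit-peak Erlang-gamma impulse response evaluated at times ``t`` (s).

    Causal: zero for t <= 0.  Computed in log space (t**10.1 overflows
    nothing here, but the unnormalized peak is ~t_max**n, so normalizing via
    logs keeps the arithmetic well-scaled).  Peaks at exactly ``t_max``.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    n, tmax = params.n, params.t_max
    # log h(t) - log h(t_max); h(t_max) = t_max**n * exp(-n)
    log_h = n * np.log(t[pos] / tmax) - n * t[pos] / tmax + n
    out[pos] = np.exp(log_h)
    return float(out) if out.ndim == 0 else out


@dataclass
class PupilSeries:
    """Uniformly sampled pupil diameter trace.

    ``time`` in seconds, ``diameter`` in recording units (z-units after
    preprocessing), ``blink_mask`` flags samples lost to blinks.
    """

    time: np.ndarray
    diameter: np.ndarray
    sampling_rate: float
    blink_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.diameter = np.asarray(self.diameter, dtype=float)
        if self.time.shape != self.diameter.shape:
            raise ValueError("time and diameter must have the same length")
        if self.blink_mask is not None:
            self.blink_mask = np.asarray(self.blink_mask, dtype=bool)

    @property
    def duration(self) -> float:
        return len(self.time) / self.sampling_rate


@dataclass
class PupilFit:
    """Per-event-type response magnitudes from least-squares deconvolution."""

    coefficients: dict
    intercept: float
    residual_variance: float
    condition_number: float
    n_samples: int


def irf_train(event_times, n_samples: int, sampling_rate: float,
              params: IrfParams) -> np.ndarray:
    """Superposed unit-peak impulse responses at the given event times.

    Events are snapped to the nearest sample; the train is evaluated on the
    sample grid (the forward model of the generator and the regressor
    constructor of the deconvolution share this function).
    """
    t = np.arange(n_samples) / sampling_rate
    out = np.zeros(n_samples)
    for te in np.atleast_1d(np.asarray(event_times, dtype=float)):
        j = int(round(te * sampling_rate))
        if j >= n_samples:
            continue
        out[j:] += erlang_irf(t[: n_samples - j], params)
    return out


def interpolate_blinks(series: PupilSeries, pad_ms: float = 200.0) -> PupilSeries:
    """Linearly interpolate across blink gaps.

    Each contiguous blink run is widened by ``pad_ms`` on both sides (from
    200 ms before blink onset to 200 ms after blink offset) and the widened
    window is replaced by the line between the nearest valid boundary
    samples.  Blinks abutting the trace edge extend the nearest valid value.
    """
    if series.blink_mask is None or not series.blink_mask.any():
        return series
    pad = int(round(pad_ms / 1000.0 * series.sampling_rate))
    mask = series.blink_mask.copy()
    # widen each blink run by pad samples on both sides
    idx = np.flatnonzero(mask)
    splits = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, splits + 1)
    widened = np.zeros_like(mask)
    for run in runs:
        lo = max(run[0] - pad, 0)
        hi = min(run[-1] + pad, len(mask) - 1)
        widened[lo : hi + 1] = True
    diameter = series.diameter.copy()
    valid = ~widened
    if not valid.any():
        raise ValueError("blink windows cover the entire trace")
    diameter[widened] = np.interp(
        series.time[widened], series.time[valid], diameter[valid]
    )
    return PupilSeries(
        time=series.time, diameter=diameter,
        sampling_rate=series.sampling_rate,
        blink_mask=np.zeros_like(mask),
    )


def downsample(series: PupilSeries, target_rate: float = 20.0) -> PupilSeries:
    """Decimate by non-overlapping block means to ``target_rate``."""
    factor = series.sampling_rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"sampling rate {series.sampling_rate} is not an integer multiple "
            f"of target rate {target_rate}"
        )
    factor = int(round(factor))
    n_out = len(series.diameter) // factor
    d = series.diameter[: n_out * factor].reshape(n_out, factor).mean(axis=1)
    t = series.time[: n_out * factor].reshape(n_out, factor)[:, 0]
    return PupilSeries(time=t, diameter=d, sampling_rate=target_rate)


def preprocess(series: PupilSeries, target_rate: float = 20.0,
               normalize: bool = True) -> PupilSeries:
    """Downsample a blink-interpolated trace to 20 Hz and z-score it.

    Z-scoring is within subject: subtract the mean of all samples, divide by
    their SD.  Raises on a zero-variance trace.
    """
    out = downsample(series, target_rate)
    if normalize:
        sd = out.diameter.std()
        if sd == 0:
            raise ValueError("cannot z-score a constant pupil trace")
        out = PupilSeries(
            time=out.time,
            diameter=(out.diameter - out.diameter.mean()) / sd,
            sampling_rate=out.sampling_rate,
        )
    return out


def deconvolve(
    series: PupilSeries,
    events: pd.DataFrame,
    params: IrfParams = IrfParams(),
    oversample: int = 25,
    include_drift: bool = False,
) -> PupilFit:
    """Estimate per-event-type response magnitudes by OLS deconvolution.

    ``events`` needs columns ``time_s`` and ``regressor`` (event type,
    optionally condition-specific).  For each regressor label the design
    column is the unit-peak impulse-response train of its events, built at
    ``oversample`` times the series rate and block-mean decimated exactly as
    ``preprocess`` decimates the data.  An intercept (and optionally a linear
    drift term) completes the design.

    Raises on rank-deficient designs, naming the collinear regressors.
    """
    if not len(events):
        raise ValueError("no events to deconvolve")
    t_max_event = events["time_s"].max()
    if t_max_event > series.time[-1] + 1.0 / series.sampling_rate:
        raise ValueError("event times extend beyond the trace")
    labels = list(dict.fromkeys(events["regressor"]))
    fine_rate = series.sampling_rate * oversample
    n_fine = len(series.diameter) * oversample
    cols = []
    for label in labels:
        times = events.loc[events["regressor"] == label, "time_s"].to_numpy()
        fine = irf_train(times, n_fine, fine_rate, params)
        cols.append(fine.reshape(-1, oversample).mean(axis=1))
    X = [np.ones(len(series.diameter))]
    names = ["intercept"]
    if include_drift:
        X.append(np.linspace(-0.5, 0.5, len(series.diameter)))
        names.append("drift")
    X.extend(cols)
    names.extend(labels)
    X = np.column_stack(X)

    sv = np.linalg.svd(X, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    if sv[-1] <= sv[0] * 1e-10:
        raise np.linalg.LinAlgError(
            f"singular deconvolution design (regressors: {labels}); "
            "check for event types with identical or empty event trains"
        )
    beta, *_ = np.linalg.lstsq(X, series.diameter, rcond=None)
    resid = series.diameter - X @ beta
    dof = max(len(series.diameter) - X.shape[1], 1)
    coefs = dict(zip(names, beta))
    return PupilFit(
        coefficients={k: float(v) for k, v in coefs.items()
                      if k not in ("intercept", "drift")},
        intercept=float(coefs["intercept"]),
        residual_variance=float(resid @ resid / dof),
        condition_number=cond,
        n_samples=len(series.diameter),
    )
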