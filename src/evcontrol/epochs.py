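"""Epoched EEG container: trial x channel x time arrays with metadata.

Epochs are stored in memory as a single float64 array plus a time axis in ms
relative to the anchor event (cue, stimulus, response or feedback onset).
On disk an EpochSet is a flat ``.npy`` array next to a JSON sidecar carrying
channel names, sampling rate, the epoch window and the (subject, trial) keys.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["EpochSet", "epoch_time_axis"]


def epoch_time_axis(window_ms: tuple, sampling_rate: float) -> np.ndarray:
    """Sample times (ms, anchor-relative) for an epoch window at a given rate.

    Samples sit at ``start + i * 1000 / rate``; the end of the window is
    exclusive, so a (-200, 800) ms window at 512 Hz has 512 samples.
    """
    start, end = window_ms
    n = int(round((end - start) * sampling_rate / 1000.0))
    return start + np.arange(n) * (1000.0 / sampling_rate)


@dataclass
class EpochSet:
    """Single-anchor epoch collection.

    data
        Array of shape (n_trials, n_channels, n_times), microvolts.
    times
        Anchor-relative sample times in ms.
    channels
        Unique channel names, one per data row.
    anchor
        Event the epochs are locked to ("cue", "stimulus", "response",
        "feedback").
    subjects, trials
        Per-epoch keys into the trial table.
    """

    data: np.ndarray
    times: np.ndarray
    channels: tuple
    anchor: str
    sampling_rate: float
    subjects: np.ndarray
    trials: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, times)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel axis does not match channel names")
        if self.data.shape[2] != len(self.times):
            raise ValueError("time axis does not match times")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_index(self, names) -> np.ndarray:
        idx = []
        for name in names:
            if name not in self.channels:
                raise KeyError(f"unknown channel {name!r}; have {self.channels}")
            idx.append(self.channels.index(name))
        return np.asarray(idx, dtype=int)

    def time_mask(self, start_ms: float, end_ms: float,
                  closed: str = "both") -> np.ndarray:
        """Boolean mask over samples; ``closed`` is 'both' or 'left'."""
        t = self.times
        if closed == "both":
            return (t >= start_ms - 1e-9) & (t <= end_ms + 1e-9)
        if closed == "left":
            return (t >= start_ms - 1e-9) & (t < end_ms - 1e-9)
        raise ValueError("closed must be 'both' or 'left'")

    # ---- IO: flat binary array + JSON sidecar --------------------------------

    def save(self, directory, name: str | None = None) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        name = name or self.anchor
        np.save(directory / f"{name}_epochs.npy", self.data)
        sidecar = {
            "anchor": self.anchor,
            "sampling_rate_hz": self.sampling_rate,
            "channels": list(self.channels),
            "window_ms": [float(self.times[0]),
                          float(self.times[-1] + 1000.0 / self.sampling_rate)],
            "n_trials": int(self.n_trials),
            "subjects": [int(s) for s in self.subjects],
            "trials": [int(t) for t in self.trials],
        }
        (directory / f"{name}_epochs.json").write_text(json.dumps(sidecar))
        return directory / f"{name}_epochs.npy"

    @classmethod
    def load(cls, directory, name: str) -> "EpochSet":
        directory = Path(directory)
        data = np.load(directory / f"{name}_epochs.npy")
        meta = json.loads((directory / f"{name}_epochs.json").read_text())
        times = epoch_time_axis(tuple(meta["window_ms"]), meta["sampling_rate_hz"])
        return cls(
            data=data,
            times=times,
            channels=tuple(meta["channels"]),
            anchor=meta["anchor"],
            sampling_rate=meta["sampling_rate_hz"],
            subjects=np.asarray(meta["subjects"], dtype=int),
            trials=np.asarray(meta["trials"], dtype=int),
        )
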