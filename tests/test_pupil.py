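"""Pupil IRF, preprocessing and deconvolution: exact inverse-problem checks."""

import numpy as np
import pandas as pd
import pytest

from evcontrol.pupil import (
    IrfParams,
    PupilSeries,
    deconvolve,
    downsample,
    erlang_irf,
    interpolate_blinks,
    irf_train,
    preprocess,
)

IRF = IrfParams()


class TestErlangIrf:
    def test_zero_at_origin_and_causal(self):
        assert erlang_irf(0.0, IRF) == 0.0
        assert erlang_irf(-0.5, IRF) == 0.0

    def test_peak_latency_on_millisecond_grid(self):
        t = np.arange(0, 5.0, 0.001)
        h = erlang_irf(t, IRF)
        assert abs(t[np.argmax(h)] - 1.30) < 1e-3
        assert h.max() == pytest.approx(1.0)

    def test_unimodal(self):
        assert erlang_irf(IRF.t_max / 2, IRF) < erlang_irf(IRF.t_max, IRF)
        assert erlang_irf(2 * IRF.t_max, IRF) < erlang_irf(IRF.t_max, IRF)
        t = np.arange(0.001, 6.0, 0.001)
        h = erlang_irf(t, IRF)
        peak = np.argmax(h)
        assert np.all(np.diff(h[:peak]) > 0)
        assert np.all(np.diff(h[peak:]) < 0)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            IrfParams(n=-1.0)
        with pytest.raises(ValueError):
            IrfParams(t_max=0.0)


def _series(diameter, rate=500.0, blink_mask=None):
    n = len(diameter)
    return PupilSeries(time=np.arange(n) / rate, diameter=np.asarray(diameter),
                       sampling_rate=rate, blink_mask=blink_mask)


class TestBlinkInterpolation:
    def test_no_blinks_identity(self):
        s = _series(np.sin(np.arange(1000) / 50))
        out = interpolate_blinks(s)
        assert np.array_equal(out.diameter, s.diameter)

    def test_linear_segment_reconstructed_exactly(self):
        x = np.linspace(0, 5, 2000)
        mask = np.zeros(2000, dtype=bool)
        mask[800:900] = True
        corrupted = x.copy()
        corrupted[mask] = -10.0
        out = interpolate_blinks(_series(corrupted, blink_mask=mask))
        assert np.allclose(out.diameter, x, atol=1e-9)

    def test_curved_segment_bounded_error(self):
        t = np.arange(3000) / 500.0
        x = erlang_irf(t, IRF)
        mask = np.zeros(3000, dtype=bool)
        mask[500:550] = True  # 100 ms blink on the rising flank
        corrupted = x.copy()
        corrupted[mask] = -10.0
        out = interpolate_blinks(_series(corrupted, blink_mask=mask))
        # linear-interpolation error over span L is bounded by max|f''| L^2 / 8;
        # the unit-peak IRF has |f''| <= n / t_max^2 near its peak and the
        # padded gap spans 0.5 s
        bound = IRF.n / IRF.t_max**2 * 0.5**2 / 8.0
        assert np.max(np.abs(out.diameter - x)) < bound

    def test_blink_at_edge_extends_nearest_value(self):
        x = np.ones(1000) * 4.0
        mask = np.zeros(1000, dtype=bool)
        mask[:50] = True
        corrupted = x.copy()
        corrupted[mask] = 0.0
        out = interpolate_blinks(_series(corrupted, blink_mask=mask))
        assert np.allclose(out.diameter, 4.0)


class TestPreprocess:
    def test_length_and_rate(self):
        s = _series(np.random.default_rng(0).normal(size=5000))  # 10 s @ 500 Hz
        out = preprocess(s)
        assert out.sampling_rate == 20.0
        assert len(out.diameter) == 200

    def test_zscore_moments(self):
        s = _series(np.random.default_rng(1).normal(3, 2, 5000))
        out = preprocess(s)
        assert abs(out.diameter.mean()) < 1e-9
        assert abs(out.diameter.std() - 1) < 1e-9

    def test_constant_trace_errors(self):
        with pytest.raises(ValueError):
            preprocess(_series(np.ones(5000)))

    def test_non_integer_decimation_errors(self):
        with pytest.raises(ValueError):
            downsample(_series(np.ones(100), rate=30.0), target_rate=20.0)


def _forward(events, n=20000, rate=500.0):
    """Noise-free forward simulation on the fine grid + block-mean decimation."""
    trace = np.zeros(n)
    for _, row in events.iterrows():
        trace += row.amplitude * irf_train([row.time_s], n, rate, IRF)
    series = PupilSeries(time=np.arange(n) / rate, diameter=trace,
                         sampling_rate=rate)
    return downsample(series)


class TestDeconvolve:
    def test_single_event_type_exact(self):
        events = pd.DataFrame({
            "time_s": [2.0, 9.0, 17.0], "regressor": "cue",
            "amplitude": [0.8, 0.8, 0.8],
        })
        fit = deconvolve(_forward(events), events, IRF)
        assert fit.coefficients["cue"] == pytest.approx(0.8, abs=1e-6)

    def test_two_overlapping_types_exact(self):
        events = pd.DataFrame({
            "time_s": [2.0, 2.5, 9.0, 9.5, 17.0, 17.5],
            "regressor": ["cue", "target"] * 3,
            "amplitude": [1.0, 0.4] * 3,
        })
        fit = deconvolve(_forward(events), events, IRF)
        assert fit.coefficients["cue"] == pytest.approx(1.0, abs=1e-6)
        assert fit.coefficients["target"] == pytest.approx(0.4, abs=1e-6)

    def test_linearity_of_coefficients(self):
        ev1 = pd.DataFrame({"time_s": [2.0, 10.0], "regressor": "a",
                            "amplitude": [1.0, 1.0]})
        ev2 = pd.DataFrame({"time_s": [4.0, 15.0], "regressor": "b",
                            "amplitude": [0.5, 0.5]})
        both = pd.concat([ev1, ev2], ignore_index=True)
        s1, s2 = _forward(ev1), _forward(ev2)
        summed = PupilSeries(time=s1.time, diameter=s1.diameter + s2.diameter,
                             sampling_rate=s1.sampling_rate)
        fit = deconvolve(summed, both, IRF)
        assert fit.coefficients["a"] == pytest.approx(1.0, abs=1e-6)
        assert fit.coefficients["b"] == pytest.approx(0.5, abs=1e-6)

    def test_scale_equivariance(self):
        events = pd.DataFrame({"time_s": [2.0, 11.0], "regressor": "cue",
                               "amplitude": [1.0, 1.0]})
        s = _forward(events)
        scaled = PupilSeries(time=s.time, diameter=3.0 * s.diameter,
                             sampling_rate=s.sampling_rate)
        fit = deconvolve(scaled, events, IRF)
        assert fit.coefficients["cue"] == pytest.approx(3.0, abs=1e-6)

    def test_singular_design_named(self):
        # two labels with identical event trains are perfectly collinear
        events = pd.DataFrame({"time_s": [2.0, 2.0, 9.0, 9.0],
                               "regressor": ["a", "b", "a", "b"],
                               "amplitude": 1.0})
        with pytest.raises(np.linalg.LinAlgError, match="a"):
            deconvolve(_forward(events.iloc[::2]), events, IRF)

    def test_event_beyond_trace_errors(self):
        events = pd.DataFrame({"time_s": [100.0], "regressor": "cue",
                               "amplitude": 1.0})
        with pytest.raises(ValueError):
            deconvolve(_forward(events.iloc[:0].assign()), events, IRF)
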