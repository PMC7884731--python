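"""Single-trial ERP quantification: exactness, thresholds, reliability."""

import numpy as np
import pytest

from evcontrol.epochs import EpochSet, epoch_time_axis
from evcontrol.erp import (
    baseline_correct,
    frn_peak_to_peak,
    mean_amplitude,
    reject_artifacts,
    split_half_reliability,
    zscore_within,
)

RATE = 512.0
CHANNELS = ("Fz", "FCz", "Cz", "Pz", "P3", "P4")


def make_epochs(data, window=(-200.0, 800.0), anchor="feedback"):
    data = np.asarray(data, dtype=float)
    times = epoch_time_axis(window, RATE)
    assert data.shape[2] == len(times)
    n = data.shape[0]
    return EpochSet(
        data=data, times=times, channels=CHANNELS[: data.shape[1]],
        anchor=anchor, sampling_rate=RATE,
        subjects=np.ones(n, dtype=int), trials=np.arange(1, n + 1),
    )


def blank(n_trials=1, n_channels=6, window=(-200.0, 800.0)):
    times = epoch_time_axis(window, RATE)
    return np.zeros((n_trials, n_channels, len(times))), times


class TestBaselineCorrect:
    def test_constant_epoch(self):
        data, _ = blank()
        data += 5.0
        corrected, baselines = baseline_correct(make_epochs(data))
        assert np.allclose(corrected.data, 0.0)
        assert np.allclose(baselines, 5.0)

    def test_zero_mean_baseline_is_identity(self):
        data, times = blank()
        post = times >= 0
        data[:, :, post] = 3.0
        corrected, baselines = baseline_correct(make_epochs(data))
        assert np.allclose(baselines, 0.0)
        assert np.allclose(corrected.data, data)

    def test_step_function(self):
        data, times = blank()
        data[:, :, times >= 0] = 4.0
        corrected, baselines = baseline_correct(make_epochs(data))
        assert np.allclose(baselines, 0.0)
        post_mean = corrected.data[:, :, times >= 0].mean()
        assert post_mean == pytest.approx(4.0)

    def test_missing_baseline_window_errors(self):
        data = np.zeros((1, 6, 100))
        times = np.arange(100) * (1000.0 / RATE)  # starts at 0: no pre-anchor
        ep = EpochSet(data=data, times=times, channels=CHANNELS,
                      anchor="cue", sampling_rate=RATE,
                      subjects=np.ones(1, int), trials=np.ones(1, int))
        with pytest.raises(ValueError):
            baseline_correct(ep)


class TestArtifactRejection:
    @pytest.mark.parametrize("amp,expected", [(149.0, False), (151.0, True)])
    def test_amplitude_threshold(self, amp, expected):
        data, times = blank()
        data[0, 2, np.searchsorted(times, 100)] = amp
        # keep the gradient below threshold by ramping up gently
        mask = reject_artifacts(make_epochs(data), gradient_limit=np.inf)
        assert bool(mask[0]) is expected

    @pytest.mark.parametrize("jump,expected", [(40.0, False), (60.0, True)])
    def test_gradient_threshold(self, jump, expected):
        data, times = blank()
        j = np.searchsorted(times, 200)
        data[0, 1, j:] = jump  # single step of `jump` uV between samples
        mask = reject_artifacts(make_epochs(data), amp_limit=np.inf)
        assert bool(mask[0]) is expected

    def test_all_zero_retained(self):
        data, _ = blank(n_trials=3)
        assert not reject_artifacts(make_epochs(data)).any()

    def test_invariant_to_channel_and_epoch_order(self):
        rng = np.random.default_rng(0)
        data = rng.normal(0, 60, size=(8, 6, 512))
        mask = reject_artifacts(make_epochs(data))
        perm_ch = rng.permutation(6)
        perm_tr = rng.permutation(8)
        shuffled = make_epochs(data[perm_tr][:, perm_ch, :])
        shuffled.channels = tuple(CHANNELS[i] for i in perm_ch)
        assert np.array_equal(reject_artifacts(shuffled), mask[perm_tr])


class TestMeanAmplitude:
    def test_constant_value(self):
        data, _ = blank(window=(-200.0, 1500.0))
        data += 3.0
        ep = make_epochs(data, window=(-200.0, 1500.0), anchor="cue")
        assert mean_amplitude(ep, (250, 550), ("Pz", "P3", "P4"))[0] == pytest.approx(3.0)

    def test_single_channel_roi(self):
        data, times = blank()
        data[0, 1, :] = 7.0
        ep = make_epochs(data)
        out = mean_amplitude(ep, (0, 100), ("FCz",))
        assert out[0] == pytest.approx(7.0)

    def test_unknown_channel(self):
        data, _ = blank()
        with pytest.raises(KeyError):
            mean_amplitude(make_epochs(data), (0, 100), ("Oz",))


class TestFrnPeakToPeak:
    def test_flat_epoch_zero(self):
        data, _ = blank()
        assert frn_peak_to_peak(make_epochs(data))[0] == 0.0

    def test_constructed_waveform(self):
        # positive peak +6 uV at 230 ms, trough -4 uV at 300 ms -> 10 uV
        data, times = blank()
        ch = CHANNELS.index("FCz")
        data[0, ch, np.argmin(np.abs(times - 230))] = 6.0
        data[0, ch, np.argmin(np.abs(times - 300))] = -4.0
        assert frn_peak_to_peak(make_epochs(data))[0] == pytest.approx(10.0)

    def test_trough_at_window_start_searches_preceding_100ms(self):
        data, times = blank()
        ch = CHANNELS.index("FCz")
        # first sample at or after 250 ms: the trough window's left edge
        j_trough = int(np.flatnonzero(times >= 250.0)[0])
        t_trough = times[j_trough]
        data[0, ch, j_trough] = -5.0
        in_pre = np.flatnonzero((times >= t_trough - 100) & (times < t_trough))
        data[0, ch, in_pre[10]] = 3.0  # inside the preceding 100 ms
        before_pre = np.flatnonzero(times < t_trough - 100)
        data[0, ch, before_pre[-1]] = 9.0  # just before the search window
        out = frn_peak_to_peak(make_epochs(data))[0]
        assert out == pytest.approx(8.0)  # 3 - (-5), not 9 - (-5)


class TestSplitHalf:
    def test_identical_halves_r1(self):
        rng = np.random.default_rng(1)
        subjects = np.repeat(np.arange(10), 40)
        trials = np.tile(np.arange(1, 41), 10)
        base = rng.normal(5, 2, 10)
        values = base[subjects]  # no trial noise: odd and even halves agree
        assert split_half_reliability(values, subjects, trials) == pytest.approx(1.0)

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(2)
        subjects = np.repeat(np.arange(44), 100)
        trials = np.tile(np.arange(1, 101), 44)
        values = rng.normal(0, 1, 4400)  # no subject-level signal
        assert abs(split_half_reliability(values, subjects, trials)) < 0.3

    def test_low_noise_amplitudes_reliable(self):
        # stable subject-level P3b differences across 600 trials -> r > 0.8
        rng = np.random.default_rng(3)
        subjects = np.repeat(np.arange(44), 600)
        trials = np.tile(np.arange(1, 601), 44)
        values = rng.normal(5, 1.5, 44)[subjects] + rng.normal(0, 2.0, 44 * 600)
        assert split_half_reliability(values, subjects, trials) > 0.8

    def test_incomplete_subject_excluded_with_warning(self):
        subjects = np.array([1, 1, 1, 1, 2, 2, 2, 2, 3])
        trials = np.array([1, 2, 3, 4, 1, 2, 3, 4, 1])  # subject 3: odd only
        values = np.array([1.0, 1.1, 0.9, 1.0, 2.0, 2.1, 1.9, 2.0, 5.0])
        with pytest.warns(UserWarning):
            r = split_half_reliability(values, subjects, trials)
        assert np.isfinite(r)


def test_zscore_within_unit_moments():
    rng = np.random.default_rng(4)
    subjects = np.repeat(np.arange(5), 100)
    z = zscore_within(rng.normal(3, 2, 500), subjects)
    for s in range(5):
        sel = z[subjects == s]
        assert abs(sel.mean()) < 1e-9
        assert abs(sel.std(ddof=1) - 1) < 1e-9
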