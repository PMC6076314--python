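import numpy as np
import pandas as pd
import pytest

from gazedecode import (GazeRecording, build_schedule, center_runs, downsample,
                        impute_blinks, lowpass_filter, preprocess_dataset,
                        preprocess_run, simulate_recording, slice_trials)
from gazedecode.preprocess import PreprocessingError


def _recording(values, mask):
    n = len(values)
    df = pd.DataFrame({
        "time_ms": np.arange(n, dtype=float),
        "xl": values, "yl": values, "xr": values, "yr": values,
        "pl": values, "pr": values,
        "blink_l": mask, "blink_r": mask,
    })
    return GazeRecording(run=0, samples=df, sampling_rate=1000.0)


class TestImputeBlinks:
    def test_no_flags_is_identity(self):
        rec = _recording([1.0, 2.0, 3.0, 4.0], [False] * 4)
        out = impute_blinks(rec)
        pd.testing.assert_frame_equal(out.samples, rec.samples)

    def test_flagged_sample_becomes_median_of_rest(self):
        rec = _recording([1.0, 2.0, np.nan, 4.0], [False, False, True, False])
        out = impute_blinks(rec)
        assert out.samples.xl.tolist() == [1.0, 2.0, 2.0, 4.0]
        # unflagged samples untouched
        assert out.samples.xl[3] == 4.0

    def test_all_flagged_raises(self):
        rec = _recording([np.nan] * 4, [True] * 4)
        with pytest.raises(PreprocessingError):
            impute_blinks(rec)


class TestLowpass:
    fs = 1000.0

    def _gain(self, freq, **kwargs):
        t = np.arange(int(4 * self.fs)) / self.fs
        x = np.sin(2 * np.pi * freq * t)
        y = lowpass_filter(x, fs=self.fs, **kwargs)
        core = slice(int(self.fs), int(3 * self.fs))  # avoid edges
        return np.abs(y[core]).max()

    @staticmethod
    def butterworth_gain(freq, cutoff=100.0, order=5, fs=1000.0):
        """Closed-form magnitude of the bilinear-designed Butterworth:
        |H| = (1 + (tan(pi f/fs)/tan(pi fc/fs))^(2 order))^(-1/2).
        Reduces to the analog (1 + (f/fc)^(2 order))^(-1/2) as fs -> inf.
        """
        ratio = np.tan(np.pi * freq / fs) / np.tan(np.pi * cutoff / fs)
        return (1.0 + ratio ** (2 * order)) ** -0.5

    def test_dc_passband_gain_is_one(self):
        x = np.full(2048, 3.7)
        assert lowpass_filter(x) == pytest.approx(x, abs=1e-9)

    def test_single_pass_gain_matches_closed_form_at_150hz(self):
        g = self._gain(150.0, zero_phase=False)
        assert g == pytest.approx(self.butterworth_gain(150.0), rel=0.02)

    def test_cutoff_gain_is_half_power(self):
        # prewarping pins the digital and analog responses together at fc
        g = self._gain(100.0, zero_phase=False)
        assert g == pytest.approx(2.0**-0.5, rel=0.02)

    def test_zero_phase_gain_is_squared(self):
        g = self._gain(150.0, zero_phase=True)
        assert g == pytest.approx(self.butterworth_gain(150.0) ** 2, rel=0.05)

    def test_passband_tone_preserved_within_one_percent(self):
        assert self._gain(10.0, zero_phase=False) == pytest.approx(1.0, rel=0.01)

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(PreprocessingError):
            lowpass_filter(np.zeros(100), cutoff_hz=500.0, fs=1000.0)


class TestDownsample:
    def test_sixteen_seconds_to_4096_samples(self):
        assert downsample(np.zeros(16000)).shape == (4096,)

    def test_constant_preserved(self):
        # polyphase FIR has unit DC gain to within its design ripple
        y = downsample(np.full(16000, 3.0))
        assert y == pytest.approx(np.full(4096, 3.0), abs=1e-3)

    def test_subnyquist_tone_keeps_its_frequency(self):
        t = np.arange(16000) / 1000.0
        x = np.sin(2 * np.pi * 10.0 * t)
        y = downsample(x)
        spec = np.abs(np.fft.rfft(y * np.hanning(len(y))))
        freqs = np.fft.rfftfreq(len(y), 1 / 256.0)
        assert freqs[spec.argmax()] == pytest.approx(10.0, abs=0.1)

    def test_upsampling_rejected(self):
        with pytest.raises(PreprocessingError):
            downsample(np.zeros(100), fs_in=256.0, fs_out=1000.0)


class TestSliceAndCenter:
    def test_one_run_yields_labelled_abutting_trials(self, small_schedule,
                                                     null_recordings):
        data, fs = preprocess_run(null_recordings[0])
        trials = slice_trials(data, small_schedule, run=0, fs=fs)
        assert len(trials) == 8
        assert all(t.data.shape == (6, 4096) for t in trials)
        labels = [t.orientation for t in trials]
        assert labels == list(small_schedule.run_labels(0))
        # first trial starts 16 s into the run
        start = int(16 * 256)
        assert np.array_equal(trials[0].data[0], data[0, start : start + 4096])

    def test_short_recording_raises(self, small_schedule):
        with pytest.raises(PreprocessingError):
            slice_trials(np.zeros((6, 1000)), small_schedule, run=0)

    def test_centering_zeroes_run_medians(self, null_trials):
        by_run = {}
        for t in null_trials:
            by_run.setdefault(t.run, []).append(t)
        for run_trials in by_run.values():
            stacked = np.concatenate([t.data for t in run_trials], axis=1)
            assert np.median(stacked, axis=1) == pytest.approx(np.zeros(6), abs=1e-12)

    def test_runs_centered_independently(self):
        from conftest import make_trial

        rng = np.random.default_rng(0)
        trials = [
            make_trial(rng.standard_normal((6, 64)) + 1.3, trial=0, run=0),
            make_trial(rng.standard_normal((6, 64)) + 1.3, trial=1, run=0),
            make_trial(rng.standard_normal((6, 64)) - 2.0, trial=2, run=1),
        ]
        centered = center_runs(trials)
        run0 = np.concatenate([t.data for t in centered if t.run == 0], axis=1)
        run1 = np.concatenate([t.data for t in centered if t.run == 1], axis=1)
        assert np.median(run0, axis=1) == pytest.approx(np.zeros(6), abs=1e-12)
        assert np.median(run1, axis=1) == pytest.approx(np.zeros(6), abs=1e-12)
        # shape preserved, offsets differ per run
        assert centered[0].data.shape == (6, 64)

    def test_centering_is_idempotent(self, null_trials):
        again = center_runs(null_trials)
        for a, b in zip(null_trials, again):
            assert a.data == pytest.approx(b.data, abs=1e-12)


def test_end_to_end_counts_and_labels(small_schedule, null_trials):
    assert len(null_trials) == small_schedule.n_trials
    labels = np.array([t.orientation for t in null_trials])
    for o in small_schedule.orientations:
        assert np.sum(labels == o) == small_schedule.n_runs
    assert all(t.data.shape == (6, 4096) for t in null_trials)
    assert not any(np.isnan(t.data).any() for t in null_trials)
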