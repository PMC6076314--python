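import numpy as np
import pytest

from conftest import make_trial
from gazedecode import (CHANCE_LEVEL, TrainConfig, cnn_decode, feature_matrix,
                        make_folds, rnn_decode, standardize, svm_raw,
                        svm_stats, svm_timepoint)
from gazedecode.decoding import DecodingError


def synthetic_trials(rng, n_runs=4, n_samples=64, signal=0.0,
                     signal_window=None, mode="offset"):
    """Noise trials with an optional class signal in channel 0.

    mode='offset': class k shifts the (x, y) position onto a circle of
    radius ``signal`` at angle k * 45 deg (an orientation-dependent gaze
    bias -- informative through means, occupancy and single timepoints).
    mode='window': each class elevates its own sample window
    (orthogonal class templates -- cleanly linearly separable even in
    the high-dimensional flattened representation).
    """
    orientations = [i * 22.5 for i in range(8)]
    w = n_samples // 8
    trials = []
    for run in range(n_runs):
        order = rng.permutation(8)
        for i in range(8):
            k = int(order[i])
            data = rng.standard_normal((6, n_samples)) * 0.5
            if signal:
                if mode == "window":
                    data[0, k * w : (k + 1) * w] += signal
                else:
                    sl = signal_window if signal_window is not None else slice(None)
                    theta = np.pi * k / 4.0
                    data[0, sl] += signal * np.cos(theta)
                    data[1, sl] += signal * np.sin(theta)
            trials.append(make_trial(data, trial=run * 8 + i, run=run,
                                     orientation=orientations[k]))
    return trials


class TestFolds:
    def test_default_design_fold_sizes(self):
        runs = np.repeat(np.arange(24), 8)
        folds = make_folds(runs)
        assert len(folds) == 24
        assert all(len(f.train_idx) == 184 and len(f.test_idx) == 8 for f in folds)

    def test_two_runs_two_folds(self):
        folds = make_folds([0, 0, 1, 1])
        assert len(folds) == 2

    def test_folds_partition_all_trials(self):
        runs = np.repeat(np.arange(5), 8)
        folds = make_folds(runs)
        seen = np.concatenate([f.test_idx for f in folds])
        assert sorted(seen) == list(range(40))
        for f in folds:
            assert not set(f.train_idx) & set(f.test_idx)

    def test_single_run_rejected(self):
        with pytest.raises(DecodingError):
            make_folds([0, 0, 0])


class TestStandardize:
    def test_train_columns_become_zero_mean_unit_sd(self, rng):
        tr, te = standardize(rng.standard_normal((50, 5)) * 3 + 2,
                             rng.standard_normal((10, 5)))
        assert tr.mean(axis=0) == pytest.approx(np.zeros(5), abs=1e-12)
        assert tr.std(axis=0) == pytest.approx(np.ones(5))

    def test_constant_column_guard(self):
        train = np.column_stack([np.full(10, 4.0), np.arange(10.0)])
        test = np.column_stack([np.full(3, 9.0), np.arange(3.0)])
        tr, te = standardize(train, test)
        assert np.all(tr[:, 0] == 0.0)
        assert te[:, 0] == pytest.approx(np.full(3, 5.0))  # (9 - 4) / 1

    def test_test_split_uses_train_statistics(self, rng):
        train = rng.standard_normal((40, 1))
        test = rng.standard_normal((40, 1)) + 10.0
        _, te = standardize(train, test)
        # had test been standardized with its own stats its mean would be ~0
        assert te.mean() == pytest.approx(
            (test.mean() - train.mean()) / train.std(), rel=1e-9
        )


class TestSvm:
    def test_separable_construction_decodes_perfectly(self, rng):
        trials = synthetic_trials(rng, signal=3.0, mode="window")
        res = svm_raw(trials)
        assert res.method == "svm_raw"
        assert res.mean_accuracy > 0.95
        assert res.mean_accuracy == pytest.approx(np.mean(res.fold_accuracies))

    def test_permuted_labels_fall_to_chance(self, rng):
        trials = synthetic_trials(rng, n_runs=6, signal=3.0, mode="window")
        y = np.array([t.orientation for t in trials])
        res = svm_raw(trials, labels=rng.permutation(y))
        assert abs(res.mean_accuracy - CHANCE_LEVEL) < 0.12

    def test_svm_stats_positive_and_null(self, rng):
        trials = synthetic_trials(rng, n_runs=6, signal=2.0)
        X = feature_matrix(trials)
        y = np.array([t.orientation for t in trials])
        runs = np.array([t.run for t in trials])
        res = svm_stats(X, y, runs=runs)
        assert res.mean_accuracy > 3 * CHANCE_LEVEL  # position bias is informative
        null = svm_stats(X, rng.permutation(y), runs=runs)
        assert abs(null.mean_accuracy - CHANCE_LEVEL) < 0.12

    def test_timepoint_accuracy_localizes_signal(self, rng):
        trials = synthetic_trials(rng, n_runs=6, n_samples=32, signal=4.0,
                                  signal_window=slice(0, 8))
        res = svm_timepoint(trials)
        acc = res.timepoint_accuracy
        assert len(acc) == 32
        assert acc[:8].mean() > 0.7
        assert abs(acc[16:].mean() - CHANCE_LEVEL) < 0.1
        assert acc[:8].mean() > acc[16:].mean() + 0.3

    def test_svm_deterministic_across_reruns(self, rng):
        trials = synthetic_trials(rng, n_runs=3)
        a = svm_raw(trials)
        b = svm_raw(trials)
        assert a.fold_accuracies == b.fold_accuracies


class TestNNDecoders:
    def test_cnn_learns_separable_signal(self, rng):
        trials = synthetic_trials(rng, n_runs=5, n_samples=64, signal=3.0,
                                  mode="window")
        cfg = TrainConfig(epochs=60, adam_alpha=0.003, batch_size=16, seed=0)
        res = cnn_decode(trials, config=cfg,
                         conv_specs=((4, 9), (8, 5), (16, 3)), hidden=16)
        assert res.mean_accuracy > 0.6
        assert len(res.train_loss) == 5  # one curve per fold
        # training loss decreases on separable data
        assert res.train_loss[0][-1] < res.train_loss[0][0]

    def test_rnn_integrates_drifting_signal(self, rng):
        trials = synthetic_trials(rng, n_runs=3, n_samples=32, signal=2.0)
        cfg = TrainConfig(epochs=40, adam_alpha=0.01, batch_size=16, seed=0)
        res = rnn_decode(trials, config=cfg, n_units=12)
        assert res.mean_accuracy > 0.5

    def test_nn_records_validation_curves(self, rng):
        trials = synthetic_trials(rng, n_runs=2, n_samples=48)
        cfg = TrainConfig(epochs=3, batch_size=8, seed=1)
        res = cnn_decode(trials, config=cfg,
                         conv_specs=((3, 7), (4, 5), (6, 3)), hidden=8)
        assert all(len(c) == 3 for c in res.train_loss)
        assert all(len(c) == 3 for c in res.val_loss)

    def test_config_validation(self):
        with pytest.raises(DecodingError):
            TrainConfig(epochs=0)
        with pytest.raises(DecodingError):
            TrainConfig(adam_beta1=1.5)
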