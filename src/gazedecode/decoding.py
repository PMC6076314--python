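"""The five decoding analyses under leave-one-run-out cross-validation.

Every analysis follows the same protocol: hold out one run, standardize
with the training split's mean/SD, train, score on the held-out run's
trials.  Methods: linear SVM on the raw flattened time series, on the
76 summary statistics, and per individual timepoint; plus a 1-D CNN and
an LSTM trained with Adam.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.svm import SVC

from .features import feature_matrix
from .microsaccades import DetectionParams
from .nnet import CNNClassifier, LSTMClassifier
from .preprocess import TrialTensor

CHANCE_LEVEL = 1.0 / 8.0


class DecodingError(ValueError):
    pass


@dataclass(frozen=True)
class FoldSplit:
    """One leave-one-run-out fold."""

    held_out_run: int
    train_idx: np.ndarray
    test_idx: np.ndarray


@dataclass(frozen=True)
class TrainConfig:
    """Neural-network training settings (Adam)."""

    epochs: int = 100
    adam_alpha: float = 0.001
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise DecodingError("epochs must be >= 1")
        if not (0 < self.adam_beta1 < 1 and 0 < self.adam_beta2 < 1):
            raise DecodingError("Adam betas must lie in (0, 1)")


@dataclass
class DecodingResult:
    """Per-fold and mean accuracy for one analysis method."""

    method: str
    fold_accuracies: list[float]
    mean_accuracy: float
    timepoint_accuracy: Optional[np.ndarray] = None   # svm_time only
    train_loss: Optional[list[list[float]]] = None    # cnn/rnn, per fold
    val_loss: Optional[list[list[float]]] = None
    config: dict = field(default_factory=dict)
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "fold_accuracies": list(map(float, self.fold_accuracies)),
            "mean_accuracy": float(self.mean_accuracy),
            "chance_level": CHANCE_LEVEL,
            "config": self.config,
            "seed": self.seed,
        }
        if self.timepoint_accuracy is not None:
            d["timepoint_accuracy"] = [float(v) for v in self.timepoint_accuracy]
        if self.train_loss is not None:
            d["train_loss"] = self.train_loss
        if self.val_loss is not None:
            d["val_loss"] = self.val_loss
        return d


def make_folds(runs: Sequence[int]) -> list[FoldSplit]:
    """Leave-one-run-out folds from per-trial run ids."""
    runs = np.asarray(runs)
    unique = np.unique(runs)
    if len(unique) < 2:
        raise DecodingError("leave-one-run-out needs at least 2 runs")
    folds = []
    for r in unique:
        test = np.nonzero(runs == r)[0]
        train = np.nonzero(runs != r)[0]
        folds.append(FoldSplit(held_out_run=int(r), train_idx=train, test_idx=test))
    return folds


def standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score both splits with the training split's mean and SD.

    Features with zero training SD are divided by 1 (they carry no
    information in train; the offset is still removed from test).
    """
    if train.shape[0] < 2:
        raise DecodingError("need >= 2 training rows to standardize")
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def _svm(seed=None):
    # one-vs-one linear SVM; C defaults to 1 per sklearn
    return SVC(kernel="linear", C=1.0, decision_function_shape="ovo")


def _cv_accuracy(X, y, folds, make_clf, collect=None):
    accs = []
    for k, fold in enumerate(folds):
        Xtr, Xte = standardize(X[fold.train_idx], X[fold.test_idx])
        ytr, yte = y[fold.train_idx], y[fold.test_idx]
        clf = make_clf(k)
        if collect is None:
            clf.fit(Xtr, ytr)
        else:
            clf.fit(Xtr, ytr, validation_data=(Xte, yte))
            collect(clf)
        accs.append(float(np.mean(clf.predict(Xte) == yte)))
    return accs


def _labels_runs(trials: Sequence[TrialTensor]):
    y = np.asarray([t.orientation for t in trials])
    runs = np.asarray([t.run for t in trials])
    return y, runs


def _encode(y) -> np.ndarray:
    """Orientation labels (degrees, float) to integer class codes."""
    return np.unique(np.asarray(y), return_inverse=True)[1]


def svm_raw(trials: Sequence[TrialTensor], folds=None,
            labels: Optional[np.ndarray] = None) -> DecodingResult:
    """Linear SVM on the flattened 6 x n_samples single-trial vector."""
    y, runs = _labels_runs(trials)
    if labels is not None:
        y = np.asarray(labels)
    folds = folds or make_folds(runs)
    X = np.stack([t.data.reshape(-1) for t in trials])
    accs = _cv_accuracy(X, _encode(y), folds, lambda k: _svm())
    return DecodingResult("svm_raw", accs, float(np.mean(accs)),
                          config={"n_features": X.shape[1]})


def svm_stats(X: np.ndarray, y: np.ndarray, folds=None,
              runs: Optional[np.ndarray] = None) -> DecodingResult:
    """Linear SVM on the 76-column summary-statistics matrix."""
    y = np.asarray(y)
    if folds is None:
        folds = make_folds(runs)
    X = np.asarray(X, dtype=float)
    accs = _cv_accuracy(X, _encode(y), folds, lambda k: _svm())
    return DecodingResult("svm_stats", accs, float(np.mean(accs)),
                          config={"n_features": X.shape[1]})


def svm_stats_from_trials(trials: Sequence[TrialTensor], folds=None,
                          detection: DetectionParams | None = None) -> DecodingResult:
    """Convenience: detect events, build the 76-feature matrix, decode."""
    y, runs = _labels_runs(trials)
    X = feature_matrix(trials, detection)
    return svm_stats(X, y, folds or make_folds(runs))


def svm_timepoint(trials: Sequence[TrialTensor], folds=None,
                  labels: Optional[np.ndarray] = None) -> DecodingResult:
    """One linear SVM per individual timepoint (6 features each).

    Returns per-timepoint accuracy (mean over folds) plus the per-fold
    accuracies averaged over timepoints.
    """
    y, runs = _labels_runs(trials)
    if labels is not None:
        y = np.asarray(labels)
    folds = folds or make_folds(runs)
    y = _encode(y)
    data = np.stack([t.data for t in trials])       # (n, 6, L)
    n, c, L = data.shape
    acc_t = np.zeros((len(folds), L))
    for k, fold in enumerate(folds):
        for t in range(L):
            Xtr, Xte = standardize(data[fold.train_idx, :, t], data[fold.test_idx, :, t])
            clf = _svm()
            clf.fit(Xtr, y[fold.train_idx])
            acc_t[k, t] = np.mean(clf.predict(Xte) == y[fold.test_idx])
    fold_accs = acc_t.mean(axis=1).tolist()
    return DecodingResult(
        "svm_time", fold_accs, float(np.mean(fold_accs)),
        timepoint_accuracy=acc_t.mean(axis=0), config={"n_timepoints": L},
    )


def _nn_decode(trials, folds, config, make_clf, method):
    y, runs = _labels_runs(trials)
    folds = folds or make_folds(runs)
    data = np.stack([t.data for t in trials])
    train_curves, val_curves = [], []

    def collect(clf):
        train_curves.append(list(clf.train_loss_curve_))
        val_curves.append(list(clf.val_loss_curve_))

    def cv_make(k):
        return make_clf(config, seed=(config.seed or 0) * 1000 + k)

    accs = []
    for k, fold in enumerate(folds):
        Xtr = data[fold.train_idx]
        Xte = data[fold.test_idx]
        mu = Xtr.mean(axis=0, keepdims=True)
        sd = Xtr.std(axis=0, keepdims=True)
        sd = np.where(sd == 0.0, 1.0, sd)
        clf = cv_make(k)
        clf.fit((Xtr - mu) / sd, y[fold.train_idx],
                validation_data=((Xte - mu) / sd, y[fold.test_idx]))
        collect(clf)
        accs.append(float(np.mean(clf.predict((Xte - mu) / sd) == y[fold.test_idx])))
    return DecodingResult(
        method, accs, float(np.mean(accs)),
        train_loss=train_curves, val_loss=val_curves,
        config={"epochs": config.epochs, "alpha": config.adam_alpha,
                "beta1": config.adam_beta1, "beta2": config.adam_beta2,
                "batch_size": config.batch_size},
        seed=config.seed,
    )


def cnn_decode(trials: Sequence[TrialTensor], folds=None,
               config: TrainConfig | None = None, **clf_kwargs) -> DecodingResult:
    """1-D CNN decoder (three conv stages, dense 84, softmax outputs)."""
    config = config or TrainConfig()

    def make(cfg, seed):
        return CNNClassifier(
            epochs=cfg.epochs, learning_rate=cfg.adam_alpha, beta1=cfg.adam_beta1,
            beta2=cfg.adam_beta2, batch_size=cfg.batch_size, random_state=seed,
            **clf_kwargs,
        )

    return _nn_decode(trials, folds, config, make, "cnn")


def rnn_decode(trials: Sequence[TrialTensor], folds=None,
               config: TrainConfig | None = None, **clf_kwargs) -> DecodingResult:
    """LSTM decoder (20 units by default, final hidden state -> softmax)."""
    config = config or TrainConfig()

    def make(cfg, seed):
        return LSTMClassifier(
            epochs=cfg.epochs, learning_rate=cfg.adam_alpha, beta1=cfg.adam_beta1,
            beta2=cfg.adam_beta2, batch_size=cfg.batch_size, random_state=seed,
            **clf_kwargs,
        )

    return _nn_decode(trials, folds, config, make, "rnn")
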