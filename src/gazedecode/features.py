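"""Per-trial summary statistics: the 76-dimensional feature vector.

Per eye: mean and SD of x, y and pupil (12 values over both eyes), a
16-bin eye-angle occupancy histogram (percent of trial time the eye
spent at each angle from fixation), and a 16-bin microsaccade-direction
histogram (event counts).  Total 2 * (3 + 3 + 16 + 16) = 76.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .microsaccades import DetectionParams, MicrosaccadeEvent, bin_direction, detect_in_trial
from .preprocess import TrialTensor

N_ANGLE_BINS = 16
N_FEATURES = 2 * (3 + 3 + N_ANGLE_BINS + N_ANGLE_BINS)  # 76


def feature_names(n_bins: int = N_ANGLE_BINS) -> list[str]:
    """Column names in the fixed concatenation order."""
    names = ["mu_xl", "mu_yl", "mu_pl", "mu_xr", "mu_yr", "mu_pr",
             "sd_xl", "sd_yl", "sd_pl", "sd_xr", "sd_yr", "sd_pr"]
    for prefix in ("theta_el", "theta_er", "theta_ml", "theta_mr"):
        names += [f"{prefix}_{i:02d}" for i in range(n_bins)]
    return names


def angle_occupancy(positions_xy: np.ndarray, n_bins: int = N_ANGLE_BINS) -> np.ndarray:
    """Percent of trial time spent at each angle from the fixation point.

    Angles are atan2(y, x) binned into half-open 360/n_bins-degree bins.
    Samples exactly at the origin have no defined angle and are dropped
    from the denominator; with centered continuous data this set has
    measure zero.  Returns zeros if every sample sits at the origin.
    """
    positions_xy = np.asarray(positions_xy, dtype=float)
    if positions_xy.size == 0 or positions_xy.shape[-1] == 0:
        raise ValueError("empty trial")
    x, y = positions_xy[0], positions_xy[1]
    nonzero = (x != 0.0) | (y != 0.0)
    hist = np.zeros(n_bins)
    total = int(nonzero.sum())
    if total == 0:
        return hist
    ang = np.degrees(np.arctan2(y[nonzero], x[nonzero])) % 360.0
    width = 360.0 / n_bins
    idx = np.minimum(np.floor(ang / width).astype(int), n_bins - 1)
    np.add.at(hist, idx, 1.0)
    return 100.0 * hist / total


def direction_histogram(events: Sequence[MicrosaccadeEvent],
                        n_bins: int = N_ANGLE_BINS,
                        normalize: bool = False) -> np.ndarray:
    """Microsaccade-direction histogram (raw counts by default)."""
    hist = np.zeros(n_bins)
    for e in events:
        hist[bin_direction(e.direction, n_bins)] += 1.0
    if normalize and hist.sum() > 0:
        hist = hist / hist.sum()
    return hist


def summarize_trial(trial: TrialTensor,
                    events: dict[str, Sequence[MicrosaccadeEvent]],
                    n_bins: int = N_ANGLE_BINS,
                    normalize_directions: bool = False) -> np.ndarray:
    """The 76-vector for one trial given its per-eye detected events.

    Concatenation order: [mu_xl mu_yl mu_pl, mu_xr mu_yr mu_pr,
    sd_xl sd_yl sd_pl, sd_xr sd_yr sd_pr, theta_el(16), theta_er(16),
    theta_ml(16), theta_mr(16)].  SDs use the population convention.
    """
    xl, yl, xr, yr, pl, pr = trial.data
    mus = [m.mean() for m in (xl, yl, pl, xr, yr, pr)]
    sds = [m.std() for m in (xl, yl, pl, xr, yr, pr)]
    occ_l = angle_occupancy(trial.data[[0, 1]], n_bins)
    occ_r = angle_occupancy(trial.data[[2, 3]], n_bins)
    dir_l = direction_histogram(events.get("left", ()), n_bins, normalize_directions)
    dir_r = direction_histogram(events.get("right", ()), n_bins, normalize_directions)
    return np.concatenate([mus, sds, occ_l, occ_r, dir_l, dir_r])


def feature_matrix(trials: Sequence[TrialTensor],
                   detection: DetectionParams | None = None,
                   n_bins: int = N_ANGLE_BINS) -> np.ndarray:
    """Detect microsaccades and stack the 76-vectors for all trials."""
    rows = []
    for t in trials:
        events = detect_in_trial(t, detection)
        rows.append(summarize_trial(t, events, n_bins))
    return np.asarray(rows)


class SummaryFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer mapping a list of trial tensors to the 76-column matrix.

    Stateless (``fit`` records only the feature names); composes with
    sklearn pipelines, where downstream standardization and
    classification see one row per trial.
    """

    def __init__(self, detection: DetectionParams | None = None,
                 n_bins: int = N_ANGLE_BINS):
        self.detection = detection
        self.n_bins = n_bins

    def fit(self, X: Sequence[TrialTensor], y=None):
        self.feature_names_out_ = feature_names(self.n_bins)
        return self

    def transform(self, X: Sequence[TrialTensor]) -> np.ndarray:
        return feature_matrix(X, self.detection, self.n_bins)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(feature_names(self.n_bins))
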