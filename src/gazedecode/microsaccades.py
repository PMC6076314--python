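"""Velocity-threshold microsaccade detection (Engbert-Kliegl style).

Positions are converted to velocities with a 5-point moving-average
derivative, a median-based noise scale sets per-axis thresholds, and a
microsaccade is a maximal run of samples whose velocity exceeds the
elliptic (combined-axis) threshold for longer than a minimum duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import TrialTensor


class DetectionError(ValueError):
    pass


@dataclass(frozen=True)
class DetectionParams:
    """Detector settings.

    ``velocity_window`` is the span, in sample intervals, of the
    moving-average derivative denominator (the classic value is 6, i.e.
    the 5-point stencil).  ``lam`` multiplies the median-based velocity
    SD to form the threshold.  Events shorter than ``min_duration_ms``
    are rejected; at 256 Hz the default 6 ms means at least 2 samples.
    ``binocular_required`` keeps only events with a temporally
    overlapping partner in the other eye.
    """

    velocity_window: int = 6
    lam: float = 6.0
    min_duration_ms: float = 6.0
    binocular_required: bool = False

    def __post_init__(self):
        if self.lam <= 0:
            raise DetectionError("lam must be > 0")
        if self.min_duration_ms <= 0:
            raise DetectionError("min_duration_ms must be > 0")


@dataclass
class MicrosaccadeEvent:
    """Detected saccadic event; [onset, offset) are 0-based sample indices."""

    eye: str                # 'left' or 'right'
    onset: int
    offset: int             # exclusive
    amplitude: float        # DVA, norm of onset->offset displacement
    direction: float        # degrees in [0, 360)
    peak_velocity: float    # DVA/s

    @property
    def duration_samples(self) -> int:
        return self.offset - self.onset


def compute_velocity(position_xy: np.ndarray, fs: float, window: int = 6) -> np.ndarray:
    """5-point moving-average derivative of a (2, n) position trace.

    v[n] = (x[n+2] + x[n+1] - x[n-1] - x[n-2]) / (window * dt); the two
    boundary samples at each end are set to 0.  Exact for linear signals.
    """
    position_xy = np.asarray(position_xy, dtype=float)
    n = position_xy.shape[-1]
    if n < 5:
        raise DetectionError("need at least 5 samples to compute velocity")
    v = np.zeros_like(position_xy)
    denom = window / fs
    v[..., 2:-2] = (
        position_xy[..., 4:]
        + position_xy[..., 3:-1]
        - position_xy[..., 1:-3]
        - position_xy[..., :-4]
    ) / denom
    return v


def estimate_thresholds(velocity_xy: np.ndarray, lam: float = 6.0) -> tuple[float, float]:
    """Per-axis detection thresholds eta = lam * sigma.

    sigma is the median-based scale sqrt(median(v^2) - median(v)^2),
    robust to the saccades themselves.
    """
    etas = []
    for axis in range(2):
        v = np.asarray(velocity_xy[axis], dtype=float)
        sigma2 = np.median(v**2) - np.median(v) ** 2
        if sigma2 <= 0:
            raise DetectionError("degenerate velocity: median-based scale is zero")
        etas.append(lam * float(np.sqrt(sigma2)))
    return etas[0], etas[1]


def _min_samples(min_duration_ms: float, fs: float) -> int:
    """Smallest sample count whose duration strictly exceeds the minimum."""
    return int(np.floor(min_duration_ms / 1000.0 * fs)) + 1


def detect_events(
    velocity_xy: np.ndarray,
    eta_x: float,
    eta_y: float,
    fs: float,
    min_duration_ms: float = 6.0,
    position_xy: np.ndarray | None = None,
    eye: str = "left",
) -> list[MicrosaccadeEvent]:
    """Maximal suprathreshold runs -> events with amplitude/direction/peak.

    A sample is suprathreshold when (vx/eta_x)^2 + (vy/eta_y)^2 > 1.
    Amplitude and direction come from the onset-to-offset displacement of
    ``position_xy`` when given, else from the integrated velocity.
    """
    vx, vy = np.asarray(velocity_xy[0]), np.asarray(velocity_xy[1])
    crit = (vx / eta_x) ** 2 + (vy / eta_y) ** 2 > 1.0
    n_min = _min_samples(min_duration_ms, fs)
    events: list[MicrosaccadeEvent] = []
    padded = np.concatenate(([False], crit, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    speed = np.hypot(vx, vy)
    for on, off in zip(starts, ends):
        if off - on < n_min:
            continue
        if position_xy is not None:
            dx = position_xy[0][off - 1] - position_xy[0][on]
            dy = position_xy[1][off - 1] - position_xy[1][on]
        else:
            dx = float(np.sum(vx[on:off])) / fs
            dy = float(np.sum(vy[on:off])) / fs
        events.append(
            MicrosaccadeEvent(
                eye=eye,
                onset=int(on),
                offset=int(off),
                amplitude=float(np.hypot(dx, dy)),
                direction=float(np.degrees(np.arctan2(dy, dx)) % 360.0),
                peak_velocity=float(speed[on:off].max()),
            )
        )
    return events


def bin_direction(angle_deg: float, n_bins: int = 16) -> int:
    """Half-open angular bin index: floor((angle mod 360) / (360/n_bins))."""
    width = 360.0 / n_bins
    idx = int(np.floor((angle_deg % 360.0) / width))
    return min(idx, n_bins - 1)


def _binocular_filter(events_l, events_r):
    """Keep events with a temporally overlapping partner in the other eye."""
    def overlaps(e, others):
        return any(e.onset < o.offset and o.onset < e.offset for o in others)

    return (
        [e for e in events_l if overlaps(e, events_r)],
        [e for e in events_r if overlaps(e, events_l)],
    )


def detect_in_trial(trial: TrialTensor, params: DetectionParams | None = None
                    ) -> dict[str, list[MicrosaccadeEvent]]:
    """Detect microsaccades per eye within one preprocessed trial.

    Thresholds are estimated from the trial's own velocity distribution,
    independently per eye.
    """
    params = params or DetectionParams()
    fs = trial.sampling_rate
    out: dict[str, list[MicrosaccadeEvent]] = {}
    for eye, (ix, iy) in (("left", (0, 1)), ("right", (2, 3))):
        pos = trial.data[[ix, iy]]
        vel = compute_velocity(pos, fs, window=params.velocity_window)
        eta_x, eta_y = estimate_thresholds(vel, lam=params.lam)
        out[eye] = detect_events(
            vel, eta_x, eta_y, fs,
            min_duration_ms=params.min_duration_ms,
            position_xy=pos, eye=eye,
        )
    if params.binocular_required:
        out["left"], out["right"] = _binocular_filter(out["left"], out["right"])
    return out


def detect_in_run(run_data: np.ndarray, fs: float,
                  params: DetectionParams | None = None
                  ) -> dict[str, list[MicrosaccadeEvent]]:
    """Detect microsaccades per eye over a continuous preprocessed run.

    ``run_data`` is the (6, n) channel array from ``preprocess_run``.
    Used mainly to evaluate detector recovery against simulated ground
    truth, where events during fixation blocks also count.
    """
    params = params or DetectionParams()
    out: dict[str, list[MicrosaccadeEvent]] = {}
    for eye, (ix, iy) in (("left", (0, 1)), ("right", (2, 3))):
        pos = run_data[[ix, iy]]
        vel = compute_velocity(pos, fs, window=params.velocity_window)
        eta_x, eta_y = estimate_thresholds(vel, lam=params.lam)
        out[eye] = detect_events(
            vel, eta_x, eta_y, fs,
            min_duration_ms=params.min_duration_ms,
            position_xy=pos, eye=eye,
        )
    if params.binocular_required:
        out["left"], out["right"] = _binocular_filter(out["left"], out["right"])
    return out


def events_to_table(events_by_trial) -> "pd.DataFrame":
    """Flatten {trial_id: {eye: [events]}} into a tidy table.

    Columns: run, trial, eye, onset_sample, offset_sample, amplitude_dva,
    direction_deg, peak_vel (half-open sample coordinates).
    """
    import pandas as pd

    rows = []
    for (run, trial), by_eye in events_by_trial.items():
        for eye, evs in by_eye.items():
            for e in evs:
                rows.append(
                    dict(run=run, trial=trial, eye=eye, onset_sample=e.onset,
                         offset_sample=e.offset, amplitude_dva=e.amplitude,
                         direction_deg=e.direction, peak_vel=e.peak_velocity)
                )
    return pd.DataFrame(
        rows,
        columns=["run", "trial", "eye", "onset_sample", "offset_sample",
                 "amplitude_dva", "direction_deg", "peak_vel"],
    )
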