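"""Experiment schedule: sessions, runs and randomized trial orders.

The design mirrors a classic passive-viewing orientation experiment:
each run starts and ends with a fixation block, and in between presents
every grating orientation exactly once, in a per-run random order, with
the grating flickering on/off at a fixed rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The eight canonical grating orientations, degrees, 0 to 157.5 in 22.5 steps.
DEFAULT_ORIENTATIONS: tuple[float, ...] = tuple(i * 22.5 for i in range(8))


class ScheduleError(ValueError):
    """Raised for invalid schedule parameters (e.g. duplicate orientations)."""


@dataclass(frozen=True)
class ExperimentSchedule:
    """Complete trial plan for one simulated participant.

    Attributes
    ----------
    sessions, runs_per_session : int
        Experiment layout; total runs = ``sessions * runs_per_session``.
    orientations : tuple of float
        Distinct grating orientations in degrees, each in [0, 180).
    trial_duration, fixation_duration : float
        Seconds. A run is ``2 * fixation_duration + n_orientations *
        trial_duration`` seconds long; trials abut with no gap.
    flicker_rate : float
        Hz; stimulus is on for the first half of each flicker cycle.
    trial_orders : tuple of tuple of int
        One permutation of orientation indices per run.
    seed : int
        Seed the orders were drawn with (provenance only).
    """

    sessions: int = 2
    runs_per_session: int = 12
    orientations: tuple[float, ...] = DEFAULT_ORIENTATIONS
    trial_duration: float = 16.0
    fixation_duration: float = 16.0
    flicker_rate: float = 2.0
    trial_orders: tuple[tuple[int, ...], ...] = field(default=())
    seed: int = 0

    @property
    def n_runs(self) -> int:
        return self.sessions * self.runs_per_session

    @property
    def n_orientations(self) -> int:
        return len(self.orientations)

    @property
    def trials_per_run(self) -> int:
        return self.n_orientations

    @property
    def n_trials(self) -> int:
        return self.n_runs * self.trials_per_run

    @property
    def run_duration(self) -> float:
        """Run length in seconds: two fixation blocks plus all trials."""
        return 2.0 * self.fixation_duration + self.trial_duration * self.n_orientations

    def trial_onsets(self) -> np.ndarray:
        """Within-run onset times (s) of each trial, first at fixation_duration."""
        return self.fixation_duration + np.arange(self.trials_per_run) * self.trial_duration

    def run_labels(self, run: int) -> np.ndarray:
        """Orientation (degrees) of each trial of ``run``, in presentation order."""
        order = self.trial_orders[run]
        return np.asarray([self.orientations[i] for i in order], dtype=float)

    def all_labels(self) -> np.ndarray:
        """Orientation labels for every trial, run-major order."""
        return np.concatenate([self.run_labels(r) for r in range(self.n_runs)])

    def to_dict(self) -> dict:
        return {
            "sessions": self.sessions,
            "runs_per_session": self.runs_per_session,
            "orientations": list(self.orientations),
            "trial_duration": self.trial_duration,
            "fixation_duration": self.fixation_duration,
            "flicker_rate": self.flicker_rate,
            "trial_orders": [list(o) for o in self.trial_orders],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentSchedule":
        d = dict(d)
        d["orientations"] = tuple(d["orientations"])
        d["trial_orders"] = tuple(tuple(o) for o in d["trial_orders"])
        return cls(**d)


def build_schedule(
    sessions: int = 2,
    runs_per_session: int = 12,
    orientations=DEFAULT_ORIENTATIONS,
    trial_duration: float = 16.0,
    fixation_duration: float = 16.0,
    flicker_rate: float = 2.0,
    seed: int = 0,
) -> ExperimentSchedule:
    """Draw per-run trial orders and return a validated schedule.

    Each run presents every orientation exactly once; orders are
    independent uniform permutations under ``seed``.
    """
    if sessions < 1 or runs_per_session < 1:
        raise ScheduleError("sessions and runs_per_session must be >= 1")
    orientations = tuple(float(o) for o in orientations)
    if len(set(orientations)) != len(orientations):
        raise ScheduleError("orientations must be distinct")
    if any(not (0.0 <= o < 180.0) for o in orientations):
        raise ScheduleError("orientations must lie in [0, 180)")
    if trial_duration <= 0 or fixation_duration < 0 or flicker_rate <= 0:
        raise ScheduleError("durations must be positive")

    rng = np.random.default_rng(seed)
    n_runs = sessions * runs_per_session
    orders = tuple(
        tuple(int(i) for i in rng.permutation(len(orientations))) for _ in range(n_runs)
    )
    return ExperimentSchedule(
        sessions=sessions,
        runs_per_session=runs_per_session,
        orientations=orientations,
        trial_duration=trial_duration,
        fixation_duration=fixation_duration,
        flicker_rate=flicker_rate,
        trial_orders=orders,
        seed=seed,
    )
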