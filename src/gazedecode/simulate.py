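"""Synthetic binocular gaze and pupil recordings during attempted fixation.

The generator emulates the three classes of fixational eye movements —
microsaccades, drift and tremor — plus pupil dilation and blinks, at
1000 Hz, organized into runs and trials per an :class:`ExperimentSchedule`.

Model summary
-------------
* **Microsaccades** arrive as a Poisson process (events/s over the whole
  run).  Each event is a smooth ballistic displacement with a
  raised-cosine velocity profile, duration drawn uniformly from a
  configurable range, amplitude uniform within its range, and a
  direction drawn from an axial von Mises mixture peaked at 0°/180°
  (horizontal bias).  An event lands in both eyes with probability
  ``binocular_correlation`` (shared direction), else in one random eye.
* **Drift** is a smooth random wander: an Ornstein–Uhlenbeck velocity
  process integrated to position, calibrated in closed form so the mean
  absolute excursion over one second equals ``drift_speed``.  Drift is
  independent between eyes and axes.
* **Tremor** is band-limited Gaussian noise (default 30–100 Hz) of small
  RMS amplitude added to position, independent between eyes.
* **Pupil** is a constant baseline plus slow (< 2 Hz) Gaussian noise,
  orientation-independent.
* **Blinks** arrive as a Poisson process; each masks a fixed window in
  both eyes.  Masked samples are flagged and set to NaN — they are
  present but unusable until imputed.
* A weak position leak (time constant ``fixation_leak_tau``) pulls the
  slow gaze component back toward the fixation point so long runs stay
  bounded, standing in for the corrective role of fixational eye
  movements.

An optional :class:`ConfoundSpec` injects an orientation-dependent
microsaccade-direction coupling as a positive control: during stimulus-on
flicker phases of a trial, an event's direction is redrawn, with
probability ``coupling_strength``, from a concentrated axial distribution
around an orientation-locked axis (default orthogonal to the grating).
``coupling_strength=0`` reproduces the baseline generator bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .schedule import ExperimentSchedule

SAMPLE_COLUMNS = ["time_ms", "xl", "yl", "xr", "yr", "pl", "pr", "blink_l", "blink_r"]


class ParameterError(ValueError):
    """Raised when generator or confound parameters are out of range."""


@dataclass(frozen=True)
class GeneratorParams:
    """Statistical parameters of the gaze generator.

    Units: positions and amplitudes in degrees of visual angle (DVA),
    rates in events per second (blinks per minute), durations in ms,
    pupil in arbitrary units.
    """

    microsaccade_rate: float = 1.5          # events/s, Poisson
    microsaccade_amplitude_min: float = 0.1  # DVA
    microsaccade_amplitude_max: float = 0.5  # DVA (30 arcmin)
    microsaccade_duration_range: tuple[float, float] = (10.0, 30.0)  # ms
    binocular_correlation: float = 0.9      # P(event lands in both eyes)
    horizontal_bias: float = 1.0            # von Mises concentration at 0/180
    drift_speed: float = 0.5                # DVA/s mean absolute 1-s excursion
    drift_tau: float = 0.2                  # s, drift velocity correlation time
    tremor_band: tuple[float, float] = (30.0, 100.0)  # Hz
    tremor_amplitude: float = 0.002         # DVA RMS
    blink_rate: float = 8.0                 # events/min
    blink_duration: float = 150.0           # ms
    pupil_baseline: float = 1000.0          # a.u.
    pupil_noise: float = 10.0               # a.u. RMS, < 2 Hz
    fixation_leak_tau: Optional[float] = 5.0  # s; None disables the leak
    sampling_rate: float = 1000.0           # Hz
    seed: int = 0

    def __post_init__(self):
        nonneg = {
            "microsaccade_rate": self.microsaccade_rate,
            "microsaccade_amplitude_min": self.microsaccade_amplitude_min,
            "microsaccade_amplitude_max": self.microsaccade_amplitude_max,
            "drift_speed": self.drift_speed,
            "tremor_amplitude": self.tremor_amplitude,
            "blink_rate": self.blink_rate,
            "blink_duration": self.blink_duration,
            "pupil_noise": self.pupil_noise,
            "horizontal_bias": self.horizontal_bias,
        }
        for name, v in nonneg.items():
            if v < 0:
                raise ParameterError(f"{name} must be nonnegative, got {v}")
        if not (0.0 <= self.binocular_correlation <= 1.0):
            raise ParameterError("binocular_correlation must lie in [0, 1]")
        lo, hi = self.tremor_band
        if not (0.0 < lo < hi < self.sampling_rate / 2):
            raise ParameterError(
                f"tremor_band must lie within (0, {self.sampling_rate / 2}) Hz"
            )
        if self.microsaccade_amplitude_min > self.microsaccade_amplitude_max:
            raise ParameterError("amplitude range inverted")


@dataclass(frozen=True)
class ConfoundSpec:
    """Orientation-coupled microsaccade-direction confound (positive control).

    ``coupling_strength`` mixes the baseline direction distribution with an
    orientation-locked axial von Mises of concentration ``kappa`` centered,
    under the default ``direction_rule='orthogonal'``, on the axis
    perpendicular to the presented grating.  Coupling applies only to
    events that fall in a stimulus-on flicker phase of a trial.
    ``rate_modulation`` optionally scales the event rate per orientation.
    """

    coupling_strength: float = 0.0
    direction_rule: Literal["orthogonal", "parallel"] = "orthogonal"
    kappa: float = 20.0
    rate_modulation: Optional[dict[float, float]] = None

    def __post_init__(self):
        if not (0.0 <= self.coupling_strength <= 1.0):
            raise ParameterError("coupling_strength must lie in [0, 1]")
        if self.kappa < 0:
            raise ParameterError("kappa must be nonnegative")

    def preferred_axis(self, orientation: float) -> float:
        """Preferred microsaccade axis (degrees, [0, 180)) for a grating."""
        if self.direction_rule == "orthogonal":
            return (orientation + 90.0) % 180.0
        return orientation % 180.0


@dataclass
class SimulatedSaccade:
    """Ground-truth microsaccade injected by the generator."""

    onset_ms: float
    duration_ms: float
    amplitude: float
    direction: float            # degrees, [0, 360)
    eyes: tuple[str, ...]       # ('left',), ('right',) or ('left', 'right')
    trial: Optional[int]        # within-run trial index, None during fixation
    confounded: bool = False


@dataclass
class GazeRecording:
    """One run of continuous binocular gaze/pupil samples.

    ``samples`` holds columns ``time_ms, xl, yl, xr, yr, pl, pr,
    blink_l, blink_r``; blink-masked position/pupil samples are NaN and
    flagged in the mask columns.  ``ground_truth`` lists the injected
    microsaccades (simulation only; empty for real data).
    """

    run: int
    samples: pd.DataFrame
    sampling_rate: float = 1000.0
    ground_truth: list[SimulatedSaccade] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def _ou_velocity(rng, n, dt, tau, sigma):
    """Stationary Ornstein-Uhlenbeck velocity series, RMS ``sigma``."""
    if sigma == 0.0:
        return np.zeros(n)
    b = math.exp(-dt / tau)
    noise = rng.standard_normal(n) * (sigma * math.sqrt(1.0 - b * b))
    noise[0] = rng.standard_normal() * sigma  # stationary start
    return signal.lfilter([1.0], [1.0, -b], noise)


def _drift_sigma_v(drift_speed: float, tau: float) -> float:
    """OU velocity RMS so that E|displacement over 1 s| = drift_speed.

    For an OU velocity with correlation time tau and variance sigma^2,
    Var(D(T)) = 2 sigma^2 tau [T - tau (1 - exp(-T/tau))]; the mean
    absolute value of a centered Gaussian is sqrt(2/pi) times its SD.
    """
    T = 1.0
    var_unit = 2.0 * tau * (T - tau * (1.0 - math.exp(-T / tau)))
    return drift_speed / (math.sqrt(2.0 / math.pi) * math.sqrt(var_unit))


def _leaky_integrate(v, dt, leak_tau):
    """x[n] = a*x[n-1] + dt*v[n], a = exp(-dt/leak_tau) (1 if no leak)."""
    a = 1.0 if leak_tau is None else math.exp(-dt / leak_tau)
    return signal.lfilter([dt], [1.0, -a], v)


def _band_noise(rng, n, fs, band, rms, order=4, btype="bandpass"):
    """Gaussian noise filtered into ``band`` and scaled to ``rms``."""
    white = rng.standard_normal(n)
    if rms == 0.0:
        return np.zeros(n)
    sos = signal.butter(order, band, btype=btype, fs=fs, output="sos")
    y = signal.sosfilt(sos, white)
    sd = y.std()
    if sd == 0.0:
        return np.zeros(n)
    return y * (rms / sd)


def _axial_von_mises(rng, center_deg: float, kappa: float) -> float:
    """Angle (deg, [0,360)) from a von Mises at center, flipped 180 w.p. 1/2."""
    ang = math.degrees(rng.vonmises(math.radians(center_deg), kappa))
    if rng.random() < 0.5:
        ang += 180.0
    return ang % 360.0


def _trial_and_phase(t_ms, schedule: ExperimentSchedule):
    """(trial index or None, stimulus-on flag) for a within-run time."""
    t = t_ms / 1000.0
    fix = schedule.fixation_duration
    dur = schedule.trial_duration
    n = schedule.trials_per_run
    if t < fix or t >= fix + n * dur:
        return None, False
    idx = int((t - fix) // dur)
    within = (t - fix) - idx * dur
    cycle = 1.0 / schedule.flicker_rate
    return idx, (within % cycle) < cycle / 2.0


def simulate_recording(
    schedule: ExperimentSchedule,
    params: Optional[GeneratorParams] = None,
    confound: Optional[ConfoundSpec] = None,
    seed: Optional[int] = None,
) -> list[GazeRecording]:
    """Simulate one participant: one :class:`GazeRecording` per run.

    Identical (schedule, params, confound, seed) yields bit-identical
    output.  With ``confound=None`` or ``coupling_strength=0`` no channel
    depends on the orientation labels, so labels are exchangeable by
    construction (the null condition).
    """
    params = params or GeneratorParams()
    if seed is None:
        seed = params.seed
    root = np.random.SeedSequence(seed)
    children = root.spawn(schedule.n_runs)
    return [
        _simulate_run(schedule, params, confound, run, np.random.default_rng(children[run]))
        for run in range(schedule.n_runs)
    ]


def _simulate_run(schedule, params, confound, run, rng) -> GazeRecording:
    fs = params.sampling_rate
    dt = 1.0 / fs
    n = int(round(schedule.run_duration * fs))
    duration_s = n * dt
    labels = schedule.run_labels(run)

    # Drift: independent OU-velocity walks per eye and axis.
    sigma_v = _drift_sigma_v(params.drift_speed, params.drift_tau)
    vel = {
        eye: np.stack(
            [_ou_velocity(rng, n, dt, params.drift_tau, sigma_v) for _ in range(2)]
        )
        for eye in ("left", "right")
    }

    # Microsaccades: Poisson master process, optionally thinned per orientation.
    events: list[SimulatedSaccade] = []
    base_rate = params.microsaccade_rate
    if base_rate > 0:
        mods = confound.rate_modulation if confound is not None else None
        max_mod = max(mods.values(), default=1.0) if mods else 1.0
        max_mod = max(max_mod, 1.0)
        n_events = rng.poisson(base_rate * max_mod * duration_s)
        onsets = np.sort(rng.uniform(0.0, duration_s * 1000.0, size=n_events))
        dlo, dhi = params.microsaccade_duration_range
        for onset_ms in onsets:
            trial, stim_on = _trial_and_phase(onset_ms, schedule)
            if mods:
                mod = mods.get(labels[trial], 1.0) if trial is not None else 1.0
                if rng.random() >= mod / max_mod:
                    continue
            dur_ms = rng.uniform(dlo, dhi)
            amp = rng.uniform(
                params.microsaccade_amplitude_min, params.microsaccade_amplitude_max
            )
            direction = _axial_von_mises(rng, 0.0, params.horizontal_bias)
            if rng.random() < params.binocular_correlation:
                eyes = ("left", "right")
            else:
                eyes = ("left",) if rng.random() < 0.5 else ("right",)
            confounded = False
            if (
                confound is not None
                and confound.coupling_strength > 0
                and trial is not None
                and stim_on
            ):
                if rng.random() < confound.coupling_strength:
                    axis = confound.preferred_axis(labels[trial])
                    direction = _axial_von_mises(rng, axis, confound.kappa)
                    confounded = True
            _inject_saccade(vel, eyes, onset_ms, dur_ms, amp, direction, fs, n)
            events.append(
                SimulatedSaccade(
                    onset_ms=float(onset_ms),
                    duration_ms=float(dur_ms),
                    amplitude=float(amp),
                    direction=float(direction),
                    eyes=eyes,
                    trial=trial,
                    confounded=confounded,
                )
            )

    # Integrate velocities to position (with fixation leak), add tremor.
    pos = {}
    for eye in ("left", "right"):
        x = _leaky_integrate(vel[eye][0], dt, params.fixation_leak_tau)
        y = _leaky_integrate(vel[eye][1], dt, params.fixation_leak_tau)
        x = x + _band_noise(rng, n, fs, params.tremor_band, params.tremor_amplitude)
        y = y + _band_noise(rng, n, fs, params.tremor_band, params.tremor_amplitude)
        pos[eye] = (x, y)

    # Pupil: baseline plus slow noise.
    pupil = {
        eye: params.pupil_baseline
        + _band_noise(rng, n, fs, 2.0, params.pupil_noise, order=2, btype="lowpass")
        for eye in ("left", "right")
    }

    # Blinks: binocular, fixed duration, masked samples become NaN.
    mask = np.zeros(n, dtype=bool)
    if params.blink_rate > 0 and params.blink_duration > 0:
        n_blinks = rng.poisson(params.blink_rate / 60.0 * duration_s)
        starts = rng.uniform(0.0, duration_s * 1000.0, size=n_blinks)
        w = int(round(params.blink_duration * fs / 1000.0))
        for s_ms in starts:
            i0 = int(round(s_ms * fs / 1000.0))
            mask[i0 : min(i0 + w, n)] = True

    xl, yl = pos["left"]
    xr, yr = pos["right"]
    pl, pr = pupil["left"], pupil["right"]
    for arr in (xl, yl, xr, yr, pl, pr):
        arr[mask] = np.nan

    samples = pd.DataFrame(
        {
            "time_ms": np.arange(n) * (1000.0 / fs),
            "xl": xl,
            "yl": yl,
            "xr": xr,
            "yr": yr,
            "pl": pl,
            "pr": pr,
            "blink_l": mask,
            "blink_r": mask.copy(),
        }
    )
    return GazeRecording(run=run, samples=samples, sampling_rate=fs, ground_truth=events)


def _inject_saccade(vel, eyes, onset_ms, dur_ms, amplitude, direction, fs, n):
    """Add a raised-cosine velocity pulse to the chosen eyes' velocity traces.

    The pulse integrates exactly to ``amplitude`` along ``direction``.
    """
    i0 = int(round(onset_ms * fs / 1000.0))
    d = max(int(round(dur_ms * fs / 1000.0)), 2)
    i1 = min(i0 + d, n)
    if i0 >= n:
        return
    k = np.arange(i1 - i0)
    # midpoint sampling makes the discrete integral exact
    profile = (amplitude / (d / fs)) * (1.0 - np.cos(2.0 * np.pi * (k + 0.5) / d))
    th = math.radians(direction)
    for eye in eyes:
        vel[eye][0][i0:i1] += profile * math.cos(th)
        vel[eye][1][i0:i1] += profile * math.sin(th)
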