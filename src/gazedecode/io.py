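"""File interfaces: gaze CSV dialect, sidecar JSON, config round-trip.

One CSV per run with header ``time_ms,xl,yl,xr,yr,pl,pr,blink_l,blink_r``;
the schedule and injected ground-truth events travel in sidecar JSON so
an analysis can be re-run from files alone.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .decoding import TrainConfig
from .microsaccades import DetectionParams
from .schedule import ExperimentSchedule
from .simulate import ConfoundSpec, GazeRecording, GeneratorParams, SimulatedSaccade

RESULTS_SCHEMA_VERSION = 1


class ConfigError(ValueError):
    pass


def write_recording_csv(recording: GazeRecording, path) -> None:
    df = recording.samples.copy()
    df["blink_l"] = df["blink_l"].astype(int)
    df["blink_r"] = df["blink_r"].astype(int)
    df.to_csv(path, index=False, float_format="%.6f")


def read_recording_csv(path, run: int, sampling_rate: float = 1000.0) -> GazeRecording:
    df = pd.read_csv(path)
    df["blink_l"] = df["blink_l"].astype(bool)
    df["blink_r"] = df["blink_r"].astype(bool)
    return GazeRecording(run=run, samples=df, sampling_rate=sampling_rate)


def write_ground_truth(recordings, schedule: ExperimentSchedule, path) -> None:
    payload = {
        "schedule": schedule.to_dict(),
        "events": {
            str(rec.run): [dataclasses.asdict(e) for e in rec.ground_truth]
            for rec in recordings
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path) -> tuple[ExperimentSchedule, dict[int, list[SimulatedSaccade]]]:
    payload = json.loads(Path(path).read_text())
    schedule = ExperimentSchedule.from_dict(payload["schedule"])
    events = {
        int(run): [SimulatedSaccade(**{**e, "eyes": tuple(e["eyes"])}) for e in evs]
        for run, evs in payload["events"].items()
    }
    return schedule, events


def write_results(results: dict, path) -> None:
    out = {"schema_version": RESULTS_SCHEMA_VERSION}
    out.update(results)
    Path(path).write_text(json.dumps(out, indent=1))


def read_results(path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# pipeline configuration

_DEFAULT_METHODS = ["svm_stats"]


@dataclasses.dataclass
class PipelineConfig:
    """Everything needed to reproduce one simulated participant's analysis."""

    seed: int = 0
    output_dir: str = "."
    schedule: ExperimentSchedule = None
    generator: GeneratorParams = None
    confound: Optional[ConfoundSpec] = None
    detection: DetectionParams = None
    train: TrainConfig = None
    methods: list[str] = None
    n_permutations: int = 1000
    alpha: float = 0.05

    def __post_init__(self):
        from .schedule import build_schedule

        if self.schedule is None:
            self.schedule = build_schedule(seed=self.seed)
        self.generator = self.generator or GeneratorParams()
        self.detection = self.detection or DetectionParams()
        self.train = self.train or TrainConfig(seed=self.seed)
        self.methods = self.methods or list(_DEFAULT_METHODS)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "schedule": self.schedule.to_dict(),
            "generator": dataclasses.asdict(self.generator),
            "confound": None if self.confound is None else dataclasses.asdict(self.confound),
            "detection": dataclasses.asdict(self.detection),
            "train": dataclasses.asdict(self.train),
            "methods": list(self.methods),
            "n_permutations": self.n_permutations,
            "alpha": self.alpha,
        }


def _strict_kwargs(cls, d: dict, where: str) -> dict:
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")
    out = dict(d)
    # YAML turns tuples into lists; dataclasses here expect tuples
    for f in dataclasses.fields(cls):
        if f.name in out and isinstance(out[f.name], list):
            out[f.name] = tuple(
                tuple(v) if isinstance(v, list) else v for v in out[f.name]
            )
    return out


def config_from_dict(d: dict) -> PipelineConfig:
    from .schedule import build_schedule

    top_allowed = {"seed", "output_dir", "schedule", "generator", "confound",
                   "detection", "train", "methods", "n_permutations", "alpha"}
    unknown = set(d) - top_allowed
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
    seed = int(d.get("seed", 0))
    sched_d = dict(d.get("schedule", {}))
    if "trial_orders" in sched_d:
        schedule = ExperimentSchedule.from_dict(sched_d)
    else:
        sched_kwargs = _strict_kwargs(ExperimentSchedule, sched_d, "schedule")
        sched_kwargs.pop("seed", None)
        schedule = build_schedule(seed=seed, **sched_kwargs)
    generator = GeneratorParams(**_strict_kwargs(GeneratorParams,
                                                 d.get("generator", {}), "generator"))
    confound = None
    if d.get("confound") is not None:
        cd = _strict_kwargs(ConfoundSpec, d["confound"], "confound")
        if cd.get("rate_modulation"):
            cd["rate_modulation"] = {float(k): float(v)
                                     for k, v in cd["rate_modulation"].items()}
        confound = ConfoundSpec(**cd)
    detection = DetectionParams(**_strict_kwargs(DetectionParams,
                                                 d.get("detection", {}), "detection"))
    train = TrainConfig(**_strict_kwargs(TrainConfig, d.get("train", {}), "train"))
    methods = list(d.get("methods", _DEFAULT_METHODS))
    known_methods = {"svm_raw", "svm_stats", "svm_time", "cnn", "rnn"}
    bad = set(methods) - known_methods
    if bad:
        raise ConfigError(f"unknown decoding methods: {sorted(bad)}")
    return PipelineConfig(
        seed=seed,
        output_dir=str(d.get("output_dir", ".")),
        schedule=schedule,
        generator=generator,
        confound=confound,
        detection=detection,
        train=train,
        methods=methods,
        n_permutations=int(d.get("n_permutations", 1000)),
        alpha=float(d.get("alpha", 0.05)),
    )


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return config_from_dict(d)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2^31) derived from the global seed."""
    ss = np.random.SeedSequence([global_seed, abs(hash_stage(stage))])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def hash_stage(stage: str) -> int:
    # stable across processes (unlike built-in hash on str)
    return int.from_bytes(stage.encode()[:8].ljust(8, b"\0"), "little")
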