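"""Run configuration: one object controlling every generator,
preprocessing, design, and inference parameter, serializable to YAML."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .simulate import (
    DEFAULT_ACCURACY,
    DEFAULT_ACCURACY_SD_BETWEEN,
    DEFAULT_RT_MEAN,
    DEFAULT_RT_SD_BETWEEN,
    BoldGenConfig,
    PupilGenConfig,
)


@dataclass(frozen=True)
class QcThresholds:
    missing_fraction_max: float = 0.20
    gaze_outside_fraction_max: float = 0.20
    gaze_sd_multiplier: float = 3.3
    sd_x: float = 105.34
    sd_y: float = 91.40


@dataclass(frozen=True)
class PreprocessParams:
    smooth_window: float = 0.2   # s
    sample_rate: float = 250.0   # Hz
    trial_mean_rate: float = 10.0  # Hz, for trial-wise pupil means
    change_rate: float = 1.0     # Hz, pupil-change bins


@dataclass(frozen=True)
class DesignParams:
    tr: float = 2.5
    n_volumes: int = 176
    discard: int = 4
    drift_cutoff: float = 128.0


@dataclass(frozen=True)
class InferenceParams:
    d_thresholds: tuple = (0.2, 0.5)
    logbf_min: float = 3.0


@dataclass(frozen=True)
class BehaviorParams:
    rt_means: dict = field(default_factory=lambda: dict(DEFAULT_RT_MEAN))
    rt_sds_between: dict = field(default_factory=lambda: dict(DEFAULT_RT_SD_BETWEEN))
    trial_rt_sd: float = 0.1
    accuracy: dict = field(default_factory=lambda: dict(DEFAULT_ACCURACY))
    accuracy_sds_between: dict = field(default_factory=lambda: dict(DEFAULT_ACCURACY_SD_BETWEEN))


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs; defaults are the task and
    analysis constants of the study design."""

    seed: int = 0
    n_subjects: int = 3
    #: inter-subject phasic-amplitude SD (z); None = per-cell reported SDs
    amp_subject_sd: float | None = None
    pupil: PupilGenConfig = field(default_factory=PupilGenConfig)
    bold: BoldGenConfig = field(default_factory=BoldGenConfig)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    qc: QcThresholds = field(default_factory=QcThresholds)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    design: DesignParams = field(default_factory=DesignParams)
    inference: InferenceParams = field(default_factory=InferenceParams)

    def to_dict(self) -> dict:
        return _normalize(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return _build(cls, d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _normalize(obj):
    """Tuples to lists, recursively, for stable YAML/JSON output."""
    if isinstance(obj, dict):
        return {k: _normalize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_normalize(v) for v in obj]
    return obj


def _build(cls, d: dict):
    """Rebuild a (possibly nested) frozen dataclass from a plain dict."""
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            v = _build(f.type, v)
        elif f.name in _NESTED:
            v = _build(_NESTED[f.name], v)
        elif isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


_NESTED = {
    "pupil": PupilGenConfig,
    "bold": BoldGenConfig,
    "behavior": BehaviorParams,
    "qc": QcThresholds,
    "preprocess": PreprocessParams,
    "design": DesignParams,
    "inference": InferenceParams,
}
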