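"""Pipeline configuration: nested dataclasses with lossless YAML round-trip.

Every default here mirrors the module-level default it configures; the
single global ``seed`` feeds every randomized component via a fixed
derivation (see :func:`derive_seed`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class BackgroundConfig:
    window_s: float = 20.0
    freeze_after_warmup: bool = False


@dataclass
class SegmentConfig:
    min_area: int = 4
    kmeans_max_iter: int = 100
    kmeans_tol: float = 1e-6
    kmeans_init: str = "minmax"


@dataclass
class ClassifierConfig:
    method: str = "rf"  # "rf" | "svm"
    model_path: str | None = None
    feature_set: str = "magnitude"
    decision_threshold: float = 0.5
    n_train_per_class: int = 200  # used when training from the synthetic DB


@dataclass
class TrackerConfig:
    lam: float = 0.5
    max_d: float | None = None  # None -> 10% of the frame diagonal
    c_min: float = 0.3
    max_age: int = 5
    min_hits: int = 2


@dataclass
class BehaviorConfig:
    window_s: float = 20.0
    epsilon: float = 0.5
    interval_s: float = 20.0
    mm_per_px: float | None = None


@dataclass
class PipelineConfig:
    input_path: str | None = None
    out_dir: str = "daphtrack_out"
    fps: float = 15.0
    roi: tuple[int, int, int, int] | None = None
    seed: int = 0
    log_level: str = "INFO"
    background: BackgroundConfig = field(default_factory=BackgroundConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d.get("roi") is not None:
            d["roi"] = list(d["roi"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (
            ("background", BackgroundConfig),
            ("segment", SegmentConfig),
            ("classifier", ClassifierConfig),
            ("tracker", TrackerConfig),
            ("behavior", BehaviorConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if d.get("roi") is not None:
            d["roi"] = tuple(d["roi"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


_SEED_STREAMS = {
    "scene": 1,
    "patch_db": 2,
    "classifier": 3,
    "kmeans": 4,
    "bootstrap": 5,
    "acceptance": 6,
}


def derive_seed(global_seed: int, stream: str) -> int:
    """Stable per-component seed derived from the single global seed."""
    if stream not in _SEED_STREAMS:
        raise KeyError(f"unknown seed stream {stream!r}")
    # SplitMix-style mix keeps streams decorrelated and below 2**31
    x = (global_seed * 0x9E3779B1 + _SEED_STREAMS[stream] * 0x85EBCA77) & 0xFFFFFFFF
    x ^= x >> 16
    x = (x * 0x45D9F3B) & 0xFFFFFFFF
    x ^= x >> 16
    return x % (2**31 - 1)
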