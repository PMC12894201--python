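"""Pipeline configuration: one dataclass, YAML round-trip, validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .features import DEFAULT_BAND_EDGES, DEFAULT_MIN_EVENT_SECONDS
from .record_io import DEFAULT_ECG_ALIASES, DEFAULT_RESPIRATORY_EVENT_NAMES, DEFAULT_SPO2_ALIASES
from .spectral import DEFAULT_F_MAX_HZ, DEFAULT_MIN_BEATS, DEFAULT_OVERLAP_S, DEFAULT_WINDOW_S


class ConfigError(ValueError):
    """Raised for invalid pipeline configuration."""


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable pipeline parameters with their analysis defaults.

    The defaults encode the analysis configuration the pipeline is built
    around: 180 s windows with 175 s overlap (0.006 Hz resolution), window
    label threshold 36 s (20% of the window), AHI decision cutoff 20/h, an
    RBF-kernel window classifier with standardized features.
    """

    window_length_s: float = DEFAULT_WINDOW_S
    overlap_s: float = DEFAULT_OVERLAP_S
    f_max_hz: float = DEFAULT_F_MAX_HZ
    band_edges: tuple[float, ...] = DEFAULT_BAND_EDGES
    min_event_seconds: float = DEFAULT_MIN_EVENT_SECONDS
    min_beats_per_window: int = DEFAULT_MIN_BEATS
    ahi_cutoff: float = 20.0
    include_spo2_features: bool = True
    svm_box_constraint: float = 1.0
    svm_kernel_scale: str | float = "auto"
    cv_folds: int = 10
    cv_grouping: str = "window"  # or "subject"
    seed: int = 0
    ecg_aliases: tuple[str, ...] = DEFAULT_ECG_ALIASES
    spo2_aliases: tuple[str, ...] = DEFAULT_SPO2_ALIASES
    respiratory_event_names: tuple[str, ...] = DEFAULT_RESPIRATORY_EVENT_NAMES

    def __post_init__(self) -> None:
        if self.overlap_s >= self.window_length_s:
            raise ConfigError(
                f"overlap_s ({self.overlap_s}) must be smaller than "
                f"window_length_s ({self.window_length_s})"
            )
        if self.min_event_seconds > self.window_length_s:
            raise ConfigError("min_event_seconds cannot exceed window_length_s")
        if self.cv_grouping not in ("window", "subject"):
            raise ConfigError("cv_grouping must be 'window' or 'subject'")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")

    @property
    def step_s(self) -> float:
        return self.window_length_s - self.overlap_s

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)
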