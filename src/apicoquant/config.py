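"""Run configuration: defaults, TOML loading, strict validation.

Configuration is flat TOML, one table per pipeline stage.  Unknown keys
are rejected (they are almost always typos), out-of-range values raise
through each parameter block's own validation, and the full effective
configuration — defaults included — is echoed to the log so every run is
auditable.  Acquisition calibration (pixel size, frame interval,
z-spacing) always comes from the user: none of it can be inferred from a
bare TIFF.
"""

from __future__ import annotations

import dataclasses
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .coloc import ColocParams
from .flattening import FilterBankParams
from .puncta import RobustBackgroundParams, SubapicalROIConfig
from .synth import (
    ColocPairConfig,
    ProtrusionMovieConfig,
    PunctaMovieConfig,
    TrackSceneConfig,
)
from .tracking import TrackingParams

logger = logging.getLogger("apicoquant")

#: early/mid/late stage windows in seconds, anchored at ~5, ~20 and
#: ~40 min into cellularization
DEFAULT_STAGE_WINDOWS = (
    ("early", 0.0, 600.0),
    ("mid", 600.0, 1800.0),
    ("late", 1800.0, 2700.0),
)


@dataclass(frozen=True)
class CalibrationConfig:
    """Physical calibration of the input acquisition."""

    pixel_size_um: float = 0.1
    frame_interval_s: float = 40.0
    z_spacing_um: float = 0.2

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "frame_interval_s", "z_spacing_um"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class PunctaPipelineConfig:
    """Detection area band and normalization baseline."""

    min_area_px: int = 2
    max_area_px: int = 200
    baseline_window: int = 20

    def __post_init__(self) -> None:
        if not (1 <= self.min_area_px <= self.max_area_px):
            raise ValueError("require 1 ≤ min_area_px ≤ max_area_px")
        if self.baseline_window < 1:
            raise ValueError("baseline_window must be ≥ 1")


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration for a full pipeline run."""

    stage_windows: tuple[tuple[str, float, float], ...] = DEFAULT_STAGE_WINDOWS
    apical_reference: float | str = "auto"
    rng_seed: int = 0
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    filter_bank: FilterBankParams = field(default_factory=FilterBankParams)
    thresholding: RobustBackgroundParams = field(
        default_factory=RobustBackgroundParams
    )
    puncta: PunctaPipelineConfig = field(default_factory=PunctaPipelineConfig)
    subapical: SubapicalROIConfig = field(default_factory=SubapicalROIConfig)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    coloc_overlap_fraction_min: float = 0.3
    protrusion_movie: ProtrusionMovieConfig = field(
        default_factory=ProtrusionMovieConfig
    )
    puncta_movie: PunctaMovieConfig = field(default_factory=PunctaMovieConfig)
    track_scene: TrackSceneConfig = field(default_factory=TrackSceneConfig)
    coloc_pair: ColocPairConfig = field(default_factory=ColocPairConfig)

    def __post_init__(self) -> None:
        windows = tuple(
            (str(lbl), float(a), float(b)) for lbl, a, b in self.stage_windows
        )
        object.__setattr__(self, "stage_windows", windows)
        prev_end = None
        for label, start, end in windows:
            if not (start < end):
                raise ValueError(f"stage window {label!r} has start ≥ end")
            if prev_end is not None and start < prev_end:
                raise ValueError("stage windows must be ordered and non-overlapping")
            prev_end = end
        if self.apical_reference != "auto":
            object.__setattr__(self, "apical_reference", float(self.apical_reference))
        if not (0.0 < self.coloc_overlap_fraction_min <= 1.0):
            raise ValueError("coloc_overlap_fraction_min must lie in (0, 1]")

    def coloc_params(self) -> ColocParams:
        return ColocParams(
            overlap_fraction_min=self.coloc_overlap_fraction_min,
            ref_background=self.thresholding,
            partner_background=self.thresholding,
            min_area=self.puncta.min_area_px,
            max_area=self.puncta.max_area_px,
        )


_SECTION_TYPES = {
    "calibration": CalibrationConfig,
    "filter_bank": FilterBankParams,
    "thresholding": RobustBackgroundParams,
    "puncta": PunctaPipelineConfig,
    "subapical": SubapicalROIConfig,
    "tracking": TrackingParams,
    "protrusion_movie": ProtrusionMovieConfig,
    "puncta_movie": PunctaMovieConfig,
    "track_scene": TrackSceneConfig,
    "coloc_pair": ColocPairConfig,
}

_TOP_LEVEL_SCALARS = {"stage_windows", "apical_reference", "rng_seed",
                      "coloc_overlap_fraction_min"}


def _build_section(name: str, cls: type, values: dict) -> object:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(
            f"unknown keys in [{name}]: {sorted(unknown)}; known: {sorted(known)}"
        )
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name not in values:
            continue
        v = values[f.name]
        coerced[f.name] = tuple(tuple(e) if isinstance(e, list) else e for e in v) \
            if isinstance(v, list) else v
    return cls(**coerced)


def load_run_config(path: str | Path | None = None) -> RunConfig:
    """Load a TOML run configuration, filling documented defaults.

    ``None`` (or an empty file) yields the all-defaults configuration.
    Unknown sections or keys and out-of-range values raise.  The
    effective configuration is logged.
    """
    raw: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    unknown_sections = set(raw) - set(_SECTION_TYPES) - _TOP_LEVEL_SCALARS
    if unknown_sections:
        raise ValueError(
            f"unknown config sections/keys: {sorted(unknown_sections)}"
        )
    kwargs: dict = {}
    for key in _TOP_LEVEL_SCALARS & set(raw):
        value = raw[key]
        if key == "stage_windows":
            value = tuple(tuple(w) for w in value)
        kwargs[key] = value
    for name, cls in _SECTION_TYPES.items():
        if name in raw:
            if not isinstance(raw[name], dict):
                raise ValueError(f"config section [{name}] must be a table")
            kwargs[name] = _build_section(name, cls, raw[name])
    cfg = RunConfig(**kwargs)
    logger.info("effective config: %s", cfg)
    return cfg
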