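"""Shared configuration for the digit-tracking pipeline.

Every protocol-level constant of the study lives here with its default
value: screen geometry (1920x1280 px tablet sampled at 60 Hz, viewed at
300 mm), the Gaussian-blur sigma of the crowding-free display, the
within-fixation dispersion limits, the kernel-density bandwidth factor,
the short/long word-length bounds and the assessment scoring rules.
Downstream modules read these defaults so a single config object can
retune the whole pipeline.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

# --- display / digitising constants -----------------------------------------

#: Gaussian blur standard deviation applied to stimulus text, px.
BLUR_SIGMA_PX: float = 20.0

#: Radius of the finger-contingent unblur window, px.  The window exposes
#: roughly the foveal area: 2 deg of visual angle at 300 mm viewing distance
#: is ~10.5 mm, i.e. ~78 px at the default pixel pitch.  Hard-edged circle.
UNBLUR_RADIUS_PX: float = 78.0

#: Maximum within-fixation spread of member samples, px (X, Y).  Slow streaks
#: wider than this are split greedily into several fixations.
DISPERSION_LIMIT_X_PX: float = 5.8
DISPERSION_LIMIT_Y_PX: float = 6.4

#: Kernel-density bandwidth = this factor times the nrd0-style reference rule.
DENSITY_BANDWIDTH_FACTOR: float = 0.4

#: Word-length classes in letters (inclusive bounds).
SHORT_WORD_RANGE: tuple[int, int] = (1, 6)
LONG_WORD_RANGE: tuple[int, int] = (7, 11)

#: Letter/syllable list scoring: discontinue after this many consecutive
#: errors; the list has at most this many items.
STOP_RUN: int = 5
MAX_LIST_ITEMS: int = 85

#: Minimum decodable-phoneme fraction for an admissible training sentence
#: (strict inequality).
DECODABILITY_MIN: float = 0.60

#: Tolerance for sampling-interval validation, as a fraction of the nominal
#: inter-sample interval (tablet schedulers jitter).
SAMPLING_TOLERANCE: float = 0.25


def _default_pixel_pitch(width_px: int = 1920, height_px: int = 1280,
                         diagonal_mm: float = 312.42) -> float:
    """mm per pixel of a 12.3-inch 3:2 panel (a plausible Dell Latitude
    tablet); the study never states the physical screen size."""
    diag_px = math.hypot(width_px, height_px)
    return diagonal_mm / diag_px


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical and digitising geometry of the touch display."""

    width_px: int = 1920
    height_px: int = 1280
    pixel_pitch: float = field(default_factory=_default_pixel_pitch)  # mm/px
    viewing_distance: float = 300.0  # mm
    sampling_rate: float = 60.0  # Hz

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("screen dimensions must be positive")
        if self.pixel_pitch is None or self.pixel_pitch <= 0:
            raise ConfigurationError("pixel_pitch must be a positive mm/px value")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def dt_ms(self) -> float:
        """Nominal inter-sample interval in milliseconds."""
        return 1000.0 / self.sampling_rate


class ConfigurationError(ValueError):
    """A required configuration value is missing or invalid."""


class ValidationError(ValueError):
    """An input file or record violates the schema."""


@dataclass
class PipelineConfig:
    """One YAML-loadable object covering every decision knob of a run."""

    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)
    blur_sigma_px: float = BLUR_SIGMA_PX
    unblur_radius_px: float = UNBLUR_RADIUS_PX
    dispersion_limit_px: tuple[float, float] = (DISPERSION_LIMIT_X_PX,
                                                DISPERSION_LIMIT_Y_PX)
    bandwidth_factor: float = DENSITY_BANDWIDTH_FACTOR
    stop_run: int = STOP_RUN
    max_list_items: int = MAX_LIST_ITEMS
    median_tie_rule: str = "poor"
    reml: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        geom_raw = raw.pop("geometry", {})
        if geom_raw is not None and "pixel_pitch" in geom_raw and (
                geom_raw["pixel_pitch"] is None or geom_raw["pixel_pitch"] <= 0):
            raise ConfigurationError("geometry.pixel_pitch must be positive")
        geometry = ScreenGeometry(**geom_raw)
        known = {f.name for f in dataclasses.fields(cls)} - {"geometry"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "dispersion_limit_px" in raw:
            raw["dispersion_limit_px"] = tuple(raw["dispersion_limit_px"])
        return cls(geometry=geometry, **raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["dispersion_limit_px"] = list(self.dispersion_limit_px)
        return d
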