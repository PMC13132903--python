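"""Acquisition and assay configuration.

The group arena is an aluminium frame with glass top and bottom; coordinates
use a fixed convention: origin at an arena corner, x along the long side,
y along the short side, millimetre units, 0-based frame indices.  One fixed
convention avoids silent mirroring between trials recorded with different
camera orientations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass(frozen=True)
class ArenaSpec:
    """Geometry and acquisition parameters of one group-arena setup.

    Parameters
    ----------
    length_mm, width_mm
        Interior dimensions; ``length_mm`` is the long side.
    fps
        Acquisition frame rate (Hz).
    mm_per_px
        Spatial scale used to convert pixel-coordinate tracker exports.
    group_size
        Number of flies per trial.
    body_length_mm
        Nominal adult body length, the distance unit of the interaction
        criterion.  Not fixed by the assay itself; default 2.5 mm for an
        adult male D. melanogaster.
    """

    length_mm: float = 66.0
    width_mm: float = 30.0
    fps: float = 30.0
    mm_per_px: float = 1.0
    group_size: int = 4
    body_length_mm: float = 2.5

    def __post_init__(self):
        if not (self.length_mm >= self.width_mm > 0):
            raise ConfigError(
                f"need length_mm >= width_mm > 0, got {self.length_mm} x {self.width_mm}"
            )
        if self.fps <= 0:
            raise ConfigError(f"fps must be positive, got {self.fps}")
        if self.mm_per_px <= 0:
            raise ConfigError(f"mm_per_px must be positive, got {self.mm_per_px}")
        if self.group_size < 2:
            raise ConfigError(f"group_size must be >= 2, got {self.group_size}")
        if self.body_length_mm <= 0:
            raise ConfigError(f"body_length_mm must be positive, got {self.body_length_mm}")


@dataclass(frozen=True)
class PhotoperiodSpec:
    """Light:dark cycle anchoring for the latency assay.

    Zeitgeber time (ZT): hours since lights-on; ZT0 = lights-on and, in the
    default 12:12 cycle, ZT12 = lights-off.  Trials start at ZT5 by default.
    """

    zt_start_h: float = 5.0
    lights_off_zt_h: float = 12.0
    lights_on_zt_h: float = 0.0

    def __post_init__(self):
        for name in ("zt_start_h", "lights_off_zt_h", "lights_on_zt_h"):
            v = getattr(self, name)
            if not (0 <= v < 24):
                raise ConfigError(f"{name} must lie in [0, 24), got {v}")
        if self.lights_off_zt_h == self.lights_on_zt_h:
            raise ConfigError("lights_off_zt_h must differ from lights_on_zt_h")

    def is_dark(self, zt_h: float) -> bool:
        """Whether absolute ZT ``zt_h`` (in [0, 24)) falls in the dark phase.

        The lights-off instant itself belongs to dark (dark onset); the
        lights-on instant belongs to light.
        """
        off, on = self.lights_off_zt_h, self.lights_on_zt_h
        zt = zt_h % 24.0
        if off < on:
            return off <= zt < on
        # dark interval wraps midnight-of-ZT, e.g. [12, 24) + [0, 0)
        return zt >= off or zt < on


@dataclass
class RunConfig:
    """Resolved parameter set for a pipeline run.

    Every run writes this next to its outputs so reruns are reproducible.
    """

    arena: ArenaSpec = field(default_factory=ArenaSpec)
    photoperiod: PhotoperiodSpec = field(default_factory=PhotoperiodSpec)
    min_coverage: float = 0.98
    coverage_mode: str = "per_fly"          # or "pooled"
    max_dist_bl: float = 2.0
    min_bout_s: float = 1.5
    bout_mode: str = "directed"             # or "undirected"
    mask_long_angle_gaps: bool = True
    n_boot: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.min_coverage <= 1):
            raise ConfigError(f"min_coverage must lie in (0, 1], got {self.min_coverage}")
        if self.coverage_mode not in ("per_fly", "pooled"):
            raise ConfigError(f"unknown coverage_mode {self.coverage_mode!r}")
        if self.max_dist_bl <= 0 or self.min_bout_s <= 0:
            raise ConfigError("thresholds must be positive")
        if self.bout_mode not in ("directed", "undirected"):
            raise ConfigError(f"unknown bout_mode {self.bout_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        arena = ArenaSpec(**raw.pop("arena", {}))
        photo = PhotoperiodSpec(**raw.pop("photoperiod", {}))
        known = {f for f in cls.__dataclass_fields__ if f not in ("arena", "photoperiod")}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(arena=arena, photoperiod=photo, **raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
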