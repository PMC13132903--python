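"""Locomotor activity and centrophobism covariates.

Between-line differences in walking speed or reluctance to enter the arena
center could confound the social metrics, so both are computed per trial:
average walking speed (cm/s) and the fraction of time spent in a central
region defined by trimming a quarter of the arena's short side from every
edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import ArenaSpec
from .errors import ConfigError
from .io import TrialRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LocomotionMetrics:
    mean_speed_cm_s: float
    center_fraction: float  # dimensionless; multiply by 100 to report as %


def center_rectangle(arena: ArenaSpec) -> tuple[float, float, float, float]:
    """Inner-rectangle bounds (x_min, x_max, y_min, y_max) in mm.

    The margin is a quarter of the short side, removed from all four edges;
    for the 66 x 30 mm arena this leaves a 51 x 15 mm center.
    """
    m = arena.width_mm / 4.0
    if arena.length_mm <= 2 * m:
        raise ConfigError(
            f"degenerate center region: length {arena.length_mm} <= 2 x margin {m}"
        )
    return m, arena.length_mm - m, m, arena.width_mm - m


def speed_metrics(trial: TrialRecord) -> float:
    """Group-mean average walking speed in cm/s.

    Per fly, speed is displacement between consecutive analysable frames
    divided by the frame period; pairs spanning a masked frame are excluded.
    Per-fly means are averaged over flies.
    """
    fps = trial.arena.fps
    per_fly = []
    for t in trial.trajectories:
        both = t.analysis_valid[:-1] & t.analysis_valid[1:]
        if not both.any():
            logger.warning(
                "trial %s fly %s: no consecutive analysable frames, excluded from speed",
                trial.trial_id, t.fly_id,
            )
            continue
        dx = np.diff(t.x_mm)[both]
        dy = np.diff(t.y_mm)[both]
        step_mm = np.hypot(dx, dy)
        per_fly.append(float(np.mean(step_mm)) * fps / 10.0)  # mm/frame -> cm/s
    if not per_fly:
        raise ValueError(f"trial {trial.trial_id}: no fly has measurable speed")
    return float(np.mean(per_fly))


def exploration_metric(trial: TrialRecord, arena: ArenaSpec | None = None) -> float:
    """Group-mean fraction of analysable frames spent in the center region.

    The rectangle is closed: a centroid exactly on the boundary counts as
    inside.
    """
    arena = arena or trial.arena
    x0, x1, y0, y1 = center_rectangle(arena)
    per_fly = []
    for t in trial.trajectories:
        av = t.analysis_valid
        if not av.any():
            continue
        inside = (
            (t.x_mm[av] >= x0) & (t.x_mm[av] <= x1)
            & (t.y_mm[av] >= y0) & (t.y_mm[av] <= y1)
        )
        per_fly.append(float(np.mean(inside)))
    if not per_fly:
        raise ValueError(f"trial {trial.trial_id}: no analysable frames")
    return float(np.mean(per_fly))


def locomotion_summary(trial: TrialRecord) -> LocomotionMetrics:
    return LocomotionMetrics(
        mean_speed_cm_s=speed_metrics(trial),
        center_fraction=exploration_metric(trial),
    )
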