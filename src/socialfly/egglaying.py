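"""Scoring of the two egg-laying sociability assays.

Preference assay: a mated female chooses between a food patch carrying
aggregation-pheromone extract (communal signal) and a solvent-control patch;
the preference index is (eggs on pheromone patch - eggs on control patch)
divided by total eggs, +1 fully communal, -1 fully solitary.

Latency assay: a focal female grouped with males is imaged at 15-minute
intervals over 24 h; latency is the time of the first egg on that grid.
Because trials start at ZT5 in a 12:12 light:dark cycle, the latency also
fixes whether the first egg fell in the light or the dark phase, and each
genotype's percentage of night layers summarises how strongly the line waits
for darkness rather than responding to the group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PhotoperiodSpec
from .errors import UndefinedMetricError, ValidationError
from .io import EggCountSeries, PreferenceTrial


@dataclass(frozen=True)
class LatencyResult:
    line_id: str
    trial_id: str
    latency_min: float | None  # None when censored (no egg by horizon)
    phase: str                 # "light" | "dark" | "censored"

    @property
    def censored(self) -> bool:
        return self.latency_min is None


def preference_index(trial: PreferenceTrial) -> float | None:
    """(E_pheromone - E_control) / total, or None when no eggs were laid.

    Trials with zero total eggs carry no information about preference and
    are excluded from aggregation (infertile trials are dropped, mirroring
    the exclusion of lines laying no eggs in 24 h).
    """
    if trial.eggs_pheromone < 0 or trial.eggs_control < 0:
        raise ValidationError("egg counts must be non-negative")
    total = trial.eggs_pheromone + trial.eggs_control
    if total == 0:
        return None
    return (trial.eggs_pheromone - trial.eggs_control) / total


def first_egg_latency(series: EggCountSeries) -> LatencyResult:
    """Latency to first egg, quantized to the sampling grid; censored if none.

    No sub-interval interpolation is applied: the time-lapse protocol only
    resolves onset to the 15-minute grid, so the estimate is the first
    sampling time with a positive cumulative count.
    """
    positive = np.flatnonzero(series.cum_eggs >= 1)
    if len(positive) == 0:
        return LatencyResult(series.line_id, series.trial_id, None, "censored")
    latency = float(series.times_min[positive[0]])
    phase = phase_of_first_egg(latency, series.photoperiod)
    return LatencyResult(series.line_id, series.trial_id, latency, phase)


def phase_of_first_egg(latency_min: float, photoperiod: PhotoperiodSpec) -> str:
    """Light/dark phase at the moment of the first egg.

    Absolute ZT = (ZT at trial start + latency in hours) mod 24; the
    lights-off instant itself is assigned to dark.
    """
    zt = (photoperiod.zt_start_h + latency_min / 60.0) % 24.0
    return "dark" if photoperiod.is_dark(zt) else "light"


def percent_night_layers(results: list[LatencyResult]) -> float:
    """Percentage of non-censored trials whose first egg fell in the dark."""
    scored = [r for r in results if not r.censored]
    if not scored:
        raise UndefinedMetricError("all trials censored; percent night layers undefined")
    dark = sum(1 for r in scored if r.phase == "dark")
    return 100.0 * dark / len(scored)


def latency_line_summary(results: list[LatencyResult]) -> pd.DataFrame:
    """Per-line mean latency, percent night layers, and censoring audit.

    Censored trials are excluded from the mean and the night percentage but
    counted, so exclusions are auditable.
    """
    rows = []
    by_line: dict[str, list[LatencyResult]] = {}
    for r in results:
        by_line.setdefault(r.line_id, []).append(r)
    for line_id in sorted(by_line):
        rs = by_line[line_id]
        scored = [r for r in rs if not r.censored]
        rows.append(
            {
                "line_id": line_id,
                "mean_latency_min": float(np.mean([r.latency_min for r in scored]))
                if scored else np.nan,
                "percent_night": percent_night_layers(rs) if scored else np.nan,
                "n": len(scored),
                "n_censored": len(rs) - len(scored),
            }
        )
    return pd.DataFrame(rows)
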