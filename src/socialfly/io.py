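"""Reading, validating and writing the pipeline's tabular inputs and outputs.

Trajectory tables follow the common tracker-export layout: one row per
(frame, fly), columns ``frame,id,x,y,angle``, comma-separated with a header.
Missing observations may be encoded either as absent rows or as NaN
coordinates; both mean the same thing.  Egg-count files are per-trial CSVs:
``time_min,eggs`` cumulative series for the latency assay and one
``eggs_pheromone,eggs_control`` pair per trial for the preference assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .config import ArenaSpec, PhotoperiodSpec
from .errors import ParseError, ValidationError

PROV_OBSERVED = "observed"
PROV_NN = "nn_filled"
PROV_SPLINE = "spline_filled"
PROV_MASKED = "masked"


@dataclass
class RawTrajectory:
    """One fly's possibly-gappy per-frame position/heading series.

    Arrays share a dense 0-based frame axis; frames where ``valid`` is False
    carry NaN coordinates.  Angles are radians in [-pi, pi).
    """

    fly_id: int
    x_mm: np.ndarray
    y_mm: np.ndarray
    theta_rad: np.ndarray
    valid: np.ndarray

    # set by trajectory_cleaning; equal to `valid` on raw input
    analysis_valid: np.ndarray = None  # type: ignore[assignment]
    provenance: np.ndarray = None      # type: ignore[assignment]

    def __post_init__(self):
        n = len(self.valid)
        for name in ("x_mm", "y_mm", "theta_rad"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} length mismatch for fly {self.fly_id}")
        if self.analysis_valid is None:
            self.analysis_valid = self.valid.copy()
        if self.provenance is None:
            self.provenance = np.where(self.valid, PROV_OBSERVED, PROV_MASKED).astype(object)

    @property
    def n_frames(self) -> int:
        return len(self.valid)

    @property
    def coverage(self) -> float:
        return float(np.mean(self.valid)) if self.n_frames else 0.0

    def copy(self) -> "RawTrajectory":
        return RawTrajectory(
            fly_id=self.fly_id,
            x_mm=self.x_mm.copy(),
            y_mm=self.y_mm.copy(),
            theta_rad=self.theta_rad.copy(),
            valid=self.valid.copy(),
            analysis_valid=self.analysis_valid.copy(),
            provenance=self.provenance.copy(),
        )


@dataclass
class TrialRecord:
    """A group-arena trial: one trajectory per fly on a shared frame axis."""

    trial_id: str
    line_id: str
    trajectories: list[RawTrajectory]
    arena: ArenaSpec
    n_frames_total: int

    def __post_init__(self):
        if len(self.trajectories) != self.arena.group_size:
            raise ValidationError(
                f"trial {self.trial_id}: expected {self.arena.group_size} trajectories, "
                f"got {len(self.trajectories)}"
            )
        for t in self.trajectories:
            if t.n_frames != self.n_frames_total:
                raise ValidationError(
                    f"trial {self.trial_id}: fly {t.fly_id} has {t.n_frames} frames, "
                    f"expected {self.n_frames_total}"
                )

    def copy(self) -> "TrialRecord":
        return replace(self, trajectories=[t.copy() for t in self.trajectories])


@dataclass(frozen=True)
class RetentionDecision:
    keep: bool
    coverage: dict[int, float]      # fly_id -> fraction of valid frames
    reason: str = ""


@dataclass
class EggCountSeries:
    """Cumulative egg counts on a fixed sampling grid over the assay horizon."""

    line_id: str
    trial_id: str
    times_min: np.ndarray
    cum_eggs: np.ndarray
    interval_min: float = 15.0
    horizon_min: float = 1440.0
    photoperiod: PhotoperiodSpec = field(default_factory=PhotoperiodSpec)

    def __post_init__(self):
        t = np.asarray(self.times_min, dtype=float)
        e = np.asarray(self.cum_eggs, dtype=float)
        if len(t) != len(e) or len(t) == 0:
            raise ValidationError("times and counts must be equal-length and non-empty")
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValidationError("times must increase strictly from 0")
        if np.any(e < 0):
            raise ValidationError("negative egg count")
        if np.any(np.diff(e) < 0):
            raise ValidationError("cumulative egg counts must be non-decreasing")
        self.times_min = t
        self.cum_eggs = e


@dataclass(frozen=True)
class PreferenceTrial:
    """Final egg counts on the pheromone-treated and control patches."""

    line_id: str
    trial_id: str
    eggs_pheromone: int
    eggs_control: int

    def __post_init__(self):
        if self.eggs_pheromone < 0 or self.eggs_control < 0:
            raise ValidationError("egg counts must be non-negative")


# ---------------------------------------------------------------------------
# trajectory tables


def read_trajectory_table(
    path: str | Path,
    arena: ArenaSpec,
    *,
    trial_id: str = "",
    line_id: str = "",
    coords: str = "mm",
    n_frames_total: int | None = None,
) -> TrialRecord:
    """Read a ``frame,id,x,y,angle`` CSV into a :class:`TrialRecord`.

    Every distinct id is re-indexed onto a dense shared frame axis
    ``[0, n_frames_total)`` with per-frame valid flags; a frame is missing
    for a fly if its row is absent or its coordinates are NaN.  With
    ``coords="px"`` coordinates are converted to mm via ``arena.mm_per_px``.
    """
    path = Path(path)
    if coords not in ("mm", "px"):
        raise ValueError(f"coords must be 'mm' or 'px', got {coords!r}")
    try:
        # round_trip float parsing: written coordinates re-read bit-identically
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    required = {"frame", "id", "x", "y", "angle"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if df["frame"].isna().any() or df["id"].isna().any():
        bad = int(df.index[df["frame"].isna() | df["id"].isna()][0]) + 2
        raise ParseError(f"{path}: missing frame or id", line_number=bad)
    dup = df.duplicated(subset=["frame", "id"])
    if dup.any():
        f, i = df.loc[dup.idxmax(), ["frame", "id"]]
        raise ValidationError(f"{path}: duplicate (frame={int(f)}, id={int(i)}) pair")

    df = df.astype({"frame": int, "id": int})
    if n_frames_total is None:
        n_frames_total = int(df["frame"].max()) + 1
    if (df["frame"] < 0).any() or (df["frame"] >= n_frames_total).any():
        raise ValidationError(f"{path}: frame index outside [0, {n_frames_total})")

    scale = arena.mm_per_px if coords == "px" else 1.0
    trajectories = []
    for fly_id, sub in df.groupby("id", sort=True):
        x = np.full(n_frames_total, np.nan)
        y = np.full(n_frames_total, np.nan)
        th = np.full(n_frames_total, np.nan)
        fr = sub["frame"].to_numpy()
        x[fr] = sub["x"].to_numpy() * scale
        y[fr] = sub["y"].to_numpy() * scale
        th[fr] = wrap_angle(sub["angle"].to_numpy(dtype=float))
        valid = ~(np.isnan(x) | np.isnan(y) | np.isnan(th))
        x[~valid] = np.nan
        y[~valid] = np.nan
        th[~valid] = np.nan
        trajectories.append(RawTrajectory(int(fly_id), x, y, th, valid))
    return TrialRecord(
        trial_id=trial_id or path.stem,
        line_id=line_id,
        trajectories=trajectories,
        arena=arena,
        n_frames_total=n_frames_total,
    )


def write_trajectory_table(trial: TrialRecord, path: str | Path) -> None:
    """Write a TrialRecord back to the ``frame,id,x,y,angle`` layout.

    Missing frames are written as rows with NaN coordinates so the frame
    axis round-trips exactly.
    """
    rows = []
    for t in trial.trajectories:
        rows.append(
            pd.DataFrame(
                {
                    "frame": np.arange(trial.n_frames_total),
                    "id": t.fly_id,
                    "x": t.x_mm,
                    "y": t.y_mm,
                    "angle": t.theta_rad,
                }
            )
        )
    out = pd.concat(rows).sort_values(["frame", "id"])
    # default float formatting is shortest-repr, which round-trips float64 exactly
    out.to_csv(path, index=False)


def wrap_angle(theta):
    """Map angles to the canonical interval [-pi, pi)."""
    return (np.asarray(theta) + np.pi) % (2 * np.pi) - np.pi


# ---------------------------------------------------------------------------
# retention


def retention_filter(
    trial: TrialRecord,
    min_coverage: float = 0.98,
    mode: str = "per_fly",
) -> RetentionDecision:
    """Keep a trial only if tracking coverage reaches ``min_coverage``.

    ``per_fly`` (default) requires every fly to reach the threshold — a
    single poorly tracked fly invalidates all pairwise metrics.  ``pooled``
    applies the threshold to the trial-wide fraction of valid (fly, frame)
    cells instead.
    """
    if trial.n_frames_total <= 0:
        raise ValidationError("n_frames_total must be positive")
    coverage = {t.fly_id: t.coverage for t in trial.trajectories}
    empties = [fid for fid, c in coverage.items() if c == 0.0]
    if empties:
        return RetentionDecision(False, coverage, f"empty trajectory for fly {empties}")
    if mode == "per_fly":
        worst = min(coverage, key=coverage.get)
        keep = coverage[worst] >= min_coverage
        reason = "" if keep else f"fly {worst} coverage {coverage[worst]:.4f} < {min_coverage}"
    elif mode == "pooled":
        pooled = float(np.mean(list(coverage.values())))
        keep = pooled >= min_coverage
        reason = "" if keep else f"pooled coverage {pooled:.4f} < {min_coverage}"
    else:
        raise ValueError(f"unknown retention mode {mode!r}")
    return RetentionDecision(keep, coverage, reason)


# ---------------------------------------------------------------------------
# egg-count files


def read_egg_series(
    path: str | Path,
    *,
    line_id: str = "",
    trial_id: str = "",
    interval_min: float = 15.0,
    photoperiod: PhotoperiodSpec | None = None,
) -> EggCountSeries:
    """Read a cumulative ``time_min,eggs`` latency-assay series."""
    path = Path(path)
    df = pd.read_csv(path)
    if not {"time_min", "eggs"}.issubset(df.columns):
        raise ParseError(f"{path}: need columns time_min,eggs")
    t = df["time_min"].to_numpy(dtype=float)
    if np.any(np.mod(t, interval_min) != 0):
        raise ValidationError(f"{path}: times must be multiples of {interval_min} min")
    return EggCountSeries(
        line_id=line_id,
        trial_id=trial_id or path.stem,
        times_min=t,
        cum_eggs=df["eggs"].to_numpy(dtype=float),
        interval_min=interval_min,
        horizon_min=float(t[-1]),
        photoperiod=photoperiod or PhotoperiodSpec(),
    )


def read_preference_table(path: str | Path) -> list[PreferenceTrial]:
    """Read a ``line_id,trial_id,eggs_pheromone,eggs_control`` table."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"line_id", "trial_id", "eggs_pheromone", "eggs_control"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if (df[["eggs_pheromone", "eggs_control"]] < 0).any().any():
        raise ValidationError(f"{path}: negative egg counts")
    return [
        PreferenceTrial(str(r.line_id), str(r.trial_id), int(r.eggs_pheromone), int(r.eggs_control))
        for r in df.itertuples()
    ]


def write_metrics_table(rows: Iterable[dict], path: str | Path) -> pd.DataFrame:
    """Write tidy per-trial metric rows (one dict per trial) to CSV."""
    df = pd.DataFrame(list(rows))
    df.to_csv(path, index=False)
    return df
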