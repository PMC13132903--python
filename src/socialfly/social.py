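"""Interaction-bout detection and group social metrics.

Two flies are scored as interacting when, simultaneously, (a) the angle
between the focal fly's body axis and the direction to the partner's centroid
is less than 90 degrees, (b) the centroid distance is at most two body
lengths, and (c) both conditions persist for at least 1.5 s.  The angular
criterion is focal-specific, so bouts are directed (focal -> partner) by
default; an undirected mode unions the two directed indicator series per
unordered pair before applying the persistence threshold.

The per-trial summary comprises the four group-level social metrics: bout
count, cumulative bout duration, interindividual distance (mean over frames
of the mean pairwise centroid distance) and nearest-neighbor distance (mean
over frames and flies of the distance to the closest conspecific).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError
from .io import TrialRecord


@dataclass(frozen=True)
class InteractionBout:
    """A maximal directed episode satisfying all three interaction criteria."""

    focal_id: int
    partner_id: int
    start_frame: int
    end_frame: int  # half-open
    duration_s: float


@dataclass(frozen=True)
class SocialMetrics:
    n_interactions: int
    total_duration_s: float
    interindividual_mm: float
    nearest_neighbor_mm: float


def min_bout_frames(min_bout_s: float, fps: float) -> int:
    """Persistence threshold in frames: ceil(min_bout_s * fps), 45 at 30 fps."""
    return math.ceil(min_bout_s * fps)


def facing(focal_x, focal_y, focal_theta, partner_x, partner_y) -> bool:
    """Whether the partner centroid lies within 90 degrees of the focal's axis.

    Strict: a partner exactly perpendicular (dot product zero) does not count.
    Coincident centroids count as facing by convention — an undefined
    direction at distance zero should not break an ongoing contact bout.
    """
    dx, dy = partner_x - focal_x, partner_y - focal_y
    if dx == 0 and dy == 0:
        return True
    return math.cos(focal_theta) * dx + math.sin(focal_theta) * dy > 0


def _stacked(trial: TrialRecord):
    """(ids, X, Y, TH, AV) arrays of shape (n_flies, n_frames)."""
    ids = [t.fly_id for t in trial.trajectories]
    X = np.stack([t.x_mm for t in trial.trajectories])
    Y = np.stack([t.y_mm for t in trial.trajectories])
    TH = np.stack([t.theta_rad for t in trial.trajectories])
    AV = np.stack([t.analysis_valid for t in trial.trajectories])
    return ids, X, Y, TH, AV


def _directed_indicator(X, Y, TH, AV, i, j, max_dist_mm):
    """Per-frame boolean: fly i interacting toward fly j (criteria a and b)."""
    dx = X[j] - X[i]
    dy = Y[j] - Y[i]
    with np.errstate(invalid="ignore"):
        dist = np.hypot(dx, dy)
        dot = np.cos(TH[i]) * dx + np.sin(TH[i]) * dy
        face = (dot > 0) | (dist == 0)
        near = dist <= max_dist_mm
    return AV[i] & AV[j] & face & near


def _runs(indicator: np.ndarray):
    """(start, end) pairs of maximal True runs, half-open."""
    padded = np.concatenate([[False], indicator, [False]])
    diff = np.diff(padded.astype(np.int8))
    return zip(np.flatnonzero(diff == 1), np.flatnonzero(diff == -1))


def frame_pair_distances(trial: TrialRecord, frame: int) -> pd.DataFrame:
    """Pairwise centroid distances (mm) among flies analysable at ``frame``."""
    ids, X, Y, _, AV = _stacked(trial)
    rows = []
    for a, b in combinations(range(len(ids)), 2):
        if AV[a, frame] and AV[b, frame]:
            d = math.hypot(X[a, frame] - X[b, frame], Y[a, frame] - Y[b, frame])
            rows.append({"fly_a": ids[a], "fly_b": ids[b], "distance_mm": d})
    return pd.DataFrame(rows, columns=["fly_a", "fly_b", "distance_mm"])


def distance_metrics(trial: TrialRecord) -> tuple[float, float]:
    """(interindividual_mm, nearest_neighbor_mm) over contributing frames.

    Frames with fewer than two analysable flies are excluded from both.
    """
    _, X, Y, _, AV = _stacked(trial)
    n_flies, n_frames = AV.shape
    pair_idx = list(combinations(range(n_flies), 2))
    D = np.full((len(pair_idx), n_frames), np.nan)
    for p, (a, b) in enumerate(pair_idx):
        both = AV[a] & AV[b]
        D[p, both] = np.hypot(X[a, both] - X[b, both], Y[a, both] - Y[b, both])
    pair_valid = ~np.isnan(D)
    contributing = pair_valid.sum(axis=0) >= 1  # >=2 valid flies <=> >=1 valid pair
    if not contributing.any():
        raise UndefinedMetricError("no frame has two analysable flies")

    with np.errstate(invalid="ignore"):
        frame_mean_pairwise = np.nanmean(D[:, contributing], axis=0)
    interindividual = float(np.mean(frame_mean_pairwise))

    # per fly per frame: min distance to any other valid fly
    NN = np.full((n_flies, n_frames), np.inf)
    for p, (a, b) in enumerate(pair_idx):
        ok = pair_valid[p]
        NN[a, ok] = np.minimum(NN[a, ok], D[p, ok])
        NN[b, ok] = np.minimum(NN[b, ok], D[p, ok])
    nn_vals = []
    for f in np.flatnonzero(contributing):
        col = NN[:, f]
        nn_vals.append(float(np.mean(col[np.isfinite(col)])))
    nearest_neighbor = float(np.mean(nn_vals))
    return interindividual, nearest_neighbor


def detect_bouts(
    trial: TrialRecord,
    body_length_mm: float | None = None,
    min_bout_s: float = 1.5,
    max_dist_bl: float = 2.0,
    mode: str = "directed",
) -> list[InteractionBout]:
    """Find all interaction bouts in a cleaned trial.

    A bout is a maximal run of frames on which the per-frame indicator
    (both flies analysable, focal facing partner, centroid distance at most
    ``max_dist_bl`` body lengths) is true for at least
    ``ceil(min_bout_s * fps)`` consecutive frames.  Masked frames break runs;
    no gap bridging is applied.

    ``mode="directed"`` (default) scans every ordered (focal, partner) pair;
    ``mode="undirected"`` unions the two directed indicators per unordered
    pair and reports one bout series per pair (focal_id < partner_id).
    """
    if mode not in ("directed", "undirected"):
        raise ValueError(f"unknown mode {mode!r}")
    fps = trial.arena.fps
    if body_length_mm is None:
        body_length_mm = trial.arena.body_length_mm
    max_dist_mm = max_dist_bl * body_length_mm
    need = min_bout_frames(min_bout_s, fps)
    ids, X, Y, TH, AV = _stacked(trial)

    bouts = []
    if mode == "directed":
        pairs = permutations(range(len(ids)), 2)
    else:
        pairs = combinations(range(len(ids)), 2)
    for i, j in pairs:
        ind = _directed_indicator(X, Y, TH, AV, i, j, max_dist_mm)
        if mode == "undirected":
            ind = ind | _directed_indicator(X, Y, TH, AV, j, i, max_dist_mm)
        for s, e in _runs(ind):
            if e - s >= need:
                bouts.append(
                    InteractionBout(ids[i], ids[j], int(s), int(e), (e - s) / fps)
                )
    return bouts


def social_summary(
    trial: TrialRecord,
    body_length_mm: float | None = None,
    min_bout_s: float = 1.5,
    max_dist_bl: float = 2.0,
    mode: str = "directed",
) -> SocialMetrics:
    """The four per-trial social metrics of a cleaned trial."""
    bouts = detect_bouts(trial, body_length_mm, min_bout_s, max_dist_bl, mode)
    inter, nn = distance_metrics(trial)
    return SocialMetrics(
        n_interactions=len(bouts),
        total_duration_s=float(sum(b.duration_s for b in bouts)),
        interindividual_mm=inter,
        nearest_neighbor_mm=nn,
    )


def bouts_table(trial_id: str, bouts: list[InteractionBout]) -> pd.DataFrame:
    """Tidy bout table for CSV export."""
    return pd.DataFrame(
        [
            {
                "trial_id": trial_id,
                "focal_id": b.focal_id,
                "partner_id": b.partner_id,
                "start_frame": b.start_frame,
                "end_frame": b.end_frame,
                "duration_s": b.duration_s,
            }
            for b in bouts
        ],
        columns=["trial_id", "focal_id", "partner_id", "start_frame", "end_frame", "duration_s"],
    )
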