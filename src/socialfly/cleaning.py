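"""Gap classification and interpolation for tracked fly trajectories.

Tracking drops frames when flies occlude each other or groom against walls.
Missing runs are handled by a three-tier policy applied per fly:

* short gaps (1-4 frames, < ~0.17 s at 30 fps): positions copied from the
  temporally nearest observed frame — displacement over such intervals is
  negligible;
* medium gaps (5-15 frames, ~0.17-0.5 s): positions filled by a local cubic
  spline, which keeps the path smooth and approximates natural motion;
* long gaps (>= 16 frames): masked out of analysis entirely; reconstructing
  half a second or more of path would invent behaviour.

Heading angles are always spline-interpolated (on the unwrapped series, so
that crossings of the -pi/pi seam do not produce spurious spins), except over
long gaps, which stay masked for consistency with positions.  Gaps touching
the start or end of a trajectory have one-sided support only and are always
masked, never extrapolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .io import (
    PROV_MASKED,
    PROV_NN,
    PROV_SPLINE,
    RawTrajectory,
    TrialRecord,
    wrap_angle,
)

logger = logging.getLogger(__name__)

SHORT_MAX = 4      # gap lengths 1..4 -> nearest-neighbor
MEDIUM_MAX = 15    # gap lengths 5..15 -> cubic spline; >= 16 -> masked
SUPPORT_FRAMES = 10  # valid frames used on each side of a spline-filled gap
MIN_SUPPORT = 2      # minimum valid frames required on each side


@dataclass(frozen=True)
class GapSegment:
    """A maximal run of missing frames, half-open [start_frame, end_frame)."""

    fly_id: int
    start_frame: int
    end_frame: int
    tier: str  # "short" | "medium" | "long"

    @property
    def length(self) -> int:
        return self.end_frame - self.start_frame


def classify_gap_length(length: int) -> str:
    if length <= 0:
        raise ValueError("gap length must be >= 1")
    if length <= SHORT_MAX:
        return "short"
    if length <= MEDIUM_MAX:
        return "medium"
    return "long"


def find_gaps(traj: RawTrajectory) -> list[GapSegment]:
    """Run-length encode the invalid frames of a trajectory into gap segments.

    Leading and trailing runs are always tier ``long`` (no two-sided support
    for interpolation), regardless of length.
    """
    invalid = ~traj.valid
    if not invalid.any():
        return []
    # boundaries of runs of True in `invalid`
    padded = np.concatenate([[False], invalid, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    gaps = []
    n = traj.n_frames
    for s, e in zip(starts, ends):
        if s == 0 or e == n:
            tier = "long"
        else:
            tier = classify_gap_length(e - s)
        gaps.append(GapSegment(traj.fly_id, int(s), int(e), tier))
    return gaps


def _nearest_valid_source(gap: GapSegment) -> np.ndarray:
    """Source frame index for each missing frame of a short gap.

    Ties (frame equidistant from both flanking observations) resolve to the
    earlier frame: deterministic and causal.
    """
    left, right = gap.start_frame - 1, gap.end_frame
    frames = np.arange(gap.start_frame, gap.end_frame)
    take_left = (frames - left) <= (right - frames)
    return np.where(take_left, left, right)


def _spline_support(valid: np.ndarray, gap: GapSegment) -> tuple[np.ndarray, bool]:
    """Indices of up to SUPPORT_FRAMES valid frames flanking a gap each side."""
    left = np.flatnonzero(valid[: gap.start_frame])[-SUPPORT_FRAMES:]
    right_rel = np.flatnonzero(valid[gap.end_frame:])[:SUPPORT_FRAMES]
    right = right_rel + gap.end_frame
    ok = len(left) >= MIN_SUPPORT and len(right) >= MIN_SUPPORT
    return np.concatenate([left, right]), ok


def fill_positions(traj: RawTrajectory, gaps: list[GapSegment] | None = None) -> RawTrajectory:
    """Apply the three-tier gap policy to the x/y channels.

    Returns a new trajectory whose observed frames are bit-identical to the
    input; each missing frame is nearest-neighbor filled, spline filled, or
    masked according to its gap's tier, recorded in ``provenance``.
    """
    if gaps is None:
        gaps = find_gaps(traj)
    out = traj.copy()
    out.analysis_valid = traj.valid.copy()
    out.provenance = np.where(traj.valid, "observed", PROV_MASKED).astype(object)
    for gap in gaps:
        sl = slice(gap.start_frame, gap.end_frame)
        if gap.tier == "short":
            src = _nearest_valid_source(gap)
            out.x_mm[sl] = traj.x_mm[src]
            out.y_mm[sl] = traj.y_mm[src]
            out.provenance[sl] = PROV_NN
            out.analysis_valid[sl] = True
        elif gap.tier == "medium":
            support, ok = _spline_support(traj.valid, gap)
            if not ok:
                logger.warning(
                    "fly %s gap [%d,%d): insufficient spline support, masking",
                    gap.fly_id, gap.start_frame, gap.end_frame,
                )
                out.analysis_valid[sl] = False
                out.provenance[sl] = PROV_MASKED
                continue
            frames = np.arange(gap.start_frame, gap.end_frame)
            for chan in ("x_mm", "y_mm"):
                vals = getattr(traj, chan)
                cs = CubicSpline(support, vals[support], bc_type="not-a-knot")
                getattr(out, chan)[sl] = cs(frames)
            out.provenance[sl] = PROV_SPLINE
            out.analysis_valid[sl] = True
        else:  # long
            out.analysis_valid[sl] = False
            out.provenance[sl] = PROV_MASKED
            out.x_mm[sl] = np.nan
            out.y_mm[sl] = np.nan
    return out


def fill_angles(
    traj: RawTrajectory,
    gaps: list[GapSegment] | None = None,
    out: RawTrajectory | None = None,
    mask_long: bool = True,
) -> RawTrajectory:
    """Spline-fill the heading channel over short and medium gaps.

    Observed angles are unwrapped to a continuous series before fitting, and
    filled values rewrapped to [-pi, pi); without unwrapping, a crossing of
    the angular seam would interpolate the long way around through 0.  Long
    gaps are masked (``mask_long=False`` splines across them instead, for
    users who want headings continuous regardless of the position policy).
    """
    if gaps is None:
        gaps = find_gaps(traj)
    if out is None:
        out = traj.copy()
    valid_idx = np.flatnonzero(traj.valid)
    unwrapped = np.full(traj.n_frames, np.nan)
    unwrapped[valid_idx] = np.unwrap(traj.theta_rad[valid_idx])
    for gap in gaps:
        sl = slice(gap.start_frame, gap.end_frame)
        boundary = gap.start_frame == 0 or gap.end_frame == traj.n_frames
        if boundary or (gap.tier == "long" and mask_long):
            out.theta_rad[sl] = np.nan
            continue
        support, ok = _spline_support(traj.valid, gap)
        if not ok:
            out.theta_rad[sl] = np.nan
            continue
        frames = np.arange(gap.start_frame, gap.end_frame)
        cs = CubicSpline(support, unwrapped[support], bc_type="not-a-knot")
        out.theta_rad[sl] = wrap_angle(cs(frames))
    return out


def clean_trajectory(traj: RawTrajectory, mask_long_angles: bool = True) -> RawTrajectory:
    """Full per-fly cleaning: gap tiers, position policy, angle splines."""
    gaps = find_gaps(traj)
    out = fill_positions(traj, gaps)
    out = fill_angles(traj, gaps, out=out, mask_long=mask_long_angles)
    # a frame is analysable only if both channels ended up defined
    out.analysis_valid &= ~np.isnan(out.theta_rad)
    return out


def clean_trial(trial: TrialRecord, mask_long_angles: bool = True) -> TrialRecord:
    """Clean every trajectory of a retained trial; logs gap counts per tier."""
    cleaned = trial.copy()
    cleaned.trajectories = []
    for traj in trial.trajectories:
        gaps = find_gaps(traj)
        tally = {"short": 0, "medium": 0, "long": 0}
        for g in gaps:
            tally[g.tier] += 1
        logger.info(
            "trial %s fly %s: %d short, %d medium, %d long gaps",
            trial.trial_id, traj.fly_id, tally["short"], tally["medium"], tally["long"],
        )
        cleaned.trajectories.append(clean_trajectory(traj, mask_long_angles))
    return cleaned


def gap_audit(trial: TrialRecord) -> list[GapSegment]:
    """All gap segments of a trial, for the gap-audit CSV export."""
    segs: list[GapSegment] = []
    for traj in trial.trajectories:
        segs.extend(find_gaps(traj))
    return segs
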