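import numpy as np
import pytest

from socialfly import ArenaSpec, RawTrajectory, TrialRecord


@pytest.fixture
def arena():
    return ArenaSpec()


def make_trajectory(fly_id, x, y, theta=None, valid=None):
    """Build a RawTrajectory from plain sequences; defaults: heading 0, all valid."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    theta = np.zeros_like(x) if theta is None else np.asarray(theta, dtype=float)
    valid = np.ones(len(x), dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
    x = np.where(valid, x, np.nan)
    y = np.where(valid, y, np.nan)
    theta = np.where(valid, theta, np.nan)
    return RawTrajectory(fly_id, x, y, theta, valid)


def make_trial(trajectories, arena=None, fps=30.0, trial_id="t0", line_id="lineA"):
    arena = arena or ArenaSpec(fps=fps, group_size=len(trajectories))
    return TrialRecord(
        trial_id=trial_id,
        line_id=line_id,
        trajectories=trajectories,
        arena=arena,
        n_frames_total=trajectories[0].n_frames,
    )


def static_trial(positions, headings=None, n_frames=100, fps=30.0):
    """Trial with every fly parked at a fixed position/heading."""
    trajs = []
    for i, (px, py) in enumerate(positions):
        th = None if headings is None else np.full(n_frames, headings[i])
        trajs.append(
            make_trajectory(i, np.full(n_frames, px), np.full(n_frames, py), th)
        )
    return make_trial(trajs, fps=fps)
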