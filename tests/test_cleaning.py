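"""Gap classification and the three-tier interpolation policy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import socialfly as sf
from socialfly.io import PROV_MASKED, PROV_NN, PROV_SPLINE

from conftest import make_trajectory
from oracles import oracle_unwrap


def gappy_trajectory(n, gaps, x=None, y=None, theta=None):
    """All-valid trajectory with the given (start, length) runs knocked out."""
    valid = np.ones(n, dtype=bool)
    for start, length in gaps:
        valid[start : start + length] = False
    x = np.arange(n, dtype=float) * 0.1 if x is None else x
    y = np.full(n, 5.0) if y is None else y
    return make_trajectory(0, x, y, theta, valid)


class TestFindGaps:
    def test_no_gaps(self):
        assert sf.find_gaps(gappy_trajectory(50, [])) == []

    @pytest.mark.parametrize(
        "length,tier",
        [(1, "short"), (4, "short"), (5, "medium"), (15, "medium"), (16, "long"), (30, "long")],
    )
    def test_tier_boundaries(self, length, tier):
        (gap,) = sf.find_gaps(gappy_trajectory(100, [(20, length)]))
        assert (gap.start_frame, gap.end_frame, gap.tier) == (20, 20 + length, tier)

    def test_interior_run_located_exactly(self):
        (gap,) = sf.find_gaps(gappy_trajectory(50, [(10, 3)]))
        assert (gap.start_frame, gap.end_frame, gap.length) == (10, 13, 3)

    @pytest.mark.parametrize("gaps", [[(0, 2)], [(47, 3)]])
    def test_boundary_runs_always_long(self, gaps):
        (gap,) = sf.find_gaps(gappy_trajectory(50, gaps))
        assert gap.tier == "long"

    @given(st.lists(st.tuples(st.integers(1, 180), st.integers(1, 20)), max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_gaps_partition_the_invalid_set(self, raw_gaps):
        """Every invalid frame lies in exactly one reported segment."""
        traj = gappy_trajectory(200, raw_gaps)
        gaps = sf.find_gaps(traj)
        covered = np.zeros(200, dtype=int)
        for g in gaps:
            covered[g.start_frame : g.end_frame] += 1
        np.testing.assert_array_equal(covered, (~traj.valid).astype(int))


class TestFillPositions:
    def test_short_gap_copies_nearest_constant(self):
        traj = gappy_trajectory(30, [(10, 3)], x=np.full(30, 3.0), y=np.full(30, 4.0))
        out = sf.fill_positions(traj)
        assert (out.x_mm[10:13] == 3.0).all() and (out.y_mm[10:13] == 4.0).all()
        assert (out.provenance[10:13] == PROV_NN).all()
        assert out.analysis_valid[10:13].all()

    def test_short_gap_tie_takes_earlier_frame(self):
        # 4-frame gap at 10..13: frames 10,11 copy frame 9; 12,13 copy frame 14.
        # frame 11 is equidistant (2 frames from 9 and from 14) -> earlier wins.
        x = np.arange(30, dtype=float)
        traj = gappy_trajectory(30, [(10, 4)], x=x, y=np.zeros(30))
        out = sf.fill_positions(traj)
        np.testing.assert_array_equal(out.x_mm[10:14], [9.0, 9.0, 14.0, 14.0])

    def test_medium_gap_reproduces_cubic_polynomial(self):
        t = np.arange(61, dtype=float)
        x = 0.001 * t**3
        y = 0.002 * t**3 - 0.05 * t
        traj = gappy_trajectory(61, [(20, 10)], x=x.copy(), y=y.copy())
        out = sf.fill_positions(traj)
        np.testing.assert_allclose(out.x_mm[20:30], x[20:30], atol=1e-6)
        np.testing.assert_allclose(out.y_mm[20:30], y[20:30], atol=1e-6)
        assert (out.provenance[20:30] == PROV_SPLINE).all()

    def test_long_gap_masked(self):
        traj = gappy_trajectory(100, [(30, 20)])
        out = sf.fill_positions(traj)
        assert not out.analysis_valid[30:50].any()
        assert (out.provenance[30:50] == PROV_MASKED).all()
        assert np.isnan(out.x_mm[30:50]).all()

    def test_medium_gap_without_support_demoted_to_masked(self, caplog):
        # only one valid frame to the left of the gap
        valid = np.ones(40, dtype=bool)
        valid[0:9] = False   # long boundary run
        valid[10:20] = False  # medium gap with single support frame 9
        traj = make_trajectory(0, np.arange(40.0), np.zeros(40), valid=valid)
        out = sf.fill_positions(traj)
        assert not out.analysis_valid[10:20].any()

    def test_observed_frames_bit_identical(self):
        rng = np.random.default_rng(0)
        traj = gappy_trajectory(
            100, [(10, 3), (40, 8), (70, 20)],
            x=rng.uniform(0, 66, 100), y=rng.uniform(0, 30, 100),
        )
        out = sf.fill_positions(traj)
        obs = traj.valid
        np.testing.assert_array_equal(out.x_mm[obs], traj.x_mm[obs])
        np.testing.assert_array_equal(out.y_mm[obs], traj.y_mm[obs])


class TestFillAngles:
    def test_constant_heading_preserved(self):
        th = np.full(30, np.pi / 2)
        traj = gappy_trajectory(30, [(10, 3)], theta=th)
        out = sf.fill_angles(traj)
        np.testing.assert_allclose(out.theta_rad[10:13], np.pi / 2, atol=1e-9)

    def test_linear_rotation_continued_through_gap(self):
        n = 60
        th = sf.io.wrap_angle(0.05 * np.arange(n))
        traj = gappy_trajectory(n, [(25, 8)], theta=th)
        out = sf.fill_angles(traj)
        expect = sf.io.wrap_angle(0.05 * np.arange(25, 33))
        np.testing.assert_allclose(out.theta_rad[25:33], expect, atol=1e-6)

    def test_wrap_crossing_interpolates_through_pi(self):
        """A jump +3.1 -> -3.1 rad must pass near the seam, not through 0."""
        n = 20
        th = np.concatenate([np.full(9, 3.1), np.full(11, -3.1)])
        traj = gappy_trajectory(n, [(9, 2)], theta=th)
        out = sf.fill_angles(traj)
        assert np.all(np.abs(out.theta_rad[9:11]) > 3.0)
        # the brute-force unwrap oracle agrees the short way is through the seam
        unwrapped = oracle_unwrap(list(th[traj.valid]))
        assert unwrapped[-1] > 3.0  # continues upward past pi

    def test_filled_angles_stay_in_canonical_interval(self):
        rng = np.random.default_rng(3)
        th = sf.io.wrap_angle(np.cumsum(rng.normal(0, 0.4, 80)))
        traj = gappy_trajectory(80, [(20, 4), (50, 10)], theta=th)
        out = sf.fill_angles(traj)
        filled = ~traj.valid
        assert np.all(out.theta_rad[filled] >= -np.pi)
        assert np.all(out.theta_rad[filled] < np.pi)


class TestCleanTrial:
    def _random_gappy_trial(self, seed):
        rng = np.random.default_rng(seed)
        spec = sf.SyntheticTrialSpec(
            seed=int(rng.integers(2**31)), duration_s=30,
            gap_counts={"short": 2, "medium": 2, "long": 1},
        )
        return sf.simulate_group_trial(spec)

    def test_gapless_trial_unchanged(self):
        spec = sf.SyntheticTrialSpec(seed=5, duration_s=10)
        trial, _ = sf.simulate_group_trial(spec)
        out = sf.clean_trial(trial)
        for a, b in zip(trial.trajectories, out.trajectories):
            np.testing.assert_array_equal(a.x_mm, b.x_mm)
            np.testing.assert_array_equal(a.theta_rad, b.theta_rad)
            assert (b.provenance == "observed").all()

    def test_provenance_matches_injected_tiers(self):
        trial, gt = self._random_gappy_trial(11)
        cleaned = sf.clean_trial(trial)
        tier_to_prov = {"short": PROV_NN, "medium": PROV_SPLINE, "long": PROV_MASKED}
        for fly, start, end, tier in gt.gap_segments:
            prov = cleaned.trajectories[fly].provenance[start:end]
            assert (prov == tier_to_prov[tier]).all(), (fly, start, end, tier)

    def test_idempotent(self):
        trial, _ = self._random_gappy_trial(13)
        once = sf.clean_trial(trial)
        twice = sf.clean_trial(once)
        for a, b in zip(once.trajectories, twice.trajectories):
            np.testing.assert_array_equal(a.x_mm, b.x_mm)
            np.testing.assert_array_equal(a.y_mm, b.y_mm)
            np.testing.assert_array_equal(a.theta_rad, b.theta_rad)
            np.testing.assert_array_equal(a.analysis_valid, b.analysis_valid)
            np.testing.assert_array_equal(a.provenance, b.provenance)

    def test_gap_audit_lists_all_segments(self):
        trial, gt = self._random_gappy_trial(17)
        audit = {(g.fly_id, g.start_frame, g.end_frame, g.tier) for g in sf.gap_audit(trial)}
        assert audit == set(gt.gap_segments)
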