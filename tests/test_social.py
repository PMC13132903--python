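"""Interaction-bout detection and the four group social metrics."""

import math

import numpy as np
import pytest

import socialfly as sf
from socialfly.errors import UndefinedMetricError
from socialfly.social import min_bout_frames

from conftest import make_trajectory, make_trial, static_trial
from oracles import oracle_bouts, oracle_distance_metrics


def face_to_face_trial(n_frames=600, fps=30.0, separation_mm=2.5):
    """Two flies parked facing each other, criteria saturated every frame."""
    return static_trial(
        [(10.0, 15.0), (10.0 + separation_mm, 15.0)],
        headings=[0.0, -np.pi],
        n_frames=n_frames,
        fps=fps,
    )


class TestFacing:
    @pytest.mark.parametrize(
        "theta,px,py,expect",
        [
            (0.0, 11.0, 10.0, True),    # directly ahead
            (0.0, 10.0, 11.0, False),   # exactly perpendicular: strict < 90
            (0.0, 9.0, 10.0, False),    # directly behind
            (np.pi / 2, 10.0, 11.0, True),
            (0.0, 10.0, 10.0, True),    # coincident centroids
        ],
    )
    def test_half_plane_rule(self, theta, px, py, expect):
        assert sf.facing(10.0, 10.0, theta, px, py) is expect


class TestDistances:
    def test_three_four_five(self):
        trial = static_trial([(0.0, 0.0), (3.0, 4.0)])
        d = sf.frame_pair_distances(trial, 0)
        assert d["distance_mm"].tolist() == [5.0]

    def test_coincident_flies_zero(self):
        trial = static_trial([(5.0, 5.0)] * 4)
        d = sf.frame_pair_distances(trial, 0)
        assert (d["distance_mm"] == 0).all() and len(d) == 6

    def test_masked_fly_drops_its_pairs(self):
        trajs = [
            make_trajectory(i, np.full(10, float(i)), np.zeros(10)) for i in range(4)
        ]
        trajs[3].analysis_valid[:] = False
        trial = make_trial(trajs)
        assert len(sf.frame_pair_distances(trial, 0)) == 3

    def test_static_square_hand_geometry(self):
        """Corners of a 10 mm square: NN 10, interindividual (4*10+2*10*sqrt2)/6."""
        trial = static_trial([(5, 5), (15, 5), (5, 15), (15, 15)])
        inter, nn = sf.distance_metrics(trial)
        assert nn == pytest.approx(10.0)
        assert inter == pytest.approx((4 * 10 + 2 * 10 * math.sqrt(2)) / 6)

    def test_two_flies_nn_equals_interindividual(self):
        trial = static_trial([(0.0, 0.0), (7.0, 3.0)])
        inter, nn = sf.distance_metrics(trial)
        assert inter == pytest.approx(nn)

    def test_matches_brute_force_on_random_trial(self):
        trial, _ = sf.simulate_group_trial(
            sf.SyntheticTrialSpec(seed=23, duration_s=20, gap_counts={"long": 1})
        )
        cleaned = sf.clean_trial(trial)
        inter, nn = sf.distance_metrics(cleaned)
        o_inter, o_nn = oracle_distance_metrics(cleaned)
        assert inter == pytest.approx(o_inter, abs=1e-12)
        assert nn == pytest.approx(o_nn, abs=1e-12)

    def test_all_frames_single_fly_is_undefined(self):
        trajs = [make_trajectory(i, np.zeros(5), np.zeros(5)) for i in range(4)]
        for t in trajs[1:]:
            t.analysis_valid[:] = False
        with pytest.raises(UndefinedMetricError):
            sf.distance_metrics(make_trial(trajs))


class TestDetectBouts:
    def test_saturated_pair_two_directed_bouts(self):
        trial = face_to_face_trial(n_frames=18000)
        bouts = sf.detect_bouts(trial)
        assert len(bouts) == 2
        assert {(b.focal_id, b.partner_id) for b in bouts} == {(0, 1), (1, 0)}
        assert all(b.duration_s == pytest.approx(600.0) for b in bouts)

    def test_undirected_mode_merges_mutual_pair(self):
        trial = face_to_face_trial(n_frames=600)
        bouts = sf.detect_bouts(trial, mode="undirected")
        assert len(bouts) == 1

    @pytest.mark.parametrize("n_true,expected", [(44, 0), (45, 1)])
    def test_persistence_boundary_at_45_frames(self, n_true, expected):
        n = 200
        x0 = np.full(n, 10.0)
        x1 = np.full(n, 40.0)          # far apart by default
        x1[:n_true] = 12.5             # within 1 body length while the window lasts
        trial = make_trial(
            [
                make_trajectory(0, x0, np.full(n, 15.0), np.zeros(n)),
                make_trajectory(1, x1, np.full(n, 15.0), np.full(n, np.pi - 1e-9)),
            ],
            fps=30.0,
        )
        bouts = [b for b in sf.detect_bouts(trial) if b.focal_id == 0]
        assert len(bouts) == expected
        if expected:
            assert bouts[0].duration_s == pytest.approx(1.5)

    def test_masked_frame_breaks_a_run(self):
        trial = face_to_face_trial(n_frames=120)
        trial.trajectories[0].analysis_valid[60] = False
        bouts = sf.detect_bouts(trial)
        # two 60- and 59-frame halves: both >= 45 frames -> 2 bouts per direction
        assert len(bouts) == 4
        assert all(b.end_frame <= 60 or b.start_frame >= 61 for b in bouts)

    def test_max_dist_widening_grows_indicator(self):
        """Pre-persistence criterion-true time is monotone in the distance cap."""
        trial, _ = sf.simulate_group_trial(sf.SyntheticTrialSpec(seed=31, duration_s=30))
        fps = trial.arena.fps
        totals = []
        for cap in (1.0, 2.0, 4.0):
            bouts = sf.detect_bouts(trial, min_bout_s=1.0 / fps, max_dist_bl=cap)
            totals.append(sum(b.end_frame - b.start_frame for b in bouts))
        assert totals == sorted(totals)

    def test_rigid_motion_leaves_metrics_unchanged(self):
        trial, _ = sf.simulate_group_trial(
            sf.SyntheticTrialSpec(seed=37, duration_s=30, encounters=[
                sf.EncounterSpec((0, 1), 5.0, 3.0),
            ])
        )
        cleaned = sf.clean_trial(trial)
        base = sf.social_summary(cleaned)
        ang, tx, ty = 0.7, 11.0, -3.0
        moved = cleaned.copy()
        for t in moved.trajectories:
            x = t.x_mm * np.cos(ang) - t.y_mm * np.sin(ang) + tx
            y = t.x_mm * np.sin(ang) + t.y_mm * np.cos(ang) + ty
            t.x_mm, t.y_mm = x, y
            t.theta_rad = sf.io.wrap_angle(t.theta_rad + ang)
        after = sf.social_summary(moved)
        assert after.n_interactions == base.n_interactions
        assert after.total_duration_s == pytest.approx(base.total_duration_s)
        assert after.interindividual_mm == pytest.approx(base.interindividual_mm)
        assert after.nearest_neighbor_mm == pytest.approx(base.nearest_neighbor_mm)

    @pytest.mark.parametrize("seed", range(12))
    def test_oracle_equivalence_random_trials(self, seed):
        trial, _ = sf.simulate_group_trial(
            sf.SyntheticTrialSpec(
                seed=seed, duration_s=30,
                encounters=[sf.EncounterSpec((seed % 4, (seed + 1) % 4), 10.0, 2.0)],
                gap_counts={"short": 1, "medium": 1, "long": 1},
            )
        )
        cleaned = sf.clean_trial(trial)
        got = sorted(
            (b.focal_id, b.partner_id, b.start_frame, b.end_frame)
            for b in sf.detect_bouts(cleaned)
        )
        assert got == oracle_bouts(cleaned, cleaned.arena.body_length_mm)

    def test_frame_rate_consistency(self):
        """The same continuous episode scores the same duration at 30 and 60 fps."""
        durations = {}
        for fps in (30.0, 60.0):
            trial = face_to_face_trial(n_frames=int(7.3 * fps), fps=fps)
            (b0, _) = sf.detect_bouts(trial)
            durations[fps] = b0.duration_s
        assert abs(durations[30.0] - durations[60.0]) < 1.0 / 30.0


class TestSocialSummary:
    def test_distant_flies_score_zero(self):
        trial = static_trial([(5, 5), (25, 5), (45, 5), (60, 25)])
        m = sf.social_summary(trial)
        assert m.n_interactions == 0 and m.total_duration_s == 0.0

    def test_saturated_pair_totals(self):
        m = sf.social_summary(face_to_face_trial(n_frames=18000))
        assert m.n_interactions == 2
        assert m.total_duration_s == pytest.approx(1200.0)

    def test_min_bout_frames_at_30fps(self):
        assert min_bout_frames(1.5, 30.0) == 45
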