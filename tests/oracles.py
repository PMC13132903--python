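"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written with plain loops and scalar math, deliberately
sharing no code path with the vectorized implementations it checks.
"""

from __future__ import annotations

import math

from scipy import stats as _st


def oracle_bouts(trial, body_length_mm, min_bout_s=1.5, max_dist_bl=2.0):
    """Per-frame re-evaluation of all three interaction criteria.

    Returns directed bouts as (focal_id, partner_id, start, end) tuples.
    """
    fps = trial.arena.fps
    need = math.ceil(min_bout_s * fps)
    max_d = max_dist_bl * body_length_mm
    n = trial.n_frames_total
    flies = []
    for t in trial.trajectories:
        flies.append(
            (t.fly_id, t.x_mm.tolist(), t.y_mm.tolist(), t.theta_rad.tolist(),
             t.analysis_valid.tolist())
        )
    bouts = []
    for fid, fx, fy, fth, fav in flies:
        for pid, px, py, _, pav in flies:
            if fid == pid:
                continue
            run_start = None
            for k in range(n + 1):
                ok = False
                if k < n and fav[k] and pav[k]:
                    dx = px[k] - fx[k]
                    dy = py[k] - fy[k]
                    d = math.hypot(dx, dy)
                    if d <= max_d:
                        if d == 0.0:
                            ok = True
                        else:
                            ok = math.cos(fth[k]) * dx + math.sin(fth[k]) * dy > 0
                if ok and run_start is None:
                    run_start = k
                elif not ok and run_start is not None:
                    if k - run_start >= need:
                        bouts.append((fid, pid, run_start, k))
                    run_start = None
    return sorted(bouts)


def oracle_distance_metrics(trial):
    """Frame-by-frame recomputation of both group distance metrics."""
    n = trial.n_frames_total
    trajs = trial.trajectories
    frame_pair_means = []
    frame_nn_means = []
    for k in range(n):
        present = [t for t in trajs if t.analysis_valid[k]]
        if len(present) < 2:
            continue
        dists = {}
        for a in range(len(present)):
            for b in range(a + 1, len(present)):
                d = math.hypot(
                    present[a].x_mm[k] - present[b].x_mm[k],
                    present[a].y_mm[k] - present[b].y_mm[k],
                )
                dists[(a, b)] = d
        frame_pair_means.append(sum(dists.values()) / len(dists))
        nns = []
        for a in range(len(present)):
            nns.append(min(d for (i, j), d in dists.items() if a in (i, j)))
        frame_nn_means.append(sum(nns) / len(nns))
    inter = sum(frame_pair_means) / len(frame_pair_means)
    nn = sum(frame_nn_means) / len(frame_nn_means)
    return inter, nn


def oracle_speed(trial):
    """Displacement-sum recomputation of group mean walking speed (cm/s)."""
    per_fly = []
    for t in trial.trajectories:
        steps = []
        for k in range(trial.n_frames_total - 1):
            if t.analysis_valid[k] and t.analysis_valid[k + 1]:
                steps.append(
                    math.hypot(t.x_mm[k + 1] - t.x_mm[k], t.y_mm[k + 1] - t.y_mm[k])
                )
        if steps:
            per_fly.append(sum(steps) / len(steps) * trial.arena.fps / 10.0)
    return sum(per_fly) / len(per_fly)


def oracle_regression(x, y):
    """Normal-equations least squares on hand-z-scored inputs.

    Returns (slope, slope_se, F, p, r_squared).
    """
    n = len(x)

    def z(v):
        m = sum(v) / n
        sd = math.sqrt(sum((a - m) ** 2 for a in v) / (n - 1))
        return [(a - m) / sd for a in v]

    zx, zy = z(list(x)), z(list(y))
    sxx = sum(a * a for a in zx) - sum(zx) ** 2 / n
    sxy = sum(a * b for a, b in zip(zx, zy)) - sum(zx) * sum(zy) / n
    slope = sxy / sxx
    intercept = (sum(zy) - slope * sum(zx)) / n
    sse = sum((b - intercept - slope * a) ** 2 for a, b in zip(zx, zy))
    se = math.sqrt(sse / (n - 2) / sxx)
    F = (slope / se) ** 2
    p = float(_st.f.sf(F, 1, n - 2))
    syy = sum(b * b for b in zy) - sum(zy) ** 2 / n
    r2 = 1.0 - sse / syy
    return slope, se, F, p, r2


def oracle_unwrap(angles):
    """Cumulative shortest-arc unwrapping of a wrapped angle sequence."""
    out = [angles[0]]
    for a in angles[1:]:
        prev = out[-1]
        d = (a - prev + math.pi) % (2 * math.pi) - math.pi
        out.append(prev + d)
    return out


def attenuated_correlation(rho, line_sd_x, resid_sd_x, line_sd_y, resid_sd_y, n_reps):
    """Expected between-line correlation of replicate means under noise.

    Each trait's line means carry variance sigma_L^2 + sigma_e^2/n, so the
    latent correlation rho is shrunk by the geometric mean of the two
    reliability factors sigma_L^2 / (sigma_L^2 + sigma_e^2 / n).
    """

    def lam(sl, se):
        return sl**2 / (sl**2 + se**2 / n_reps)

    return rho * math.sqrt(lam(line_sd_x, resid_sd_x) * lam(line_sd_y, resid_sd_y))
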