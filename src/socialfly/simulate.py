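"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the three assays' data-generating processes:

* group-arena trials: bounded correlated random walks for each fly
  (reflecting walls via coordinate folding), with choreographed interaction
  episodes in which a pair is held at a stated separation with headings
  toward each other, and missing-data gaps injected in all three length
  tiers;
* egg-count series: a latent latency (line effect + residual noise) followed
  by Poisson egg deposition, sampled on the 15-minute grid;
* genotype panels: per-line latent trait vectors drawn from a multivariate
  normal with a configurable cross-trait correlation matrix, plus replicate
  residual noise — the ground truth for correlation-recovery tests.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ArenaSpec, PhotoperiodSpec
from .errors import SpecError
from .io import EggCountSeries, PreferenceTrial, RawTrajectory, TrialRecord
from .social import InteractionBout, min_bout_frames

_WALL_MARGIN_MM = 2.0


@dataclass(frozen=True)
class MotionSpec:
    """Correlated-random-walk parameters.

    ``step_mm`` is the mean per-frame step length (0.5 mm/frame at 30 fps is
    ~1.5 cm/s, ordinary fly walking speed); ``persistence`` in [0, 1] sets
    heading autocorrelation (turn SD = (1 - persistence) * pi rad/frame).
    ``tether_box_mm``, when set, folds each fly's walk into a box of that
    half-width around a per-fly home point spread along the arena, which
    guarantees wide spacing between non-choreographed flies.
    """

    step_mm: float = 0.5
    persistence: float = 0.9
    tether_box_mm: float | None = None

    def __post_init__(self):
        if self.step_mm < 0 or not (0 <= self.persistence <= 1):
            raise SpecError("step_mm >= 0 and persistence in [0,1] required")


@dataclass(frozen=True)
class EncounterSpec:
    """A scripted interaction episode between one pair of flies."""

    pair: tuple[int, int]          # fly indices
    start_s: float
    duration_s: float
    separation_bl: float = 1.0     # centroid separation in body lengths
    mutual: bool = True            # both facing, or focal (pair[0]) only

    def __post_init__(self):
        if self.pair[0] == self.pair[1]:
            raise SpecError("encounter pair must be two distinct flies")
        if self.separation_bl <= 0:
            raise SpecError("separation must be positive")
        if self.start_s < 0 or self.duration_s <= 0:
            raise SpecError("encounter times must be non-negative/positive")


@dataclass
class SyntheticTrialSpec:
    seed: int = 0
    n_flies: int = 4
    duration_s: float = 600.0
    fps: float = 30.0
    arena: ArenaSpec = field(default_factory=ArenaSpec)
    motion: MotionSpec = field(default_factory=MotionSpec)
    encounters: list[EncounterSpec] = field(default_factory=list)
    # explicit gaps: (fly_index, start_frame, length); or per-tier counts per fly
    gap_plan: list[tuple[int, int, int]] = field(default_factory=list)
    gap_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass
class TrialGroundTruth:
    """What the generator knows that the pipeline must recover."""

    clean_trial: TrialRecord                       # before gap injection
    scripted_bouts: list[InteractionBout]          # from the choreography alone
    gap_segments: list[tuple[int, int, int, str]]  # (fly, start, end, tier)


def _fold(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect coordinates into [lo, hi] (triangle-wave folding)."""
    span = hi - lo
    return lo + np.abs(((v - lo) % (2 * span)) - span)


def _crw(rng, n_frames, x0, y0, motion: MotionSpec, arena: ArenaSpec):
    turn_sd = (1.0 - motion.persistence) * np.pi
    theta = rng.uniform(-np.pi, np.pi) + np.cumsum(rng.normal(0, turn_sd, n_frames))
    steps = rng.exponential(motion.step_mm, n_frames) if motion.step_mm > 0 else np.zeros(n_frames)
    x = x0 + np.cumsum(steps * np.cos(theta))
    y = y0 + np.cumsum(steps * np.sin(theta))
    if motion.tether_box_mm is not None:
        b = motion.tether_box_mm
        x = _fold(x, max(x0 - b, _WALL_MARGIN_MM), min(x0 + b, arena.length_mm - _WALL_MARGIN_MM))
        y = _fold(y, max(y0 - b, _WALL_MARGIN_MM), min(y0 + b, arena.width_mm - _WALL_MARGIN_MM))
    else:
        x = _fold(x, _WALL_MARGIN_MM, arena.length_mm - _WALL_MARGIN_MM)
        y = _fold(y, _WALL_MARGIN_MM, arena.width_mm - _WALL_MARGIN_MM)
    wrapped = (theta + np.pi) % (2 * np.pi) - np.pi
    return x, y, wrapped


def _home_points(n_flies: int, arena: ArenaSpec) -> list[tuple[float, float]]:
    xs = np.linspace(0, arena.length_mm, n_flies + 2)[1:-1]
    return [(float(x), arena.width_mm / 2.0) for x in xs]


def simulate_group_trial(spec: SyntheticTrialSpec) -> tuple[TrialRecord, TrialGroundTruth]:
    """One synthetic group trial plus its ground truth.

    Flies follow bounded correlated random walks; during each scripted
    encounter the pair is parked at the stated separation with headings
    toward each other (mutual) or focal-only.  Gaps are then injected by
    deleting frames.  The returned TrialRecord carries the gaps; the ground
    truth carries the pre-gap trial, the bout list implied by the
    choreography, and the injected gap tiers.
    """
    rng = np.random.default_rng(spec.seed)
    arena = spec.arena
    n = spec.n_frames
    if spec.n_flies != arena.group_size:
        arena = ArenaSpec(
            length_mm=arena.length_mm, width_mm=arena.width_mm, fps=spec.fps,
            mm_per_px=arena.mm_per_px, group_size=spec.n_flies,
            body_length_mm=arena.body_length_mm,
        )
    homes = _home_points(spec.n_flies, arena)
    X = np.empty((spec.n_flies, n))
    Y = np.empty((spec.n_flies, n))
    TH = np.empty((spec.n_flies, n))
    for i, (hx, hy) in enumerate(homes):
        X[i], Y[i], TH[i] = _crw(rng, n, hx, hy, spec.motion, arena)

    # --- choreographed encounters -----------------------------------------
    windows: dict[int, list[tuple[int, int]]] = {}
    scripted: list[InteractionBout] = []
    need = min_bout_frames(1.5, spec.fps)
    for enc in spec.encounters:
        s = int(round(enc.start_s * spec.fps))
        e = s + int(round(enc.duration_s * spec.fps))
        if e > n:
            raise SpecError(f"encounter {enc} extends past trial end")
        for fly in enc.pair:
            if fly >= spec.n_flies:
                raise SpecError(f"encounter names fly {fly}, trial has {spec.n_flies}")
            for ws, we in windows.get(fly, []):
                if s < we and ws < e:
                    raise SpecError(f"fly {fly} double-booked in overlapping encounters")
            windows.setdefault(fly, []).append((s, e))
        i, j = enc.pair
        sep = enc.separation_bl * arena.body_length_mm
        # anchor at the focal fly's position so the parked pair stays inside
        # its own range and clear of other flies' home ranges
        ax = float(np.clip(X[i, s], _WALL_MARGIN_MM,
                           arena.length_mm - sep - _WALL_MARGIN_MM))
        ay = float(np.clip(Y[i, s], _WALL_MARGIN_MM, arena.width_mm - _WALL_MARGIN_MM))
        X[i, s:e], Y[i, s:e], TH[i, s:e] = ax, ay, 0.0                    # facing +x, toward j
        X[j, s:e], Y[j, s:e] = ax + sep, ay
        TH[j, s:e] = -np.pi if enc.mutual else 0.0                        # toward i, or away
        if e - s >= need:
            dur = (e - s) / spec.fps
            scripted.append(InteractionBout(i, j, s, e, dur))
            if enc.mutual:
                scripted.append(InteractionBout(j, i, s, e, dur))

    all_valid = np.ones(n, dtype=bool)
    clean = TrialRecord(
        trial_id=f"sim{spec.seed}",
        line_id="synthetic",
        trajectories=[
            RawTrajectory(i, X[i].copy(), Y[i].copy(), TH[i].copy(), all_valid.copy())
            for i in range(spec.n_flies)
        ],
        arena=arena,
        n_frames_total=n,
    )

    # --- gap injection ----------------------------------------------------
    plan = list(spec.gap_plan)
    if spec.gap_counts:
        plan.extend(_sample_gap_plan(rng, spec.n_flies, n, spec.gap_counts, plan))
    gap_segments = []
    gappy = clean.copy()
    for fly, start, length in plan:
        if not (1 <= start and start + length <= n - 1):
            raise SpecError(f"gap ({fly},{start},{length}) touches the trial boundary")
        tier = "short" if length <= 4 else ("medium" if length <= 15 else "long")
        t = gappy.trajectories[fly]
        t.valid[start:start + length] = False
        t.x_mm[start:start + length] = np.nan
        t.y_mm[start:start + length] = np.nan
        t.theta_rad[start:start + length] = np.nan
        gap_segments.append((fly, start, start + length, tier))
    for t in gappy.trajectories:
        t.analysis_valid = t.valid.copy()
        t.provenance = np.where(t.valid, "observed", "masked").astype(object)
    return gappy, TrialGroundTruth(clean, scripted, gap_segments)


_TIER_RANGES = {"short": (1, 4), "medium": (5, 15), "long": (16, 40)}


def _sample_gap_plan(rng, n_flies, n_frames, counts, existing):
    """Random non-overlapping, non-adjacent interior gaps per fly per tier.

    Gaps must be separated by at least one valid frame or they would merge
    into a single longer gap and change tier.
    """
    occupied = {i: [] for i in range(n_flies)}
    for fly, start, length in existing:
        occupied[fly].append((start - 1, start + length + 1))
    plan = []
    for fly in range(n_flies):
        for tier, k in counts.items():
            lo, hi = _TIER_RANGES[tier]
            for _ in range(k):
                for _attempt in range(1000):
                    length = int(rng.integers(lo, hi + 1))
                    start = int(rng.integers(1, n_frames - length - 1))
                    if all(not (start - 1 < e and s < start + length + 1)
                           for s, e in occupied[fly]):
                        occupied[fly].append((start - 1, start + length + 1))
                        plan.append((fly, start, length))
                        break
                else:
                    raise SpecError("could not place all requested gaps without overlap")
    return plan


# ---------------------------------------------------------------------------
# egg-laying generators


@dataclass(frozen=True)
class EggModelSpec:
    """Latent-latency + Poisson-deposition model for the latency assay.

    The default mean latency of 420 min puts the population right at the
    lights-off boundary of a trial started at ZT5 (ZT12 = 420 min in), so
    line effects of a few hours move lines across the light/dark divide —
    the regime in which latency and percent-night-layers covary.
    """

    latency_mean_min: float = 420.0
    line_sd_min: float = 180.0
    resid_sd_min: float = 90.0
    rate_per_h: float = 2.0
    interval_min: float = 15.0
    horizon_min: float = 1440.0
    photoperiod: PhotoperiodSpec = field(default_factory=PhotoperiodSpec)


def simulate_egg_series(
    model: EggModelSpec,
    line_effect_min: float,
    rng: np.random.Generator,
    line_id: str = "",
    trial_id: str = "",
) -> tuple[EggCountSeries, float]:
    """One cumulative egg-count series and its true (unquantized) latency.

    True latency = mean + line effect + residual noise, clipped into
    (0, inf); trials whose latency exceeds the horizon yield an all-zero
    (censored) series.  The first egg is guaranteed at the first grid point
    at or after the true latency; later intervals add Poisson counts at
    ``rate_per_h``.
    """
    L = model.latency_mean_min + line_effect_min + rng.normal(0, model.resid_sd_min)
    L = max(L, 1e-9)
    times = np.arange(0, model.horizon_min + model.interval_min / 2, model.interval_min)
    cum = np.zeros_like(times)
    if L <= model.horizon_min:
        k_first = int(np.ceil(L / model.interval_min))
        rate_per_min = model.rate_per_h / 60.0
        cum[k_first] = 1 + rng.poisson(rate_per_min * (times[k_first] - L))
        for k in range(k_first + 1, len(times)):
            cum[k] = cum[k - 1] + rng.poisson(rate_per_min * model.interval_min)
    series = EggCountSeries(
        line_id=line_id, trial_id=trial_id, times_min=times, cum_eggs=cum,
        interval_min=model.interval_min, horizon_min=model.horizon_min,
        photoperiod=model.photoperiod,
    )
    return series, float(L)


def simulate_preference_trial(
    true_index: float,
    rng: np.random.Generator,
    mean_total_eggs: float = 40.0,
    line_id: str = "",
    trial_id: str = "",
) -> PreferenceTrial:
    """Two-patch counts: total ~ Poisson, split binomially by the true index.

    A true index of +1 sends every egg to the pheromone patch; 0 splits
    evenly.
    """
    if not -1 <= true_index <= 1:
        raise SpecError("true_index must lie in [-1, 1]")
    total = int(rng.poisson(mean_total_eggs))
    p = (1.0 + true_index) / 2.0
    eggs_ph = int(rng.binomial(total, p)) if total else 0
    return PreferenceTrial(line_id, trial_id, eggs_ph, total - eggs_ph)


# ---------------------------------------------------------------------------
# genotype panels


@dataclass
class LinePanelSpec:
    """A panel of genotype lines with correlated latent traits.

    Per line, the latent trait vector is multivariate normal with unit
    marginals correlated by ``corr``, scaled by ``line_sds`` and shifted by
    ``trait_means``; replicates add independent residual noise.  The default
    three traits stand for the three assays' headline measures.
    """

    seed: int = 0
    n_lines: int = 105
    traits: tuple[str, ...] = ("preference", "latency", "interactions")
    trait_means: tuple[float, ...] = (0.05, 420.0, 20.0)
    line_sds: tuple[float, ...] = (0.20, 180.0, 8.0)
    resid_sds: tuple[float, ...] = (0.30, 90.0, 10.0)
    reps_per_line: int = 20
    corr: np.ndarray | None = None  # default: identity (independent assays)

    def resolved_corr(self) -> np.ndarray:
        k = len(self.traits)
        R = np.eye(k) if self.corr is None else np.asarray(self.corr, dtype=float)
        if R.shape != (k, k) or not np.allclose(R, R.T):
            raise SpecError("corr must be a symmetric k x k matrix")
        if not np.allclose(np.diag(R), 1.0):
            raise SpecError("corr must have unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise SpecError("corr must be positive semi-definite")
        return R


def simulate_line_panel(spec: LinePanelSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(tidy replicate table, true per-line latents).

    The replicate table has columns line_id, trait, rep, value; the latents
    table one row per line with the true trait values, for recovery tests.
    """
    R = spec.resolved_corr()
    k = len(spec.traits)
    if not (len(spec.trait_means) == len(spec.line_sds) == len(spec.resid_sds) == k):
        raise SpecError("trait_means, line_sds, resid_sds must match traits")
    rng = np.random.default_rng(spec.seed)
    # unit-variance correlated latents via Cholesky-like factor of R
    w, V = np.linalg.eigh(R)
    factor = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
    Z = rng.standard_normal((spec.n_lines, k)) @ factor.T
    latent = Z * np.asarray(spec.line_sds) + np.asarray(spec.trait_means)

    line_ids = [f"line_{i:03d}" for i in range(spec.n_lines)]
    rows = []
    for li, line_id in enumerate(line_ids):
        for ti, trait in enumerate(spec.traits):
            obs = latent[li, ti] + rng.normal(0, spec.resid_sds[ti], spec.reps_per_line)
            for rep, v in enumerate(obs):
                rows.append((line_id, trait, rep, float(v)))
    panel = pd.DataFrame(rows, columns=["line_id", "trait", "rep", "value"])
    latents = pd.DataFrame(latent, columns=list(spec.traits))
    latents.insert(0, "line_id", line_ids)
    return panel, latents
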