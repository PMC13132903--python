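# Methods

## Scope and data model

The pipeline starts at tracker output (per-frame centroid and heading per
fly) and at egg-count records; video processing, egg counting from images,
GLMM-based line-effect inference and GWAS are outside its scope — the
replicate-level tidy table it exports is the interface to such downstream
modelling. Coordinates follow one fixed convention: origin at an arena
corner, x along the long (66 mm) side, y along the short (30 mm) side,
millimetres, 0-based frames. Trajectory CSVs are `frame,id,x,y,angle`;
a missing observation may be an absent row or NaN coordinates — the two are
equivalent. Pixel-space exports are converted via `mm_per_px`.

## Retention

A trial is kept when tracking covers at least 98% of frames. The threshold
is applied **per fly** by default: one poorly tracked fly invalidates every
pairwise quantity, so the strictest reading is the safe default. A pooled
mode (mean coverage over flies) is available via `coverage_mode` for users
who prefer the trial-wide reading; the boundary is inclusive (exactly 98%
keeps).

## Gap policy

Missing runs are maximal runs of invalid frames, classified by length:
1–4 frames short, 5–15 medium, ≥ 16 long — a literal reading of
"shorter than five", "between 5 and 15", "longer than 15" that makes the
tiers a partition. Short gaps copy the temporally nearest observed frame
(ties go to the earlier frame: deterministic and causal). Medium gaps are
filled per coordinate by a cubic spline fitted on up to 10 valid frames on
each side with not-a-knot end conditions; locality keeps a gap's fill
independent of distant data, and not-a-knot reproduces cubic polynomials
exactly, which the tests exploit as an exactness oracle (reconstruction
error ≤ 1e-6 mm on cubic paths). A medium gap with fewer than 2 valid
frames on either side cannot support a spline and is demoted to masked with
a logged warning. Long gaps are masked: reconstructing ≥ 0.5 s of path
would invent behaviour. Gaps touching the trajectory's start or end have
one-sided support only and are always masked, never extrapolated,
regardless of length.

Heading angles are always spline-interpolated (short and medium gaps), but
on the **unwrapped** series: observed angles are lifted to a continuous
real-valued series before fitting and the fill is rewrapped to [−π, π).
Without unwrapping, a crossing of the angular seam (e.g. +3.1 → −3.1 rad)
would interpolate the long way through 0 and fabricate a half-spin. Whether
the angle channel should also be interpolated across long gaps is genuinely
open ("always" could be read either way); long gaps are masked for angles
too by default, so that a frame is analysable only when both channels are
defined, with `mask_long_angle_gaps=False` exposing the other reading.

Observed frames are never altered (no smoothing or outlier rejection), and
cleaning is idempotent. Every frame carries a provenance tag
(`observed`/`nn_filled`/`spline_filled`/`masked`) exported with the
cleaned-trajectory CSV.

## Interaction bouts

Per ordered (focal, partner) pair and frame, the indicator is: both flies
analysable ∧ the focal's heading unit vector dotted with the vector to the
partner is strictly positive (strict < 90°; exactly perpendicular fails) ∧
centroid distance ≤ 2 body lengths. Coincident centroids satisfy both
criteria by convention — an undefined direction at distance zero should not
break an ongoing contact bout. Bouts are maximal indicator runs of at least
⌈1.5 s × fps⌉ frames (45 at 30 fps; the 44/45 boundary is tested). A single
false or masked frame terminates a run; no gap bridging is applied, as no
bridging rule is part of the bout definition being implemented.

The angular criterion is focal-specific, so bouts are **directed** and a
mutual encounter counts twice (once per direction); `mode="undirected"`
unions the two directed indicator series per unordered pair before the
persistence filter, for users who want encounter-level counts. Body length
is not fixed by the assay; it defaults to 2.5 mm (adult male
*D. melanogaster*) and is configurable, and the value used is written into
the output metadata because it scales the distance criterion directly.

Distance metrics exclude frames with fewer than two analysable flies.
Interindividual distance averages each contributing frame's mean pairwise
distance; nearest-neighbor distance averages, over frames and analysable
flies, each fly's minimum distance to a conspecific. The former never falls
below the latter (mean of per-fly minima ≤ mean of pairwise means), an
invariant checked on every simulated trial.

## Locomotion covariates

Walking speed uses consecutive analysable frame pairs only
(displacement × fps, reported in cm/s), per-fly mean then group mean; pairs
spanning a masked frame are excluded, and interpolated frames participate
like observed ones since they passed the gap policy. The center region
trims width/4 (7.5 mm) from all four edges, leaving 51 × 15 mm in the
default arena; the boundary counts as inside (a measure-zero choice fixed
for determinism). Center occupancy is the per-fly fraction of analysable
frames inside, averaged over flies.

## Egg-laying scoring

The preference index is (E_ph − E_ctrl)/(E_ph + E_ctrl); zero-total trials
are undefined and excluded from aggregation but counted. Latency is the
first sampling time with a positive cumulative count — quantized to the
15-min grid because that is the resolution of the time-lapse protocol; no
sub-interval interpolation is attempted. Trials with no egg by the 24-h
horizon are censored: excluded from line means and night percentages but
reported (`n_censored`) so exclusions are auditable. Phase of the first
egg: absolute ZT = (ZT_start + latency/60) mod 24, dark iff ZT ∈ [12, 24)
under the 12:12 default; the lights-off instant itself belongs to dark
(dark onset). Percent night layers = 100 × dark / non-censored.

## Line-level statistics

Line means use a percentile bootstrap (default 10,000 resamples within
line, mandatory seed; single-replicate lines get a degenerate CI). The
percentile bootstrap undercovers slightly at small n (measured ~93% at
n = 20 for a normal mean), which is accepted and documented rather than
corrected. Traits are z-scored (denominator n − 1) before OLS on line
means, so slope = Pearson r, R² = slope², F = t² with p from F(1, n − 2);
the implementation is cross-checked against a hand-rolled normal-equations
oracle. The trait-pair matrix drops lines pairwise-complete, reports n per
pair, and adds a Benjamini–Hochberg column alongside raw p-values. Grand
means are reported in both readings — mean of line means and mean of pooled
trials — explicitly labelled, since either convention is defensible.
Replicate noise attenuates an observed between-line correlation by
√(λ_x λ_y) with λ = σ²_L/(σ²_L + σ²_e/n); the recovery tests use this
closed form as their oracle.

## Synthetic data

The group-trial generator is a bounded correlated random walk: heading is a
Gaussian random walk with turn SD (1 − persistence)·π rad/frame,
exponential step lengths with mean `step_mm`, and positions folded back
into the arena (reflecting walls). Defaults — 0.5 mm/frame at 30 fps
(~1.5 cm/s) and persistence 0.9 — sit in the range of ordinary fly walking.
Headings are not reflected at walls; the heading channel is an independent
CRW observable, which is sufficient for the facing criterion the metrics
consume. An optional tether folds each fly's walk into a small box around a
per-fly home point spread along the arena, guaranteeing wide spacing for
choreography tests. Scripted encounters park a pair at the stated
separation, anchored at the focal fly's position, with headings toward each
other (mutual) or focal-only; the ground-truth bout list is derived from
this choreography before gap injection, so the effect of each cleaning tier
on bout recovery is directly measurable. Gaps are injected by deleting
frames, either from an explicit plan or sampled per tier without adjacency
(adjacent gaps would merge and change tier). Infeasible specs — a fly
double-booked across overlapping encounters, encounters past the trial end
— are rejected.

The egg-series generator draws a true latency (mean + line effect +
residual noise, clipped positive; default mean 420 min places the
population at the lights-off boundary so line effects move lines across the
light/dark divide), guarantees the first egg at the first grid point at or
after it, and adds Poisson counts (default 2 eggs/h) per subsequent
interval; latencies past the horizon yield censored all-zero series.
Preference counts split a Poisson total binomially with
p = (1 + true index)/2. Line panels draw per-line latent trait vectors from
a multivariate normal with configurable correlation matrix (validated
symmetric PSD with unit diagonal) and add replicate residual noise,
returning both observations and latents.

What the generators do **not** emulate: real fly kinematics (velocity
autocorrelation spectra, wall-following, social avoidance), identity-swap
tracking errors, non-Poisson egg clustering, or non-Gaussian line-effect
distributions. Passing tests therefore demonstrate that the pipeline's
scoring, cleaning and aggregation are correct and internally consistent —
not that the biological effect sizes of any particular panel will be
reproduced on real data.

## Problem sizes and determinism

The test and reproduction runs use desk-scale sizes chosen to exercise each
property densely: 200 random 2,000-frame trials for oracle equivalence,
1,000 egg series for latency/phase recovery, 100 null panels and 30
correlated panels of 105 lines × 20 replicates for correlation recovery.
All randomness flows through `numpy.random.default_rng` seeded from the
spec or the CLI/script `--seed`; identical seeds give bit-identical
outputs, and every run writes its resolved configuration next to its
outputs.

## Known limitations

- Group size is configurable (default 4); metrics are well-defined for any
  group ≥ 2, but the interaction criteria were designed for small groups in
  a shallow arena where flies cannot stack.
- The bout count depends linearly on the configurable body length; compare
  counts only across runs scored with the same value.
- The retention filter cannot distinguish a fly that left the tracking
  volume from tracker failure; both read as missing frames.
- `RunConfig` drives the CLI; library users pass thresholds explicitly.
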