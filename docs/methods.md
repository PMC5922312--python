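# Methods

This note documents the models and procedures implemented in `welltrack`,
the defaults that matter, and the choices made where the design was open.

## Well detection

Wells are circles sharing one radius. Stage 1 estimates that radius by a
circular Hough scan: the candidate ladder starts at
`floor(longer_side / sqrt(n_wells))` — the largest radius `n_wells` disks
could have along the longer image side — and descends in 5-px steps for up
to 100 radii (never below 5 px). Edge evidence is the set of pixels whose
gradient magnitude exceeds the image's 95th percentile; each votes one
point along its gradient direction, which at the rim of a bright well
points at the center. Voting a single direction (rather than both signs)
was chosen because it cannot create ghost peaks in the dark interstices
between wells. Each radius is scored by its accumulator maximum divided by
the circle circumference `2πr`, so large radii do not win merely by
collecting more coincidental votes; the best-scoring radius is `r_est`.
With a 5-px ladder, `r_est` is accurate to one step.

Stage 2 re-votes over nine radii spanning `[0.8, 1.2]·r_est`, smooths the
accumulator with a Gaussian of `σ = r_est/10` (the smoothing scale must
track the well scale; the procedure itself fixes no value), and extracts
centers greedily: global maximum, suppress a disk of radius `r_est`,
repeat. Ties break toward the lowest `(y, x)`. Centers are returned
row-major. Coordinates are 0-based, `x` = column, `y` = row; sub-pixel
refinement is not attempted because the tracker's anchor positions are
integer pixels anyway. Manual corrections replace the nearest center when
within `r_est`, else count as a missed well and are appended.

## Tracking

All thresholds operate on mean-normalized intensities (every frame, or
per-well crop, is divided by its mean), which makes detection invariant to
overall illumination scale — doubling the lamp brightness changes nothing.
Defaults the procedure itself does not dictate, all config-overridable:
smoothing `σ = 1 px`; blob connectivity 8; "larger than one pixel" read as
size ≥ 2; per-well crops are squares of side `2.4·r_est` (prevents
cross-well interference) and positions beyond `1.2·r_est` from the center
are discarded.

The detection threshold −0.5 applies to (frame − static background) in
normalized units; the static background is the mean of up to 1000
equi-spaced processed frames, the dynamic background the mean of the
previous ≤5. Acceptance rules: a blob must overlap the previous frame's
larva pixels (rule a) or contain a pixel below threshold against the
dynamic background (rule b). At frame 0 neither rule is evaluable and
blobs are accepted unconditionally to initialize. After a gap the larva is
assumed stationary; only rule (b) — movement evidence — resumes tracking,
and the stale previous-frame pixels are not used for rule (a) during the
gap. Reflection removal drops any blob that has a strictly bigger,
strictly closer-to-center companion within 10° of angular separation, as
seen from the well center; size, distance and angle are computed from blob
pixel counts and anchor (most-contrasted-pixel) rays, since the method
names no other reference point.

A consequence of the static-background design worth knowing: an object
that never moves is, by construction, part of the background and is never
detected; and in *short* videos a larva that rests in one spot for a large
fraction of the recording partially erases its own contrast there. At the
20-min recordings the pipeline targets (and the ≥500-frame test videos),
typical rest bouts are a negligible fraction of the background average and
this effect is irrelevant.

## Behavioral parameters

Frame `t` counts as movement when the displacement from `t−1` exceeds
`ε = 1 px` (the tracker's resolution; overridable). Gaps are filled with
the last known position before labeling, consistent with the tracker
semantics that a lost larva has not moved. Tortuosity is the mean scalar
product of successive *unit* velocity vectors — the cosine of the turning
angle — keeping it bounded in [−1, 1]; instant tortuosity applies the same
product to the first two velocities after each stop→move transition (the
transition step and the one following it). Bursting is reported as
transitions per frame (duration-invariant); the raw transition count is
also emitted. The radial index is the mean of `1 − d/R` clamped to [0, 1].
A larva with zero movement has no speed/tortuosity/etc.: those are
reported missing (NaN), never 0. Fragments are consecutive, non-overlapping
30-s windows; a trailing partial window is dropped (20 min at 25 fps → 40
fragments).

For the rectangular novel-tank arena the radial index is replaced by the
mean distance to the nearest long wall, scaled to 0 at the walls and 1 on
the midline.

## Variability statistics

Sample covariances use `n−1` throughout. The kernel density map uses
per-axis bandwidths `σ = N^(−1/6) α` (normal-reference rule for a 2-D
density) on a 200×200 grid padded by 3 bandwidths; the padding is what
keeps the numerical integral within 0.01 of 1. Dispersion of a parameter
across fragments is its CV, except for the signed tortuosity parameters
where the SD is used; a zero mean under CV falls back to SD with a
warning.

The intra/inter permutation test shuffles the pooled fragments across
individuals (preserving per-individual counts, so intra and inter remain
comparable), statistic = median(inter) − median(intra). The group test
shuffles individuals between groups, statistic = |GV(A) − GV(B)| by
default (two-sided via the absolute difference; sidedness was open) or the
centroid distance for mean comparisons. p-values are the plain proportion
of permuted statistics ≥ observed over 1000 shuffles by default (the
`(b+1)/(n+1)` variant is available by flag); identical groups give p = 1
by construction. Polar coordinates are computed on raw
(activity, radial index) units — both are bounded fractions, so axis
standardization is unnecessary (a config option exposes the center).
Inter-individual dispersion pairs fragments by time window; a random-draw
pairing across fish would also be defensible, but window pairing keeps the
inter series aligned with the intra series and is what the permutation
scheme preserves.

## Pooling

Equal-size clustering seeds k centroids on randomly chosen individuals and
then binds (individual, centroid) pairs *globally* closest-first until
every cluster holds exactly `size` members — a processing-order-free
reading of "nearest not-occupied centroid"; centroids are recomputed and
the round repeats until the assignment is exactly stable (the stability
rule names no tolerance) or 100 iterations. Ties break toward the lowest
individual index. Linkage pooling scores every merge-tree subtree of
exactly `pool_size` leaves by mean intra-pool pairwise distance and takes
the tightest disjoint ones, which operationalizes "pools of very similar
behavior".

## The synthetic population

The generator is the package's testbed; no generative model is prescribed
by the tracking method itself, so the simplest model producing all eight
parameters with controllable individuality was chosen: a two-state
stop/move Markov chain (per-frame probabilities `p_stop_to_move`,
`p_move_to_stop`), gamma-distributed step lengths, a persistent heading
(turn magnitude shrinks with `heading_persistence`) with proportional
steering toward a preferred radius `radial_target·R` at gain
`radial_pull`, and specular wall reflection. The stationary moving
fraction `a/(a+b)` is the individual's expected activity — an analytic
target the pipeline's measured activity can be checked against.

Defaults (the simulated study conditions): 24 individuals, one per well;
`a = 0.05`, `b = 0.08` per frame at 25 fps, i.e. mean rest bouts of 0.8 s,
mean swim bouts of 0.5 s and activity ≈ 0.38 — bout-like larval swimming;
`step_mean = 4 px` with gamma shape 4 (comfortably above the 1-px movement
threshold, so state labeling is nearly exact); `heading_persistence =
0.7`; `radial_target = 0.6`, `radial_pull = 0.5`. The steering gain
saturates at |radial error| ≥ R/3; the value 0.5 was set so that the
realized radial index responds strongly and monotonically to the
individual's target (range ≈ 0.19–0.59 across targets 0.3–0.9) instead of
being washed out by diffusion against the wall. Individual parameters are
drawn log-normally (mean-preserving) around the population values with a
coefficient of variation of 0.3 per field; probabilities are clamped to
[1e-4, 1−1e-4] so no individual becomes absorbing. This yields population
SDs of ≈ 0.10 in both activity and radial index — a behavioral cloud
occupying roughly 0.4 × 0.4 of the unit plane. `shrink_variability`
multiplies all spreads by a factor in [0, 1], narrowing individuality
without moving the population mean — the in-silico analog of an HDAC-
inhibition treatment that reduces variability only.

Rendering: wells are bright disks (interior 1.0, exterior 0.25, sigmoid
rim) under a ±15% smooth illumination gradient; larvae are Gaussian
dimples (amplitude 0.95, σ 1.8 px), with a smaller, fainter mirrored
dimple placed just outside the wall whenever the larva is beyond 0.75 R
(±2° angular jitter) — the classic reflection artifact; pixel noise SD
0.01; output is 8-bit. These defaults put the post-smoothing blob depth
near −0.9 normalized units against a −0.5 threshold, i.e. robust but not
trivially easy detection; a config that cannot clear the threshold is
rejected up front. All randomness flows from single integer seeds;
identical seeds give byte-identical videos.

What the simulator does *not* emulate: body posture and tail kinematics,
multi-animal wells, stimulus responses, camera vignetting/rolling shutter,
water-surface glare, or drifting illumination. Passing the end-to-end
tests therefore demonstrates correctness of the algorithms under the
stated appearance model, not performance on any particular real rig.

## Problem sizes used in the validation suite

Tracking fidelity runs on 24 wells × 500 frames with reflections and
noise on. Permutation calibration and power use 10-min-equivalent
(15 000-frame) individuals — at that length measurement noise in activity
is an order of magnitude below the inter-individual spread, so the group
statistics are already in their long-recording regime — with 200 null
replicates and 100 treatment replicates, n = 24 per group, 500 shuffles
per test. Activity recovery uses full 20-min (30 000-frame) runs and is
asserted on the population mean absolute error (< 0.03): per-individual
errors at finite recording length have an irreducible stochastic floor
(SE ≈ 0.01 for these switching rates), so the mean over 24 individuals is
the stable quantity. Calibration-scale suites stream
`population_behavior_sample`, which consumes the exact RNG stream of the
trajectory simulator (asserted equal in tests) while accumulating only
(activity, radial index).

## Known limitations

- One larva per well; no identity handling if animals are moved.
- Integer-pixel positions; sub-pixel accuracy is not attempted.
- The static background assumes a mostly-static scene over the video.
- AVI input requires an imageio ffmpeg backend; image sequences and
  multi-page TIFF are the native formats.
- The radius scan assumes all wells share one radius, as in the plates
  the pipeline was designed for.
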