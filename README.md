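# welltrack

Tracking single zebrafish larvae in multiwell plates and quantifying
behavioral individuality.

Zebrafish larvae raised in identical conditions still behave like
individuals: each animal keeps its own characteristic activity level and
wall affinity day after day. Measuring that individuality at scale takes
three things this package provides as one tested pipeline:

1. **Video tracking.** Circular wells are auto-detected with a two-stage
   circular Hough transform. Each well is then tracked by background
   subtraction: every frame is normalized to mean intensity 1 and
   smoothed; a *static* background (mean of up to 1000 equi-spaced
   frames) exposes both resting and swimming larvae, while a *dynamic*
   background (mean of the previous five frames) provides movement
   evidence that filters noise blobs and wall reflections. Candidate
   blobs are connected components of `frame − static_bg < −0.5` with at
   least 2 px; a blob survives only if it overlaps the previous larva
   pixels or carries dynamic evidence. Reflections — smaller blobs
   further from the well center within 10° of a bigger blob — are
   removed; the most contrasted pixel of the most contrasted blob is the
   larva's position, and frames with no surviving blob become explicit
   gaps.
2. **Behavioral parameters.** From each trajectory: activity, radial
   index, speed, bursting, tortuosity, circularity, instant acceleration
   and instant tortuosity, both per individual and over consecutive 30-s
   fragments.
3. **Variability statistics.** The population lives in the
   (activity, radial index) plane. Dispersion there is summarized by a
   Gaussian kernel density map

   `P(x, y) = (1 / (N · 2π σx σy)) Σᵢ exp(−½ [(x−xᵢ)²/σx² + (y−yᵢ)²/σy²])`

   with bandwidths `σx = N^(−1/6) αx` (αx the sample SD), and by the
   generalized variance `|Σ| = σx² σy² (1 − ρ²)`. Permutation tests
   (1000 shuffles) compare inter- vs intra-individual variability and
   the generalized variance of two groups; constrained equal-size
   clustering (e.g. 18 pools of 5 from 90 larvae) and average-linkage
   pool selection support pooling designs for molecular assays.

A synthetic-data module simulates individualized larvae (two-state
stop/move Markov chain, gamma step lengths, persistent headings with a
radial preference) and renders them into plate videos with reflections,
uneven illumination and noise — so the whole pipeline is verifiable
against known ground truth without animals.

## Worked example

```python
import numpy as np
import welltrack as wt

# a 24-well plate with 24 individualized larvae, 500 frames at 25 fps
wells = wt.make_plate(24, radius=26.0)
pop = wt.PopulationParams(n_individuals=24, interindividual_spread=0.3,
                          seed=5)
truth = wt.simulate_trajectories(pop, wells, 500)
video = wt.render_video(truth, wells, wt.RenderConfig(seed=5)).frames

# detect the wells, track every larva, score behavior
wellmap = wt.detect_wells(video[0] / 255.0, n_wells=24)
trajs = wt.track_video(video, wellmap)
from welltrack.behavior import compute_behavior_vector
pts = np.array([[v.activity, v.radial_index]
                for v in map(compute_behavior_vector, trajs)])

err = np.hypot(*(np.stack([t.positions for t in trajs], 1)
                 - truth.positions_array()).transpose(2, 0, 1))
print(f"r_est = {wellmap.radius:.0f} px")
print(f"tracking RMSE = {np.sqrt(np.nanmean(err**2)):.2f} px")
print(f"density integral = {wt.kernel_density_map(pts).integral():.3f}")
print(f"generalized variance = {wt.generalized_variance(pts):.2e}")
```

prints

```
r_est = 24 px
tracking RMSE = 0.42 px
density integral = 1.000
generalized variance = 1.41e-04
```

i.e. the wells are recovered within one 5-px radius step, tracked
positions sit half a pixel from ground truth, the probability surface
over the behavioral plane integrates to 1, and the population's
dispersion in that plane is summarized by one scalar ready for
permutation testing.

A command-line interface mirrors the library
(`welltrack simulate | detect-wells | track | behavior | stats |
cluster | run`).

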