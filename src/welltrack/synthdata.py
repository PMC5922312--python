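"""Synthetic larval populations with known ground truth.

Real recordings are 20-min videos of single zebrafish larvae in circular
wells (24 wells per plate, 25 fps). This module generates individualized
trajectories from a minimal generative model and renders them into plate
videos, so the tracker and the variability statistics can be validated
end-to-end against known truth.

Motion model (per individual, per frame):

* a two-state stop/move Markov chain with per-frame transition
  probabilities ``p_stop_to_move`` and ``p_move_to_stop`` — the stationary
  moving fraction ``p_stop_to_move / (p_stop_to_move + p_move_to_stop)`` is
  the individual's expected *activity*;
* while moving, step lengths are gamma distributed with mean ``step_mean``
  and shape ``step_shape``;
* the heading persists between steps (turn magnitude shrinks as
  ``heading_persistence`` grows) with a proportional correction steering
  the larva toward radius ``radial_target * R`` at gain ``radial_pull`` —
  this sets the individual's expected *radial index*;
* positions reflect specularly off the well wall.

Individual parameters are drawn log-normally around population means with
a per-field coefficient of variation (``interindividual_spread``), so a
spread of zero collapses the population onto identical individuals, and
:func:`shrink_variability` emulates an intervention that narrows
individuality without moving the population mean.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .tracker import Trajectory
from .welldetect import WellMap

_PROB_CLAMP = (1e-4, 1.0 - 1e-4)
#: Larvae keep this fraction of the well radius as wall stand-off so that a
#: rendered blob never leaves the well.
_WALL_MARGIN = 0.95


@dataclass(frozen=True)
class MotionParams:
    """Per-individual motion parameters.

    All values are per-frame quantities at the simulation frame rate.
    """

    p_stop_to_move: float = 0.05   #: stop -> move probability per frame
    p_move_to_stop: float = 0.08   #: move -> stop probability per frame
    step_mean: float = 4.0         #: mean step length while moving, px/frame
    step_shape: float = 4.0        #: gamma shape of the step-length law
    heading_persistence: float = 0.7  #: 0 = uniform turns, 1 = straight
    radial_target: float = 0.6     #: preferred radius, fraction of R
    radial_pull: float = 0.5       #: steering gain toward the target radius

    def __post_init__(self):
        vals = dataclasses.asdict(self)
        if not all(np.isfinite(v) for v in vals.values()):
            raise ValueError(f"non-finite motion parameter: {vals}")
        for p in ("p_stop_to_move", "p_move_to_stop"):
            if not 0.0 <= vals[p] <= 1.0:
                raise ValueError(f"{p} must be in [0, 1]")
        if self.step_mean <= 0 or self.step_shape <= 0:
            raise ValueError("step_mean and step_shape must be > 0")
        if self.heading_persistence < 0:
            raise ValueError("heading_persistence must be >= 0")
        if not 0.0 <= self.radial_target <= 1.0:
            raise ValueError("radial_target must be in [0, 1]")
        if not 0.0 <= self.radial_pull <= 1.0:
            raise ValueError("radial_pull must be in [0, 1]")

    @property
    def stationary_moving_probability(self) -> float:
        """Long-run moving fraction of the stop/move chain (NaN if both
        transition probabilities are zero)."""
        s = self.p_stop_to_move + self.p_move_to_stop
        if s == 0:
            return float("nan")
        return self.p_stop_to_move / s


@dataclass(frozen=True)
class PopulationParams:
    """A population: mean motion parameters plus inter-individual spread.

    ``interindividual_spread`` is the coefficient of variation of the
    log-normal law each parameter is drawn from, either one value for all
    fields or a mapping ``field -> CV``. ``spread = 0`` reproduces
    ``mean_params`` exactly for every individual.
    """

    n_individuals: int = 24
    mean_params: MotionParams = MotionParams()
    interindividual_spread: float | dict[str, float] = 0.3
    seed: int = 0

    def spread_for(self, field: str) -> float:
        if isinstance(self.interindividual_spread, dict):
            return float(self.interindividual_spread.get(field, 0.0))
        return float(self.interindividual_spread)

    def sample_individuals(self, rng: np.random.Generator
                           ) -> list[MotionParams]:
        """Draw per-individual parameters (mean-preserving log-normal)."""
        fields = [f.name for f in dataclasses.fields(MotionParams)]
        draws: dict[str, np.ndarray] = {}
        for f in fields:
            mean = getattr(self.mean_params, f)
            cv = self.spread_for(f)
            if cv < 0:
                raise ValueError("interindividual_spread must be >= 0")
            if cv == 0 or mean == 0:
                vals = np.full(self.n_individuals, mean)
            else:
                sig = np.sqrt(np.log1p(cv ** 2))
                vals = mean * np.exp(
                    rng.normal(0.0, sig, self.n_individuals) - sig ** 2 / 2)
            draws[f] = vals
        lo, hi = _PROB_CLAMP
        for f in ("p_stop_to_move", "p_move_to_stop"):
            # keep probabilities away from the absorbing boundaries unless
            # the mean itself sits there
            if getattr(self.mean_params, f) not in (0.0, 1.0):
                draws[f] = np.clip(draws[f], lo, hi)
            else:
                draws[f] = np.clip(draws[f], 0.0, 1.0)
        draws["radial_target"] = np.clip(draws["radial_target"], 0.0, 1.0)
        draws["radial_pull"] = np.clip(draws["radial_pull"], 0.0, 1.0)
        return [MotionParams(**{f: float(draws[f][i]) for f in fields})
                for i in range(self.n_individuals)]


def shrink_variability(pop: PopulationParams,
                       factor: float) -> PopulationParams:
    """Scale every inter-individual spread by ``factor`` in [0, 1].

    Emulates an intervention that narrows behavioral individuality while
    leaving the population mean untouched: ``factor = 1`` is the identity,
    ``factor = 0`` makes all individuals identical to the mean.
    """
    if not 0.0 <= factor <= 1.0:
        raise ValueError("factor must be in [0, 1]")
    spread = pop.interindividual_spread
    if isinstance(spread, dict):
        spread = {k: v * factor for k, v in spread.items()}
    else:
        spread = spread * factor
    return dataclasses.replace(pop, interindividual_spread=spread)


# ---------------------------------------------------------------------------
# Plate geometry helper

def make_plate(n_wells: int = 24, radius: float = 26.0,
               spacing_factor: float = 2.5) -> WellMap:
    """A regular grid plate (rows x cols as square as ``n_wells`` allows)."""
    rows = int(np.floor(np.sqrt(n_wells)))
    while rows > 1 and n_wells % rows:
        rows -= 1
    cols = n_wells // rows
    s = spacing_factor * radius
    h, w = int(np.ceil(rows * s)), int(np.ceil(cols * s))
    centers = [((j + 0.5) * s, (i + 0.5) * s)
               for i in range(rows) for j in range(cols)]
    return WellMap(centers=np.asarray(centers), radius=radius,
                   image_shape=(h, w))


# ---------------------------------------------------------------------------
# Trajectory simulation

@dataclass
class GroundTruth:
    """Simulation output: trajectories plus the latent truth behind them."""

    trajectories: list[Trajectory]
    true_states: np.ndarray        # (n_frames, n_individuals) bool, True=move
    true_params: list[MotionParams]

    @property
    def n_individuals(self) -> int:
        return len(self.trajectories)

    def positions_array(self) -> np.ndarray:
        """(n_frames, n_individuals, 2) stacked positions."""
        return np.stack([t.positions for t in self.trajectories], axis=1)


def _wrap_angle(a):
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def _simulation_stream(params: list[MotionParams], centers: np.ndarray,
                       radius: float, n_frames: int,
                       rng: np.random.Generator):
    """Yield ``(positions (n, 2), moving (n,))`` per frame.

    Single source of the dynamics: both the trajectory collector and the
    streaming behavior summarizer consume this generator, so they draw the
    exact same random sequence for a given seed.
    """
    n = len(params)
    a = np.array([p.p_stop_to_move for p in params])
    b = np.array([p.p_move_to_stop for p in params])
    shape = np.array([p.step_shape for p in params])
    scale = np.array([p.step_mean / p.step_shape for p in params])
    persistence = np.array([p.heading_persistence for p in params])
    target = np.array([p.radial_target for p in params]) * radius
    pull = np.array([p.radial_pull for p in params])
    r_bound = _WALL_MARGIN * radius
    turn_scale = 1.0 - np.clip(persistence, 0.0, 1.0)

    # Initial conditions: stationary state draw, position at the preferred
    # radius with a random angle, random heading.
    p_stat = np.where(a + b > 0, a / np.where(a + b > 0, a + b, 1.0), 0.0)
    moving = rng.random(n) < p_stat
    theta0 = rng.uniform(-np.pi, np.pi, n)
    r0 = np.minimum(target, r_bound)
    pos = np.column_stack([r0 * np.cos(theta0), r0 * np.sin(theta0)])
    heading = rng.uniform(-np.pi, np.pi, n)

    yield centers + pos, moving.copy()
    for _ in range(n_frames - 1):
        u = rng.random(n)
        moving = np.where(moving, u >= b, u < a)
        steps = rng.gamma(shape, scale)
        turns = turn_scale * rng.uniform(-np.pi, np.pi, n)
        heading = _wrap_angle(heading + turns)
        # proportional steering toward the preferred radius
        d = np.hypot(pos[:, 0], pos[:, 1])
        outward = np.arctan2(pos[:, 1], pos[:, 0])
        err = (d - target) / radius
        aim = np.where(err > 0, _wrap_angle(outward + np.pi), outward)
        gain = pull * np.minimum(3.0 * np.abs(err), 1.0)
        heading = _wrap_angle(heading + gain * _wrap_angle(aim - heading))
        step_vec = np.column_stack([steps * np.cos(heading),
                                    steps * np.sin(heading)])
        new = np.where(moving[:, None], pos + step_vec, pos)
        # specular reflection off the wall (radial fold keeps it simple)
        dn = np.hypot(new[:, 0], new[:, 1])
        over = dn > r_bound
        if over.any():
            fold = (2.0 * r_bound - dn[over]) / dn[over]
            fold = np.clip(fold, 0.0, 1.0)
            new[over] *= fold[:, None]
            phi = np.arctan2(new[over, 1], new[over, 0])
            heading[over] = _wrap_angle(2.0 * phi + np.pi - heading[over])
        pos = new
        yield centers + pos, moving.copy()


def simulate_trajectories(pop: PopulationParams, wells: WellMap,
                          n_frames: int, fps: float = 25.0) -> GroundTruth:
    """Simulate one larva per well and return full ground truth.

    Raises if the plate has fewer wells than the population has
    individuals, or if ``n_frames < 2``.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if pop.n_individuals > wells.n_wells:
        raise ValueError(
            f"{pop.n_individuals} individuals but only "
            f"{wells.n_wells} wells")
    rng = np.random.default_rng(pop.seed)
    params = pop.sample_individuals(rng)
    centers = wells.centers[: pop.n_individuals]
    n = pop.n_individuals
    positions = np.empty((n_frames, n, 2))
    states = np.empty((n_frames, n), dtype=bool)
    stream = _simulation_stream(params, centers, wells.radius, n_frames, rng)
    for t, (p, s) in enumerate(stream):
        positions[t] = p
        states[t] = s
    trajectories = [
        Trajectory(well_id=i, positions=positions[:, i, :], fps=fps,
                   center=tuple(centers[i]), radius=wells.radius)
        for i in range(n)
    ]
    return GroundTruth(trajectories=trajectories, true_states=states,
                       true_params=params)


def population_behavior_sample(pop: PopulationParams, wells: WellMap,
                               n_frames: int, fps: float = 25.0,
                               epsilon: float = 1.0) -> np.ndarray:
    """Per-individual (activity, radial index) without storing trajectories.

    Streams the same dynamics as :func:`simulate_trajectories` (identical
    seed -> identical trajectories) and accumulates the two headline
    behavioral parameters online: activity = fraction of frames with
    displacement above ``epsilon`` (frame 0 counts as stopped), radial
    index = mean of ``1 - d/R`` clipped to [0, 1]. Orders of magnitude
    cheaper in memory for large calibration populations.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if pop.n_individuals > wells.n_wells:
        raise ValueError("more individuals than wells")
    rng = np.random.default_rng(pop.seed)
    params = pop.sample_individuals(rng)
    centers = wells.centers[: pop.n_individuals]
    n = pop.n_individuals
    move_count = np.zeros(n)
    radial_sum = np.zeros(n)
    prev = None
    stream = _simulation_stream(params, centers, wells.radius, n_frames, rng)
    for p, _ in stream:
        if prev is not None:
            disp = np.hypot(p[:, 0] - prev[:, 0], p[:, 1] - prev[:, 1])
            move_count += disp > epsilon
        d = np.hypot(p[:, 0] - centers[:, 0], p[:, 1] - centers[:, 1])
        radial_sum += np.clip(1.0 - d / wells.radius, 0.0, 1.0)
        prev = p
    return np.column_stack([move_count / n_frames, radial_sum / n_frames])


# ---------------------------------------------------------------------------
# Video rendering

@dataclass
class RenderConfig:
    """Appearance of the rendered plate video (raw intensities in [0, 1])."""

    well_intensity: float = 1.0        #: bright well interior
    exterior_intensity: float = 0.25   #: plate material between wells
    edge_softness: float = 1.0         #: rim transition width, px
    blob_amplitude: float = 0.95       #: larva darkness (fraction of interior)
    blob_sigma: float = 1.8            #: larva Gaussian radius, px
    reflection: bool = True            #: render wall reflections
    reflection_amplitude: float = 0.75  #: relative to the larva amplitude
    reflection_sigma: float = 1.5      #: reflection Gaussian radius, px
    reflection_min_radius: float = 0.75  #: reflections appear beyond this * R
    illumination_gradient: float = 0.15  #: peak-to-mean smooth shading
    noise_sigma: float = 0.01          #: additive Gaussian noise SD
    seed: int = 0
    ensure_detectable: bool = True     #: validate blob depth vs threshold


@dataclass
class RenderResult:
    frames: np.ndarray                 # (n_frames, h, w) uint8
    truth: GroundTruth
    reflection_positions: np.ndarray   # (n_frames, n, 2), NaN where absent


def _plate_background(wells: WellMap, cfg: RenderConfig) -> np.ndarray:
    h, w = wells.image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.full((h, w), cfg.exterior_intensity)
    soft = max(cfg.edge_softness, 1e-6)
    for cx, cy in wells.centers:
        d = np.hypot(xx - cx, yy - cy)
        rim = 1.0 / (1.0 + np.exp((d - wells.radius) / soft))
        img = img + (cfg.well_intensity - cfg.exterior_intensity) * rim
    if cfg.illumination_gradient:
        gx = np.linspace(-1.0, 1.0, w)[None, :]
        gy = np.linspace(-1.0, 1.0, h)[:, None]
        img = img * (1.0 + 0.5 * cfg.illumination_gradient * (gx + gy))
    return img


def _stamp_gaussian(img, x, y, amplitude, sigma):
    """Subtract a Gaussian dimple at a (float) position, in place."""
    h, w = img.shape
    half = int(np.ceil(4 * sigma))
    x0, x1 = int(np.floor(x)) - half, int(np.floor(x)) + half + 1
    y0, y1 = int(np.floor(y)) - half, int(np.floor(y)) + half + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return
    yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
    img[y0c:y1c, x0c:x1c] -= amplitude * np.exp(
        -((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma ** 2))


def render_video(truth: GroundTruth, wells: WellMap,
                 cfg: RenderConfig | None = None) -> RenderResult:
    """Render ground-truth trajectories into an 8-bit plate video.

    Larvae are dark Gaussian blobs on bright well interiors; optionally a
    smaller, fainter mirrored blob is placed just outside the wall when
    the larva is close to it (the classic reflection artifact), plus a
    smooth illumination gradient and additive pixel noise.
    """
    cfg = cfg or RenderConfig()
    bg = _plate_background(wells, cfg)
    positions = truth.positions_array()
    n_frames, n, _ = positions.shape
    centers = wells.centers[:n]
    R = wells.radius
    depth = cfg.blob_amplitude * cfg.well_intensity

    if cfg.ensure_detectable:
        # Depth surviving tracker smoothing (sigma 1) in mean-normalized
        # units must clearly exceed the 0.5 detection threshold.
        mean_est = bg.mean()
        smooth_keep = cfg.blob_sigma ** 2 / (cfg.blob_sigma ** 2 + 1.0)
        norm_depth = depth * smooth_keep / mean_est
        norm_depth *= 1.0 - cfg.illumination_gradient
        if norm_depth <= 0.55:
            raise ValueError(
                f"blob depth {norm_depth:.2f} (normalized, post-smoothing) "
                "cannot reliably exceed the 0.5 detection threshold; "
                "raise blob_amplitude or blob_sigma")

    rng = np.random.default_rng(cfg.seed)
    frames = np.empty((n_frames, *bg.shape), dtype=np.uint8)
    refl = np.full((n_frames, n, 2), np.nan)
    for t in range(n_frames):
        img = bg.copy()
        for i in range(n):
            x, y = positions[t, i]
            _stamp_gaussian(img, x, y, depth, cfg.blob_sigma)
            if cfg.reflection:
                cx, cy = centers[i]
                dx, dy = x - cx, y - cy
                d = np.hypot(dx, dy)
                if d > cfg.reflection_min_radius * R:
                    jitter = rng.normal(0.0, np.deg2rad(2.0))
                    phi = np.arctan2(dy, dx) + jitter
                    rr = R + 0.8 * (R - d)
                    rx, ry = cx + rr * np.cos(phi), cy + rr * np.sin(phi)
                    _stamp_gaussian(img, rx, ry,
                                    cfg.reflection_amplitude * depth,
                                    cfg.reflection_sigma)
                    refl[t, i] = (rx, ry)
        if cfg.noise_sigma:
            img = img + rng.normal(0.0, cfg.noise_sigma, img.shape)
        frames[t] = np.clip(img, 0.0, 1.0) * 255.0 + 0.5
    return RenderResult(frames=frames, truth=truth,
                        reflection_positions=refl)


# ---------------------------------------------------------------------------
# Disk output

def write_frames(frames: np.ndarray, out: str | Path,
                 fmt: str = "png") -> list[Path]:
    """Write frames as zero-padded PNG/TIFF sequence or one multi-page TIFF.

    ``fmt`` is ``"png"``, ``"tiff"`` (sequence) or ``"tiff-stack"``.
    """
    import imageio.v3 as iio
    import tifffile

    out = Path(out)
    if fmt == "tiff-stack":
        out.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(out, np.asarray(frames, dtype=np.uint8))
        return [out]
    out.mkdir(parents=True, exist_ok=True)
    ext = {"png": "png", "tiff": "tif"}[fmt]
    paths = []
    for t, frame in enumerate(frames):
        p = out / f"frame_{t:06d}.{ext}"
        iio.imwrite(p, np.asarray(frame, dtype=np.uint8))
        paths.append(p)
    return paths


def write_ground_truth(truth: GroundTruth, csv_path: str | Path,
                       json_path: str | Path | None = None) -> None:
    """Ground truth as CSV (frame, well, x, y, state) + JSON parameter sidecar."""
    import pandas as pd

    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, traj in enumerate(truth.trajectories):
        n = len(traj)
        rows.append(pd.DataFrame({
            "frame": np.arange(n),
            "well": i,
            "x": traj.positions[:, 0],
            "y": traj.positions[:, 1],
            "state": np.where(truth.true_states[:, i], "move", "stop"),
        }))
    pd.concat(rows, ignore_index=True).to_csv(csv_path, index=False)
    if json_path is not None:
        payload = [dataclasses.asdict(p) for p in truth.true_params]
        Path(json_path).write_text(json.dumps(payload, indent=1))
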