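"""Behavioral parameters of a tracked larva.

Eight per-individual parameters are computed from a trajectory:

(i)    activity — fraction of frames in movement;
(ii)   radial index — mean relative distance from the well border toward
       the center (0 = at the wall, 1 = at the center);
(iii)  tortuosity — mean scalar product of successive unit velocity
       vectors while moving (cosine of the turning angle: 1 = straight,
       negative = reversals);
(iv)   speed — mean step length (px/frame) over moving frames;
(v)    bursting — stop->move transitions (rate per frame by default; the
       raw count is also reported);
(vi)   circularity — distance travelled along the border/center axis
       divided by total distance travelled;
(vii)  instant acceleration — mean step length at stop->move transitions;
(viii) instant tortuosity — mean scalar product of the first two velocity
       vectors following each stop->move transition.

A frame counts as movement when the displacement from the previous frame
exceeds ``epsilon`` (default 1 px, the tracker's pixel resolution). Gaps
are filled with the last known position before labeling, because the
tracker only loses a larva that has stopped moving.

Conditional parameters (iii)-(viii) are undefined (NaN) for a larva that
never moves.

For the rectangular novel-tank assay, :func:`wall_distance_index` replaces
the radial index: mean distance to the nearest long wall, scaled to 1 on
the midline and 0 at the walls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracker import Trajectory

PARAMETER_NAMES = (
    "activity", "radial_index", "speed", "bursting", "tortuosity",
    "circularity", "instant_acceleration", "instant_tortuosity",
)

#: Parameters that take both signs; dispersion for them uses the SD, not
#: the coefficient of variation.
SIGNED_PARAMETERS = ("tortuosity", "instant_tortuosity")


@dataclass(frozen=True)
class BehaviorVector:
    """The eight behavioral parameters of one larva (or one fragment)."""

    activity: float
    radial_index: float
    speed: float
    bursting: float
    tortuosity: float
    circularity: float
    instant_acceleration: float
    instant_tortuosity: float
    bursting_count: int = 0   #: raw stop->move transition count

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in PARAMETER_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAMETER_NAMES])


def label_motion_states(traj: Trajectory, epsilon: float = 1.0) -> np.ndarray:
    """Boolean per-frame MOVE labels (frame 0 is STOP by convention)."""
    pos = traj.filled_positions()
    disp = np.hypot(*np.diff(pos, axis=0).T)
    states = np.zeros(len(pos), dtype=bool)
    states[1:] = disp > epsilon
    return states


def compute_behavior_vector(traj: Trajectory,
                            epsilon: float = 1.0) -> BehaviorVector:
    """All eight parameters for one trajectory (well geometry from it)."""
    pos = traj.filled_positions()
    states = label_motion_states(traj, epsilon)
    n = len(pos)
    cx, cy = traj.center
    d = np.hypot(pos[:, 0] - cx, pos[:, 1] - cy)
    radial_index = float(np.clip(1.0 - d / traj.radius, 0.0, 1.0).mean())
    activity = float(states.mean())

    vel = np.diff(pos, axis=0)                 # vel[t-1] = p[t] - p[t-1]
    step = np.hypot(vel[:, 0], vel[:, 1])
    move = states[1:]                          # move[t-1] <-> frame t moving
    transitions = move & ~states[:-1]          # stop -> move at frame t
    n_bursts = int(transitions.sum())
    bursting = n_bursts / n

    if not move.any():
        nan = float("nan")
        return BehaviorVector(activity=activity, radial_index=radial_index,
                              speed=nan, bursting=bursting, tortuosity=nan,
                              circularity=nan, instant_acceleration=nan,
                              instant_tortuosity=nan, bursting_count=n_bursts)

    speed = float(step[move].mean())

    # unit velocities; dot products over consecutive moving frame pairs
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = vel / np.where(step[:, None] > 0, step[:, None], np.nan)
    dots = np.einsum("ij,ij->i", unit[:-1], unit[1:])
    pair_ok = move[:-1] & move[1:] & np.isfinite(dots)
    tortuosity = float(dots[pair_ok].mean()) if pair_ok.any() else float("nan")

    radial_step = np.abs(np.diff(d))
    circ_den = step[move].sum()
    circularity = float(radial_step[move].sum() / circ_den) if circ_den > 0 \
        else float("nan")

    instant_acceleration = float(step[transitions].mean()) if n_bursts \
        else float("nan")
    inst_ok = transitions[:-1] & move[1:] & np.isfinite(dots)
    instant_tortuosity = float(dots[inst_ok].mean()) if inst_ok.any() \
        else float("nan")

    return BehaviorVector(
        activity=activity, radial_index=radial_index, speed=speed,
        bursting=bursting, tortuosity=tortuosity, circularity=circularity,
        instant_acceleration=instant_acceleration,
        instant_tortuosity=instant_tortuosity, bursting_count=n_bursts)


@dataclass
class FragmentSeries:
    """Behavior vectors over consecutive, non-overlapping time fragments."""

    individual_id: int
    fragment_seconds: float
    vectors: list[BehaviorVector]

    def __len__(self) -> int:
        return len(self.vectors)

    def parameter(self, name: str) -> np.ndarray:
        """Fragment series of one named parameter."""
        if name not in PARAMETER_NAMES:
            raise KeyError(f"unknown parameter {name!r}")
        return np.array([getattr(v, name) for v in self.vectors])

    def points(self) -> np.ndarray:
        """(n_fragments, 2) array of (activity, radial index)."""
        return np.column_stack([self.parameter("activity"),
                                self.parameter("radial_index")])


def fragment_series(traj: Trajectory, fragment_seconds: float = 30.0,
                    epsilon: float = 1.0) -> FragmentSeries:
    """Split a trajectory into consecutive fragments and score each.

    Each fragment spans ``fragment_seconds * fps`` frames; a trailing
    partial fragment is discarded. A standard 20-min recording at 25 fps
    yields 40 fragments of 30 s.
    """
    frames_per = int(round(fragment_seconds * traj.fps))
    if frames_per < 2:
        raise ValueError("fragment shorter than two frames")
    n_frag = len(traj) // frames_per
    if n_frag < 1:
        raise ValueError(
            f"trajectory ({len(traj)} frames) shorter than one "
            f"{fragment_seconds}-s fragment ({frames_per} frames)")
    vectors = []
    for k in range(n_frag):
        chunk = traj.positions[k * frames_per:(k + 1) * frames_per]
        sub = Trajectory(well_id=traj.well_id, positions=chunk,
                         fps=traj.fps, center=traj.center,
                         radius=traj.radius)
        if np.isnan(sub.positions).all():
            # an all-gap fragment inherits the last known position
            prev = traj.filled_positions()[k * frames_per]
            sub = Trajectory(well_id=traj.well_id,
                             positions=np.tile(prev, (frames_per, 1)),
                             fps=traj.fps, center=traj.center,
                             radius=traj.radius)
        vectors.append(compute_behavior_vector(sub, epsilon=epsilon))
    return FragmentSeries(individual_id=traj.well_id,
                          fragment_seconds=fragment_seconds,
                          vectors=vectors)


def wall_distance_index(positions: np.ndarray,
                        rect: tuple[float, float, float, float]) -> float:
    """Mean normalized distance to the nearest long wall of a rectangle.

    ``rect`` is ``(x0, y0, x1, y1)``. The long walls are the two sides
    parallel to the longer axis; the index is 0 at a wall and 1 on the
    midline, averaged over frames.
    """
    x0, y0, x1, y1 = rect
    w, h = x1 - x0, y1 - y0
    if w <= 0 or h <= 0:
        raise ValueError("degenerate rectangle")
    pos = np.asarray(positions, dtype=float).reshape(-1, 2)
    ok = ~np.isnan(pos).any(axis=1)
    pos = pos[ok]
    if len(pos) == 0:
        raise ValueError("no positions")
    inside = ((pos[:, 0] >= x0) & (pos[:, 0] <= x1)
              & (pos[:, 1] >= y0) & (pos[:, 1] <= y1))
    if not inside.all():
        raise ValueError("positions outside the arena rectangle")
    if w >= h:   # long walls run along x: distance measured in y
        dist = np.minimum(pos[:, 1] - y0, y1 - pos[:, 1])
        half = h / 2.0
    else:
        dist = np.minimum(pos[:, 0] - x0, x1 - pos[:, 0])
        half = w / 2.0
    return float((dist / half).mean())


def behavior_table(trajectories: list[Trajectory],
                   epsilon: float = 1.0):
    """Per-individual behavior parameters as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for traj in trajectories:
        vec = compute_behavior_vector(traj, epsilon=epsilon)
        row = {"individual": traj.well_id}
        row.update(vec.as_dict())
        row["bursting_count"] = vec.bursting_count
        rows.append(row)
    return pd.DataFrame(rows)


def fragment_table(trajectories: list[Trajectory],
                   fragment_seconds: float = 30.0, epsilon: float = 1.0):
    """Per-fragment behavior parameters as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for traj in trajectories:
        series = fragment_series(traj, fragment_seconds, epsilon)
        for k, vec in enumerate(series.vectors):
            row = {"individual": traj.well_id, "fragment": k}
            row.update(vec.as_dict())
            rows.append(row)
    return pd.DataFrame(rows)
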