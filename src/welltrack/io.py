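"""File formats, run configuration, and the end-to-end pipeline.

CSV conventions: comma-separated, UTF-8, header row, '.' decimal; a
trajectory gap is an empty x/y cell. All CSV writers round-trip to full
float precision through their paired readers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, varstats
from .tracker import Trajectory, TrackerConfig, track_video
from .welldetect import WellMap, detect_wells

logger = logging.getLogger("welltrack")

_IMAGE_EXTS = (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""


@dataclass
class RunConfig:
    """End-to-end run parameters; every default is overridable and the
    whole config is echoed verbatim into the run log."""

    fps: float = 25.0              #: recording frame rate
    n_wells: int = 24              #: wells per plate
    threshold: float = -0.5        #: blob detection threshold
    fragment_seconds: float = 30.0  #: intra-individual fragment length
    n_perm: int = 1000             #: permutation count for tests
    epsilon: float = 1.0           #: movement threshold, px/frame
    sigma: float = 1.0             #: frame smoothing sigma, px
    seed: int = 0
    r_est: float | None = None     #: skip radius estimation when known
    input_path: str = ""
    output_dir: str = "welltrack_out"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def tracker_config(self) -> TrackerConfig:
        return TrackerConfig(threshold=self.threshold, sigma=self.sigma,
                             fps=self.fps)


# ---------------------------------------------------------------------------
# Frame input

def _to_gray_float(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)   # RGB -> luminance (plain average)
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    return arr.astype(float)


def read_frames(path: str | Path) -> np.ndarray:
    """Load a video as a (n_frames, h, w) float array in [0, 1].

    Accepts a directory of PNG/TIFF frames (read in filename order), a
    multi-page TIFF, or an AVI (requires an imageio ffmpeg backend).
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in _IMAGE_EXTS)
        if not files:
            raise FileNotFoundError(f"no image frames in {path}")
        import imageio.v3 as iio

        frames = [_to_gray_float(iio.imread(p)) for p in files]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"mixed frame sizes in {path}: {shapes}")
        return np.stack(frames)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        return np.stack([_to_gray_float(f) for f in stack])
    if path.suffix.lower() == ".avi":
        try:
            import imageio.v3 as iio

            frames = [_to_gray_float(f) for f in iio.imiter(path)]
        except Exception as exc:   # backend-dependent
            raise RuntimeError(
                f"cannot decode {path}: no AVI backend available "
                "(install imageio-ffmpeg), or convert the video to an "
                "image sequence") from exc
        if not frames:
            raise ValueError(f"no frames decoded from {path}")
        return np.stack(frames)
    raise ValueError(f"unsupported input {path}")


# ---------------------------------------------------------------------------
# CSV formats

def write_wellmap(wellmap: WellMap, path: str | Path) -> None:
    df = pd.DataFrame({
        "well": np.arange(wellmap.n_wells),
        "cx": wellmap.centers[:, 0],
        "cy": wellmap.centers[:, 1],
        "radius": wellmap.radius,
        "height": wellmap.image_shape[0],
        "width": wellmap.image_shape[1],
    })
    df.to_csv(path, index=False)


def read_wellmap(path: str | Path) -> WellMap:
    df = pd.read_csv(path, float_precision="round_trip")
    return WellMap(centers=df[["cx", "cy"]].to_numpy(),
                   radius=float(df["radius"].iloc[0]),
                   image_shape=(int(df["height"].iloc[0]),
                                int(df["width"].iloc[0])))


def write_trajectories(trajectories: list[Trajectory],
                       path: str | Path) -> None:
    """Trajectory CSV: frame, well, x, y — gap rows have empty x/y."""
    parts = []
    for traj in trajectories:
        parts.append(pd.DataFrame({
            "frame": np.arange(len(traj)),
            "well": traj.well_id,
            "x": traj.positions[:, 0],
            "y": traj.positions[:, 1],
        }))
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def read_trajectories(path: str | Path, wellmap: WellMap,
                      fps: float = 25.0) -> list[Trajectory]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for well, g in df.groupby("well", sort=True):
        g = g.sort_values("frame")
        pos = g[["x", "y"]].to_numpy(dtype=float)
        c = wellmap.centers[int(well)]
        out.append(Trajectory(well_id=int(well), positions=pos, fps=fps,
                              center=(float(c[0]), float(c[1])),
                              radius=wellmap.radius))
    return out


def save_density_map(dmap: varstats.DensityMap, csv_path: str | Path,
                     png_path: str | Path | None = None) -> None:
    dmap.to_dataframe().to_csv(csv_path, index=False)
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        m = ax.pcolormesh(dmap.x, dmap.y, dmap.values, shading="auto")
        fig.colorbar(m, ax=ax, label="probability density")
        ax.set_xlabel("activity")
        ax.set_ylabel("radial index")
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)


# ---------------------------------------------------------------------------
# End-to-end pipeline

def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """detect wells -> track -> behavior -> variability statistics.

    Writes trajectory/behavior/fragment CSVs, the density map (CSV + PNG),
    a JSON stats report and a JSON run log into ``config.output_dir`` and
    returns the artifact paths. Identical config and seed produce
    byte-identical artifacts.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"[{name}] {exc}") from exc

    frames = stage("read", read_frames, config.input_path)

    def _detect():
        from .welldetect import WellDetectionError, locate_well_centers
        from .welldetect import estimate_well_radius

        r = config.r_est or estimate_well_radius(frames[0], config.n_wells)
        try:
            return locate_well_centers(frames[0], r, config.n_wells)
        except WellDetectionError as exc:
            logger.warning("found %d of %d wells; saving partial map",
                           exc.found, config.n_wells)
            if exc.found == 0:
                raise
            return locate_well_centers(frames[0], r, exc.found)

    wellmap = stage("detect-wells", _detect)
    artifacts["wells"] = out / "wells.csv"
    write_wellmap(wellmap, artifacts["wells"])

    trajectories = stage("track", track_video, frames, wellmap,
                         config.tracker_config())
    artifacts["trajectories"] = out / "trajectories.csv"
    write_trajectories(trajectories, artifacts["trajectories"])

    btable = stage("behavior", behavior.behavior_table, trajectories,
                   config.epsilon)
    artifacts["behavior"] = out / "behavior.csv"
    btable.to_csv(artifacts["behavior"], index=False)
    ftable = stage("behavior", behavior.fragment_table, trajectories,
                   config.fragment_seconds, config.epsilon)
    artifacts["fragments"] = out / "fragments.csv"
    ftable.to_csv(artifacts["fragments"], index=False)

    def _stats():
        pts = btable[["activity", "radial_index"]].to_numpy()
        report: dict = {"n_individuals": int(len(pts))}
        if len(pts) >= 3:
            report["generalized_variance"] = varstats.generalized_variance(pts)
            dmap = varstats.kernel_density_map(pts)
            report["density_integral"] = dmap.integral()
            save_density_map(dmap, out / "density.csv", out / "density.png")
            artifacts["density_csv"] = out / "density.csv"
            artifacts["density_png"] = out / "density.png"
        series = [
            behavior.fragment_series(t, config.fragment_seconds,
                                     config.epsilon)
            for t in trajectories
        ]
        if len(series) >= 2 and min(len(s) for s in series) >= 2:
            tests = {}
            for param in ("activity", "radial_index"):
                res = varstats.permutation_test_intra_inter(
                    series, param, n_perm=config.n_perm, seed=config.seed)
                tests[param] = res.to_dict()
            report["intra_inter_tests"] = tests
        return report

    report = stage("stats", _stats)
    artifacts["stats"] = out / "stats.json"
    artifacts["stats"].write_text(json.dumps(report, indent=1,
                                             sort_keys=True))

    log = {
        "config": dataclasses.asdict(config),
        "n_frames": int(len(frames)),
        "wells_found": int(wellmap.n_wells),
        "gap_fraction": {int(t.well_id): t.gap_fraction
                         for t in trajectories},
    }
    artifacts["log"] = out / "run_log.json"
    artifacts["log"].write_text(json.dumps(log, indent=1, sort_keys=True))
    return artifacts
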