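"""Background-subtraction larva tracking in detected wells.

One larva per well. Per well and per frame the pipeline is:

crop to a square window around the well -> normalize the crop to mean
intensity 1 -> Gaussian-smooth -> subtract the *static* background (mean of
up to 1000 equi-spaced frames) -> threshold at ``diff < -0.5`` -> connected
components ("blobs", 8-connectivity, size >= 2 px) -> keep a blob only if
(a) it overlaps the larva pixels of the previous frame or (b) it contains a
pixel that is also below the threshold against the *dynamic* background
(mean of the previous five frames, i.e. evidence of current movement) ->
drop wall reflections -> report the most contrasted pixel of the most
contrasted blob, or a gap if nothing survives.

After a gap the larva is assumed stationary and is not re-tracked until it
moves: resuming requires dynamic-background evidence (condition (b)).

All thresholds operate on mean-normalized intensities, so detections are
invariant to overall illumination scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

#: 8-connectivity structuring element for blob labeling.
_STRUCT8 = np.ones((3, 3), dtype=bool)

#: Detection threshold on (frame - background) in mean-normalized units.
DEFAULT_THRESHOLD = -0.5


@dataclass
class TrackerConfig:
    """Tunable tracking parameters (defaults follow the method description;
    values the method leaves open are flagged in the docs)."""

    threshold: float = DEFAULT_THRESHOLD  #: blob threshold, normalized units
    sigma: float = 1.0                    #: pre-smoothing sigma, px
    min_blob_size: int = 2                #: "larger than one pixel"
    bg_samples: int = 1000                #: static-background sample count
    dyn_window: int = 5                   #: dynamic-background window, frames
    crop_factor: float = 2.4              #: crop side = crop_factor * r_est
    max_radial: float = 1.2               #: positions beyond this * r_est are discarded
    reflection_angle_deg: float = 10.0    #: reflection rule (c)
    fps: float = 25.0


@dataclass(eq=False)
class Blob:
    """Connected dark component in a background-subtracted frame."""

    pixels: np.ndarray          # (n, 2) int array of (x, y)
    min_diff: float             # most negative (frame - static bg) value
    anchor: tuple[int, int]     # (x, y) of that pixel
    cond_prev: bool = False     # rule (a): overlaps previous larva pixels
    cond_moving: bool = False   # rule (b): dynamic-background evidence

    @property
    def size(self) -> int:
        return len(self.pixels)


GAP = (np.nan, np.nan)


@dataclass
class Trajectory:
    """Per-well, per-frame larva positions; gaps are NaN rows.

    Positions are in full-image pixel coordinates ``(x, y)``.
    """

    well_id: int
    positions: np.ndarray       # (n_frames, 2) float, NaN = gap
    fps: float
    center: tuple[float, float]
    radius: float

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def gap_mask(self) -> np.ndarray:
        return np.isnan(self.positions).any(axis=1)

    @property
    def gap_fraction(self) -> float:
        return float(self.gap_mask.mean())

    def filled_positions(self) -> np.ndarray:
        """Positions with gaps filled by the last known position.

        A gap means the larva was not re-detected, which the tracking rules
        equate with "has not moved"; leading gaps take the first known
        position. Raises on an all-gap trajectory.
        """
        pos = self.positions.copy()
        good = ~self.gap_mask
        if not good.any():
            raise ValueError(f"well {self.well_id}: all-gap trajectory")
        # leading gaps -> first detection; later gaps -> previous detection
        valid = np.where(good)[0]
        take = valid[np.searchsorted(valid, np.arange(len(pos)), side="right") - 1]
        take[: valid[0]] = valid[0]
        return pos[take]


# ---------------------------------------------------------------------------
# Frame operations

def normalize_frame(raw: np.ndarray) -> np.ndarray:
    """Divide every pixel by the frame's mean intensity (output mean = 1)."""
    arr = np.asarray(raw, dtype=float)
    m = arr.mean()
    if m <= 0:
        raise ValueError("cannot normalize a frame with non-positive mean")
    return arr / m


def smooth_frame(frame: np.ndarray, sigma: float) -> np.ndarray:
    """2-D Gaussian low-pass with reflective boundaries; sigma 0 = identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    arr = np.asarray(frame, dtype=float)
    if sigma == 0:
        return arr.copy()
    return ndimage.gaussian_filter(arr, sigma, mode="reflect")


def equispaced_indices(n_frames: int, n_samples: int = 1000) -> np.ndarray:
    """Indices of up to ``n_samples`` equi-spaced frames, first frame included."""
    if n_frames < 1:
        raise ValueError("need at least one frame")
    m = min(n_samples, n_frames)
    return np.rint(np.linspace(0, n_frames - 1, m)).astype(int)


def static_background(frames, sigma: float = 1.0,
                      n_samples: int = 1000) -> np.ndarray:
    """Mean of up to 1000 equi-spaced normalized-and-smoothed frames."""
    n = len(frames)
    idx = equispaced_indices(n, n_samples)
    acc = None
    for i in idx:
        f = smooth_frame(normalize_frame(frames[i]), sigma)
        acc = f if acc is None else acc + f
    return acc / len(idx)


def dynamic_background(recent: list[np.ndarray]) -> np.ndarray:
    """Mean of the previous (up to five) processed frames.

    Early in the video the buffer holds fewer frames and the mean is taken
    over what exists; an empty buffer (frame 0) is an error — the dynamic
    condition is unusable for that frame.
    """
    if len(recent) == 0:
        raise ValueError("dynamic background undefined with an empty buffer")
    return np.mean(np.asarray(recent), axis=0)


# ---------------------------------------------------------------------------
# Blob detection and filtering

def detect_candidate_blobs(frame: np.ndarray, static_bg: np.ndarray,
                           dyn_bg: np.ndarray | None,
                           prev_pixels: np.ndarray | None,
                           threshold: float = DEFAULT_THRESHOLD,
                           min_size: int = 2) -> list[Blob]:
    """Thresholded connected components that pass the noise-filter rules.

    Parameters
    ----------
    frame, static_bg, dyn_bg : ndarray
        Normalized-and-smoothed crop, its static background, and the
        dynamic background (``None`` at frame 0, when it does not exist).
    prev_pixels : bool ndarray or None
        Mask of the pixels assigned to the larva in the previous frame
        (``None`` if there was no previous detection).

    A blob is kept iff rule (a) — overlap with ``prev_pixels`` — or rule
    (b) — some pixel with ``frame - dyn_bg < threshold`` — holds. At the
    very first frame neither rule can be evaluated and blobs are accepted
    unconditionally to initialize tracking.
    """
    diff = frame - static_bg
    mask = diff < threshold
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return []
    dyn_mask = (frame - dyn_bg < threshold) if dyn_bg is not None else None
    blobs: list[Blob] = []
    slices = ndimage.find_objects(labels)
    for lab, sl in enumerate(slices, start=1):
        comp = labels[sl] == lab
        size = int(comp.sum())
        if size < min_size:
            continue
        cond_a = bool(prev_pixels is not None
                      and (prev_pixels[sl] & comp).any())
        cond_b = bool(dyn_mask is not None and (dyn_mask[sl] & comp).any())
        bootstrap = prev_pixels is None and dyn_mask is None
        if not (cond_a or cond_b or bootstrap):
            continue
        sub = np.where(comp, diff[sl], np.inf)
        iy, ix = np.unravel_index(int(np.argmin(sub)), sub.shape)
        ys, xs = np.nonzero(comp)
        pixels = np.column_stack([xs + sl[1].start, ys + sl[0].start])
        blobs.append(Blob(
            pixels=pixels,
            min_diff=float(sub[iy, ix]),
            anchor=(int(ix + sl[1].start), int(iy + sl[0].start)),
            cond_prev=cond_a,
            cond_moving=cond_b,
        ))
    return blobs


def remove_reflections(blobs: list[Blob], center: tuple[float, float],
                       angle_deg: float = 10.0) -> list[Blob]:
    """Drop wall reflections.

    Blob A is removed when some blob B is (a) strictly bigger, (b) strictly
    closer to the well center, and (c) the rays well-center->A and
    well-center->B subtend an angle below ``angle_deg``. The largest blob
    can never be removed (no strictly bigger B exists).
    """
    if len(blobs) < 2:
        return list(blobs)
    cx, cy = center
    vec = np.array([[b.anchor[0] - cx, b.anchor[1] - cy] for b in blobs])
    dist = np.hypot(vec[:, 0], vec[:, 1])
    ang = np.arctan2(vec[:, 1], vec[:, 0])
    sizes = np.array([b.size for b in blobs])
    keep = []
    limit = np.deg2rad(angle_deg)
    for i, a in enumerate(blobs):
        reflected = False
        for j in range(len(blobs)):
            if j == i:
                continue
            sep = np.abs(np.angle(np.exp(1j * (ang[i] - ang[j]))))
            if sizes[j] > sizes[i] and dist[j] < dist[i] and sep < limit:
                reflected = True
                break
        if not reflected:
            keep.append(a)
    return keep


def select_position(blobs: list[Blob]) -> Blob | None:
    """Pick the blob with the highest contrast (most negative ``min_diff``);
    its anchor pixel becomes the larva position. ``None`` means a gap."""
    if not blobs:
        return None
    best = min(range(len(blobs)), key=lambda i: blobs[i].min_diff)
    return blobs[best]


# ---------------------------------------------------------------------------
# Whole-video tracking

def _crop_window(center, radius, shape, factor):
    half = factor * radius / 2.0
    cx, cy = center
    x0 = max(int(np.floor(cx - half)), 0)
    x1 = min(int(np.ceil(cx + half)) + 1, shape[1])
    y0 = max(int(np.floor(cy - half)), 0)
    y1 = min(int(np.ceil(cy + half)) + 1, shape[0])
    return x0, x1, y0, y1


def track_well(frames, center, radius, well_id: int,
               cfg: TrackerConfig | None = None) -> Trajectory:
    """Track one well across an indexable sequence of grayscale frames."""
    cfg = cfg or TrackerConfig()
    n = len(frames)
    shape = np.asarray(frames[0]).shape
    x0, x1, y0, y1 = _crop_window(center, radius, shape, cfg.crop_factor)
    ccx, ccy = center[0] - x0, center[1] - y0  # center in crop coords

    # Pass 1: normalize + smooth every crop once (cached for both uses).
    crops = np.empty((n, y1 - y0, x1 - x0), dtype=np.float32)
    for t in range(n):
        crop = np.asarray(frames[t], dtype=float)[y0:y1, x0:x1]
        crops[t] = smooth_frame(normalize_frame(crop), cfg.sigma)
    idx = equispaced_indices(n, cfg.bg_samples)
    static_bg = crops[idx].mean(axis=0, dtype=np.float64)

    positions = np.full((n, 2), np.nan)
    prev_pixels: np.ndarray | None = None
    in_gap = False
    ever_tracked = False
    for t in range(n):
        frame = crops[t].astype(np.float64)
        dyn_bg = (crops[max(0, t - cfg.dyn_window):t]
                  .mean(axis=0, dtype=np.float64) if t > 0 else None)
        blobs = detect_candidate_blobs(
            frame, static_bg, dyn_bg, prev_pixels,
            threshold=cfg.threshold, min_size=cfg.min_blob_size)
        # Discard blobs whose anchor falls outside the well neighborhood.
        blobs = [b for b in blobs
                 if np.hypot(b.anchor[0] - ccx, b.anchor[1] - ccy)
                 <= cfg.max_radial * radius]
        blobs = remove_reflections(blobs, (ccx, ccy),
                                   angle_deg=cfg.reflection_angle_deg)
        if in_gap and ever_tracked:
            # Re-track only when the larva moves: require rule (b).
            blobs = [b for b in blobs if b.cond_moving]
        chosen = select_position(blobs)
        if chosen is None:
            in_gap = True
            # prev_pixels persist only as resume context, not for rule (a):
            prev_pixels = None
        else:
            positions[t] = (chosen.anchor[0] + x0, chosen.anchor[1] + y0)
            mask = np.zeros_like(frame, dtype=bool)
            mask[chosen.pixels[:, 1], chosen.pixels[:, 0]] = True
            prev_pixels = mask
            in_gap = False
            ever_tracked = True
    return Trajectory(well_id=well_id, positions=positions, fps=cfg.fps,
                      center=(float(center[0]), float(center[1])),
                      radius=float(radius))


def track_video(frames, wellmap, cfg: TrackerConfig | None = None
                ) -> list[Trajectory]:
    """Track every well of a plate video.

    Parameters
    ----------
    frames : sequence of 2-D arrays (or a 3-D array)
        Grayscale video; any intensity scale (normalization makes the
        tracker invariant to it).
    wellmap : WellMap
        Detected well geometry matching the frame size.
    """
    cfg = cfg or TrackerConfig()
    shape = tuple(np.asarray(frames[0]).shape)
    if shape != tuple(wellmap.image_shape):
        raise ValueError(
            f"frame shape {shape} does not match well map "
            f"{tuple(wellmap.image_shape)}")
    return [
        track_well(frames, tuple(c), wellmap.radius, well_id=i, cfg=cfg)
        for i, c in enumerate(wellmap.centers)
    ]
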