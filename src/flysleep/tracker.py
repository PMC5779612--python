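"""Background-subtraction movement tracker for single-fly video.

Re-creation of the real-time detector used in closed-loop rigs: each new
frame is compared against a temporally low-pass filtered background (an
exponential moving average); pixels whose absolute difference exceeds an
intensity threshold are grouped into connected clusters, small clusters
are discarded, and the intensity-weighted centroid of the largest
surviving cluster is the candidate fly position.  Candidate displacements
below 2.5 mm are discarded as noise, in which case the fly is assumed to
have remained at its last known location.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = [
    "FrameStack",
    "BackgroundModel",
    "TrackerConfig",
    "MovementEvent",
    "update_background",
    "detect_movement",
    "track",
]


@dataclass
class FrameStack:
    """Grayscale video frames (n, height, width) with acquisition metadata."""

    frames: np.ndarray
    frame_rate: float  # Hz
    px_per_mm: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, height, width) array")
        if self.frame_rate <= 0 or self.px_per_mm <= 0:
            raise ValueError("frame_rate and px_per_mm must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) / self.frame_rate

    def to_tiff(self, path: str | Path) -> None:
        meta = {"frame_rate_hz": self.frame_rate, "px_per_mm": self.px_per_mm}
        tifffile.imwrite(
            path, self.frames, photometric="minisblack", description=json.dumps(meta)
        )

    @classmethod
    def from_tiff(cls, path: str | Path) -> "FrameStack":
        with tifffile.TiffFile(path) as tf:
            frames = tf.asarray()
            desc = tf.pages[0].description or "{}"
        meta = json.loads(desc)
        return cls(frames, meta["frame_rate_hz"], meta["px_per_mm"])


@dataclass
class BackgroundModel:
    """Exponential-moving-average background: new = (1-alpha)*old + alpha*frame."""

    image: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")


@dataclass
class TrackerConfig:
    """Detector thresholds.

    ``intensity_threshold`` acts on the absolute difference image (gray
    levels); clusters smaller than ``min_cluster_px`` are discarded;
    candidate displacements below ``displacement_threshold`` mm (default
    2.5) are ignored.  ``connectivity`` is 4 or 8.
    """

    intensity_threshold: float = 20.0
    min_cluster_px: int = 5
    displacement_threshold: float = 2.5
    px_per_mm: float = 10.0
    connectivity: int = 8
    difference: str = "positive"  # "positive" (frame - background) or "abs"

    def __post_init__(self) -> None:
        if self.displacement_threshold <= 0:
            raise ValueError("displacement_threshold must be positive")
        if self.min_cluster_px < 1:
            raise ValueError("min_cluster_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.difference not in ("positive", "abs"):
            raise ValueError("difference must be 'positive' or 'abs'")


@dataclass
class MovementEvent:
    time: float  # s
    from_xy: tuple[float, float]  # mm
    to_xy: tuple[float, float]  # mm
    displacement: float  # mm


def update_background(model: BackgroundModel, frame: np.ndarray) -> BackgroundModel:
    """One EMA step of the temporally low-pass filtered background."""
    frame = np.asarray(frame, dtype=float)
    if frame.shape != model.image.shape:
        raise ValueError(
            f"frame shape {frame.shape} does not match background {model.image.shape}"
        )
    return replace(model, image=(1.0 - model.alpha) * model.image + model.alpha * frame)


def _largest_cluster_centroid(
    diff: np.ndarray, cfg: TrackerConfig
) -> tuple[float, float] | None:
    """Intensity-weighted centroid (px, x right / y down) of the largest
    above-threshold cluster, or None when no cluster survives the size cut.

    Ties on pixel count break by greater summed intensity, then by lowest
    component label — deterministic.
    """
    mask = diff > cfg.intensity_threshold
    if not mask.any():
        return None
    structure = (
        np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        if cfg.connectivity == 4
        else np.ones((3, 3), dtype=int)
    )
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return None
    ids = np.arange(1, n + 1)
    sizes = ndimage.sum_labels(np.ones_like(diff), labels, ids)
    keep = sizes >= cfg.min_cluster_px
    if not keep.any():
        return None
    sums = ndimage.sum_labels(diff, labels, ids)
    order = np.lexsort((ids[keep], -sums[keep], -sizes[keep]))
    best = ids[keep][order[0]]
    m = labels == best
    w = diff[m]
    yy, xx = np.nonzero(m)
    return float(np.average(xx, weights=w)), float(np.average(yy, weights=w))


def detect_movement(
    frame: np.ndarray,
    model: BackgroundModel,
    last_pos: tuple[float, float] | None,
    cfg: TrackerConfig,
    time: float = 0.0,
) -> tuple[tuple[float, float] | None, MovementEvent | None]:
    """Detect a movement in one frame against the background model.

    Returns the updated position (mm) and an event if the candidate
    centroid lies at least ``displacement_threshold`` mm from the last
    accepted position.  Absence of clusters is the no-movement outcome,
    not an error; with no prior position the first candidate is adopted
    silently (no event can be scored without a reference point).

    With the default ``difference="positive"`` the cluster search runs on
    ``frame - background`` clipped at zero: a bright fly arriving at a new
    location is a positive deviation, while the darkening ghost it leaves
    behind (still present in the slow background) is negative and ignored.
    ``difference="abs"`` keeps both polarities.
    """
    delta = np.asarray(frame, dtype=float) - model.image
    diff = np.abs(delta) if cfg.difference == "abs" else np.clip(delta, 0.0, None)
    cand_px = _largest_cluster_centroid(diff, cfg)
    if cand_px is None:
        return last_pos, None
    cand = (cand_px[0] / cfg.px_per_mm, cand_px[1] / cfg.px_per_mm)
    if last_pos is None:
        return cand, None
    disp = float(np.hypot(cand[0] - last_pos[0], cand[1] - last_pos[1]))
    if disp < cfg.displacement_threshold:
        return last_pos, None
    return cand, MovementEvent(time, last_pos, cand, disp)


def track(
    stack: FrameStack,
    cfg: TrackerConfig,
    bg_alpha: float = 0.05,
    initial_position: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, list[MovementEvent]]:
    """Stream the detector over a frame stack.

    The first frame initializes the background; output begins at the
    second frame.  The background is updated with every frame, movement
    or not, so a resting fly is slowly absorbed (alpha default 0.05 at
    ~5 Hz framing).  Returns a per-frame position table (held positions
    included, ``moved`` flagging event frames) and the event list.
    """
    if len(stack) < 2:
        raise ValueError("need at least 2 frames to track")
    cfg = replace(cfg, px_per_mm=stack.px_per_mm)
    model = BackgroundModel(stack.frames[0], bg_alpha)
    pos = initial_position
    times = stack.times
    rows = []
    events: list[MovementEvent] = []
    for i in range(1, len(stack)):
        frame = stack.frames[i]
        pos, ev = detect_movement(frame, model, pos, cfg, time=float(times[i]))
        if ev is not None:
            events.append(ev)
        x, y = pos if pos is not None else (float("nan"), float("nan"))
        rows.append(
            {"frame": i, "t_s": float(times[i]), "x_mm": x, "y_mm": y, "moved": int(ev is not None)}
        )
        model = update_background(model, frame)
    return pd.DataFrame(rows), events


def write_positions_csv(positions: pd.DataFrame, path: str | Path) -> None:
    positions.to_csv(path, index=False)


def write_events_csv(events: list[MovementEvent], path: str | Path) -> None:
    pd.DataFrame(
        {
            "t_s": [e.time for e in events],
            "from_x": [e.from_xy[0] for e in events],
            "from_y": [e.from_xy[1] for e in events],
            "to_x": [e.to_xy[0] for e in events],
            "to_y": [e.to_xy[1] for e in events],
            "displacement_mm": [e.displacement for e in events],
        }
    ).to_csv(path, index=False)
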